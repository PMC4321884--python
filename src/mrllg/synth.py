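"""Self-contained synthetic crystal benchmarks.

Generates toy crystal structures (poly-alanine-like backbones on smoothed
self-avoiding random walks, packed into a cell with generous solvent),
simulates structure-factor amplitudes from them, and derives "predictions"
by perturbing the target with known, spatially heterogeneous per-atom
coordinate errors — emulating a CASP-style corpus in which some predictors
submit genuine error estimates in the B column, some submit zeros, some
carry over template B factors, and some submit miscalibrated estimates.

Error convention: the per-residue sigma_i of an :class:`ErrorProfile` is
the 1-D per-coordinate standard deviation; the 3-D mean-square error is
<|dr|^2> = 3 sigma_i^2, so an honest predictor writes |dr|_rms =
sigma_i * sqrt(3) into the B column.  Conflating the two conventions is
exactly the factor-of-3 pitfall the rms/rms_no3 scheme pair probes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import prep, sfcalc
from .iohub import (AtomicModel, ReflectionSet, ValidationError,
                    build_reflection_set, get_space_group, write_model,
                    write_reflections)

__all__ = [
    "ErrorProfile",
    "PredictorSpec",
    "DEFAULT_PREDICTORS",
    "make_target",
    "simulate_amplitudes",
    "perturb_model",
    "make_benchmark",
]

SQRT3 = float(np.sqrt(3.0))


@dataclasses.dataclass
class ErrorProfile:
    """Per-residue true coordinate-error levels (1-D sd, angstroms)."""

    resnum: np.ndarray
    sigma: np.ndarray  # per-residue 1-D sd
    generator: str = "explicit"
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise ValidationError("error-profile sigmas must be >= 0")

    def sigma_of(self, resnum: np.ndarray) -> np.ndarray:
        lut = dict(zip(self.resnum.tolist(), self.sigma.tolist()))
        return np.array([lut[int(r)] for r in resnum])

    @classmethod
    def uniform(cls, model: AtomicModel, sigma: float) -> "ErrorProfile":
        res = np.unique(model.resnum)
        return cls(res, np.full(len(res), sigma), "uniform", {"sigma": sigma})

    @classmethod
    def two_population(cls, model: AtomicModel, p_core: float = 0.5,
                       sigma_core: float = 0.3, sigma_surf: float = 1.5,
                       ) -> "ErrorProfile":
        """Core/surface split: the p_core fraction of residues closest to the
        centroid get sigma_core, the rest sigma_surf."""
        res = np.unique(model.resnum)
        centroid = model.xyz.mean(axis=0)
        dist = np.array([np.linalg.norm(
            model.xyz[model.resnum == r].mean(axis=0) - centroid) for r in res])
        n_core = int(round(p_core * len(res)))
        order = np.argsort(dist, kind="stable")
        sigma = np.full(len(res), sigma_surf)
        sigma[order[:n_core]] = sigma_core
        return cls(res, sigma, "two_population",
                   {"p_core": p_core, "sigma_core": sigma_core,
                    "sigma_surf": sigma_surf})

    @classmethod
    def radial(cls, model: AtomicModel, sigma_min: float = 0.2,
               sigma_max: float = 1.5) -> "ErrorProfile":
        """sigma grows linearly with residue distance from the centroid."""
        res = np.unique(model.resnum)
        centroid = model.xyz.mean(axis=0)
        dist = np.array([np.linalg.norm(
            model.xyz[model.resnum == r].mean(axis=0) - centroid) for r in res])
        span = dist.max() - dist.min()
        frac = (dist - dist.min()) / span if span > 0 else np.zeros(len(res))
        sigma = sigma_min + frac * (sigma_max - sigma_min)
        return cls(res, sigma, "radial",
                   {"sigma_min": sigma_min, "sigma_max": sigma_max})


# ---------------------------------------------------------------------------
# target generation


def _ca_walk(n_res: int, rng: np.random.Generator, max_tries: int = 300) -> np.ndarray:
    """Self-avoiding smoothed random walk of CA positions, 3.8 A steps.

    Alternates straighter helix-like segments with sharper turns; rejects
    walks where non-neighbor CAs come closer than 4 A.
    """
    r_max = 3.2 * n_res ** (1.0 / 3.0)  # compact-globule radius bound
    for _ in range(max_tries):
        pts = [np.zeros(3)]
        direction = _unit(rng.standard_normal(3))
        seg_left = int(rng.integers(8, 16))
        wiggle = 0.25
        ok = True
        for i in range(1, n_res):
            if seg_left == 0:
                seg_left = int(rng.integers(6, 16))
                wiggle = float(rng.uniform(0.2, 0.9))
                direction = _unit(direction + rng.standard_normal(3))
            placed = False
            trial_dir = direction
            for attempt in range(30):
                trial_dir = _unit(trial_dir + wiggle * rng.standard_normal(3))
                centroid = np.mean(pts, axis=0)
                out_vec = pts[-1] - centroid
                if np.linalg.norm(out_vec) > r_max:
                    # steer back toward the centroid to keep the fold globular
                    trial_dir = _unit(trial_dir - 0.8 * _unit(out_vec))
                new = pts[-1] + 3.8 * trial_dir
                if i >= 3:
                    d = np.linalg.norm(np.array(pts[:i - 2]) - new, axis=1)
                    if d.min() < 4.0:
                        continue
                placed = True
                direction = trial_dir
                break
            if not placed:
                ok = False
                break
            pts.append(new)
            seg_left -= 1
        if ok:
            return np.array(pts)
    raise ValidationError(f"failed to generate a self-avoiding {n_res}-residue walk")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _backbone_from_ca(ca: np.ndarray) -> tuple:
    """Place N, CA, C, O atoms (4 heavy atoms/residue) around a CA trace."""
    n_res = len(ca)
    xyz, names = [], []
    for i in range(n_res):
        e = _unit((ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)]))
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(e, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(e, ref))
        v = np.cross(e, u)
        n_at = ca[i] - 1.22 * e + 0.80 * u
        c_at = ca[i] + 1.25 * e + 0.78 * u
        o_at = c_at + 1.10 * v + 0.55 * u
        xyz.extend([n_at, ca[i], c_at, o_at])
        names.extend(["N", "CA", "C", "O"])
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    return np.array(xyz), names, [elements[n] for n in names]


def _min_cross_distance(xyz: np.ndarray, cell: gemmi.UnitCell,
                        sg: gemmi.SpaceGroup) -> float:
    """Minimum distance between the molecule and its symmetry/lattice images."""
    frac_m = np.array(cell.frac.mat.tolist())
    orth_m = np.array(cell.orth.mat.tolist())
    frac = xyz @ frac_m.T
    tree = cKDTree(xyz)
    best = np.inf
    ops = list(sg.operations())
    for k, op in enumerate(ops):
        R = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    if k == 0 and sx == sy == sz == 0:
                        continue
                    img = (frac @ R.T + t + np.array([sx, sy, sz])) @ orth_m.T
                    d, _ = tree.query(img, k=1)
                    best = min(best, float(d.min()))
    return best


def make_target(n_res: int, n_copies: int = 1, space_group: str = "P1",
                seed: int = 0) -> AtomicModel:
    """Generate a toy crystal structure.

    A poly-alanine-like backbone (N, CA, C, O per residue) is laid along a
    self-avoiding smoothed random walk, B factors drawn U[10, 40] per
    residue.  ``n_copies`` > 1 places additional NCS copies (chains B, C,
    ...) by random rigid transforms.  The unit cell is grown until all
    symmetry and lattice images are at least 2 A apart.
    """
    if n_res < 20:
        raise ValidationError("n_res must be >= 20")
    sg = get_space_group(space_group)
    rng = np.random.default_rng([seed, 7919])
    ca = _ca_walk(n_res, rng)
    xyz, names, elements = _backbone_from_ca(ca)
    n_atoms_per = len(xyz)
    b_res = rng.uniform(10.0, 40.0, n_res)
    b = np.repeat(b_res, 4)
    chains, all_xyz, all_b = ["A"] * n_atoms_per, [xyz], [b]
    for ci in range(1, n_copies):
        R = Rotation.random(random_state=np.random.RandomState(seed * 977 + ci)
                            ).as_matrix()
        centroid = xyz.mean(axis=0)
        offset = np.zeros(3)
        offset[ci % 3] = (xyz.max(axis=0) - xyz.min(axis=0)).max() + 8.0
        copy = (xyz - centroid) @ R.T + centroid + offset
        all_xyz.append(copy)
        all_b.append(b)
        chains.extend([chr(ord("A") + ci)] * n_atoms_per)
    xyz_all = np.vstack(all_xyz)
    xyz_all -= xyz_all.min(axis=0) - 2.0
    extent = xyz_all.max(axis=0) + 2.0
    n_ops = len(list(sg.operations()))
    factor = 1.0 if n_ops == 1 else (1.3 if n_ops == 2 else 1.45)
    cell_lengths = extent * factor
    for _ in range(20):
        cell = gemmi.UnitCell(*cell_lengths, 90, 90, 90)
        if _min_cross_distance(xyz_all, cell, sg) >= 2.0:
            break
        cell_lengths = cell_lengths * 1.1
    resnum = np.tile(np.repeat(np.arange(1, n_res + 1), 4), n_copies)
    return AtomicModel(
        element=np.tile(elements, n_copies), xyz=xyz_all,
        b=np.concatenate(all_b), occ=np.ones(len(xyz_all)),
        chain=np.array(chains), resnum=resnum,
        resname=np.full(len(xyz_all), "ALA"),
        atomname=np.tile(names, n_copies),
        cell=(cell_lengths[0], cell_lengths[1], cell_lengths[2], 90, 90, 90),
        space_group=sg.hm, b_column_meaning="b_factor")


def simulate_amplitudes(target: AtomicModel, d_min: float = 2.5,
                        noise_frac: float = 0.0, seed: int = 0) -> ReflectionSet:
    """Simulate observed amplitudes complete to d_min.

    F_obs = |F_calc(target)| perturbed multiplicatively by Gaussian noise of
    relative standard deviation ``noise_frac``; sigF records the applied
    noise level.
    """
    sg = get_space_group(target.space_group)
    cell = target.gemmi_cell
    hkl = gemmi.make_miller_array(cell, sg, d_min)
    if len(hkl) == 0:
        raise ValidationError("no reflections to d_min")
    placeholder = build_reflection_set(hkl, np.ones(len(hkl)), None,
                                       target.cell, target.space_group)
    fcalc = np.abs(sfcalc.calc_sf(target, placeholder))
    rng = np.random.default_rng([seed, 104729])
    if noise_frac > 0:
        f = fcalc * (1.0 + noise_frac * rng.standard_normal(len(fcalc)))
        f = np.maximum(f, 1e-6 * fcalc.mean())
        sigf = noise_frac * fcalc
    else:
        f, sigf = fcalc, None
    return placeholder.replace_f(f) if sigf is None else dataclasses.replace(
        placeholder, f=f, sigf=sigf)


def perturb_model(target: AtomicModel, profile: ErrorProfile,
                  completeness: float = 1.0, seed: int = 0,
                  error_mode: str = "none", error_scale: float = 1.0):
    """Derive a "prediction" from a target chain with known errors.

    Each atom is displaced by isotropic Gaussian noise with its residue's
    1-D sigma; a random (1 - completeness) fraction of residues is deleted.
    ``error_mode`` controls what lands in the B column:

    - ``none``: original B factors kept (b_column_meaning unchanged)
    - ``honest``: |dr|_rms = sigma * sqrt(3), as error estimates
    - ``scaled``: honest values multiplied by ``error_scale`` (miscalibrated)
    - ``zeros``: all zeros (predictor submitted no estimates)
    - ``template_b``: B factors carried over from the target

    Returns (prediction, per-atom true 1-D sigma array).
    """
    if not (0.0 < completeness <= 1.0):
        raise ValidationError("completeness must be in (0, 1]")
    rng = np.random.default_rng([seed, 15485863])
    pred = target.copy()
    sigma_atom = profile.sigma_of(pred.resnum)
    pred.xyz = pred.xyz + rng.standard_normal(pred.xyz.shape) * sigma_atom[:, None]
    residues = np.unique(pred.resnum)
    n_keep = int(round(completeness * len(residues)))
    kept = rng.choice(residues, size=n_keep, replace=False)
    mask = np.isin(pred.resnum, kept)
    pred = pred.select(mask)
    sigma_atom = sigma_atom[mask]
    if error_mode == "none":
        pass
    elif error_mode in ("honest", "scaled"):
        scale = 1.0 if error_mode == "honest" else error_scale
        pred.b = profile.sigma_of(pred.resnum) * SQRT3 * scale
        pred.b_column_meaning = "error_estimate"
    elif error_mode == "zeros":
        pred.b = np.zeros(pred.n_atoms)
        pred.b_column_meaning = "unknown"
    elif error_mode == "template_b":
        pred.b_column_meaning = "unknown"  # B values kept from the template
    else:
        raise ValidationError(f"unknown error_mode {error_mode!r}")
    return pred, sigma_atom


# ---------------------------------------------------------------------------
# benchmark corpus


@dataclasses.dataclass
class PredictorSpec:
    """Accuracy distribution and error-estimate behavior of one archetype."""

    name: str
    profile: str = "two_population"   # two_population | radial | uniform
    profile_params: dict = dataclasses.field(default_factory=dict)
    completeness: float = 1.0
    error_mode: str = "honest"        # honest | zeros | template_b | scaled
    error_scale: float = 1.0
    submits_estimates: bool = True    # ground truth for detection studies

    def make_profile(self, chain: AtomicModel) -> ErrorProfile:
        if self.profile == "two_population":
            return ErrorProfile.two_population(chain, **self.profile_params)
        if self.profile == "radial":
            return ErrorProfile.radial(chain, **self.profile_params)
        if self.profile == "uniform":
            return ErrorProfile.uniform(chain, **self.profile_params)
        raise ValidationError(f"unknown profile {self.profile!r}")


# The default corpus mirrors the CASP situation the evaluation targets: a
# small minority of predictors submit genuine error estimates while the
# bulk submit zeros (or, less commonly, B factors carried over from a
# template), with a spread of structural accuracies.  Sigmas below are 1-D
# per-coordinate sds; the corresponding 3-D |dr| values are sqrt(3) larger
# (e.g. surf 0.87 -> |dr| 1.5 A).  The error-submitters sit inside the
# bulk's quality range and the template-B archetype is structurally poor,
# so per-target Z distributions stay comparable across schemes — the
# regime in which the Z-gap detection heuristic is meaningful.
DEFAULT_PREDICTORS = (
    PredictorSpec("honest_a", "two_population",
                  {"p_core": 0.5, "sigma_core": 0.173, "sigma_surf": 0.866},
                  error_mode="honest", submits_estimates=True),
    PredictorSpec("honest_b", "two_population",
                  {"p_core": 0.5, "sigma_core": 0.231, "sigma_surf": 1.039},
                  error_mode="honest", submits_estimates=True),
    PredictorSpec("miscal", "two_population",
                  {"p_core": 0.5, "sigma_core": 0.173, "sigma_surf": 0.866},
                  error_mode="scaled", error_scale=1.3, submits_estimates=True),
    PredictorSpec("template_b", "uniform", {"sigma": 1.5},
                  error_mode="template_b", submits_estimates=False),
    PredictorSpec("zeros_1", "two_population",
                  {"p_core": 0.55, "sigma_core": 0.087, "sigma_surf": 0.520},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_2", "two_population",
                  {"p_core": 0.55, "sigma_core": 0.173, "sigma_surf": 0.693},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_3", "two_population",
                  {"p_core": 0.5, "sigma_core": 0.173, "sigma_surf": 0.866},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_4", "two_population",
                  {"p_core": 0.5, "sigma_core": 0.231, "sigma_surf": 1.039},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_5", "two_population",
                  {"p_core": 0.45, "sigma_core": 0.289, "sigma_surf": 1.155},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_rad", "radial",
                  {"sigma_min": 0.1, "sigma_max": 1.1},
                  error_mode="zeros", submits_estimates=False),
    PredictorSpec("zeros_poor", "uniform", {"sigma": 0.7},
                  completeness=0.9, error_mode="zeros",
                  submits_estimates=False),
)


def make_benchmark(n_targets: int = 5, predictor_specs=None, seed: int = 1,
                   out_dir=None, n_res_range=(60, 120),
                   space_groups=("P 1", "P 21 21 21"),
                   d_min_range=(2.0, 2.5), noise_frac: float = 0.03) -> dict:
    """Generate a benchmark corpus with full ground truth.

    Returns a dict with per-target entries (target model, reflections,
    baseline model, predictions per predictor with true sigma profiles) and
    a JSON-serializable manifest.  With ``out_dir``, targets and predictions
    are written as PDB, reflections as text hkl, plus ``manifest.json``.
    """
    specs = list(predictor_specs) if predictor_specs is not None \
        else list(DEFAULT_PREDICTORS)
    rng = np.random.default_rng([seed, 2])
    targets = []
    manifest = {"seed": seed, "targets": [], "predictors":
                [dataclasses.asdict(s) for s in specs]}
    for ti in range(n_targets):
        t_seed = int(rng.integers(0, 2 ** 31 - 1))
        t_rng = np.random.default_rng([t_seed, 3])
        n_res = int(t_rng.integers(n_res_range[0], n_res_range[1] + 1))
        sg = space_groups[ti % len(space_groups)]
        d_min = float(t_rng.uniform(*d_min_range))
        target = make_target(n_res, n_copies=1, space_group=sg, seed=t_seed)
        refl = simulate_amplitudes(target, d_min=d_min, noise_frac=noise_frac,
                                   seed=t_seed)
        chain = target.chain_model("A")
        # baseline: a degraded template available without modeling
        baseline_profile = ErrorProfile.uniform(chain, 0.8)
        baseline, _ = perturb_model(chain, baseline_profile, completeness=0.95,
                                    seed=t_seed + 1, error_mode="template_b")
        predictions = {}
        for pi, spec in enumerate(specs):
            profile = spec.make_profile(chain)
            p_seed = t_seed + 100 + pi
            pred, sigma_atom = perturb_model(
                chain, profile, completeness=spec.completeness, seed=p_seed,
                error_mode=spec.error_mode, error_scale=spec.error_scale)
            predictions[spec.name] = {
                "model": pred, "true_sigma_atom": sigma_atom,
                "profile": profile, "seed": p_seed,
            }
        entry = {"id": f"T{ti:03d}", "model": target, "reflections": refl,
                 "baseline": baseline, "predictions": predictions,
                 "n_res": n_res, "space_group": sg, "d_min": d_min,
                 "seed": t_seed}
        targets.append(entry)
        manifest["targets"].append({
            "id": entry["id"], "seed": t_seed, "n_res": n_res,
            "space_group": sg, "d_min": d_min, "noise_frac": noise_frac,
            "predictions": {name: {
                "seed": p["seed"],
                "profile": {"generator": p["profile"].generator,
                            "params": p["profile"].params},
                "true_sigma_per_residue": p["profile"].sigma.tolist(),
            } for name, p in predictions.items()}})
    bench = {"targets": targets, "manifest": manifest, "specs": specs}
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _write_benchmark(bench: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for entry in bench["targets"]:
        tdir = out_dir / entry["id"]
        tdir.mkdir(exist_ok=True)
        write_model(entry["model"], tdir / "target.pdb")
        write_model(entry["baseline"], tdir / "baseline.pdb")
        write_reflections(entry["reflections"], tdir / "reflections.hkl")
        for name, p in entry["predictions"].items():
            write_model(p["model"], tdir / f"pred_{name}.pdb")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bench["manifest"], fh, indent=1)


def score_benchmark(bench: dict, schemes=("original", "rms", "constant"),
                    config=None, include_baseline: bool = True):
    """Score every prediction of a benchmark under each B-factor scheme.

    Returns an :class:`mrllg.score.EvaluationTable`.  For the 'rms' and
    'rms_no3' schemes the submitted B column is *interpreted* as error
    estimates whatever the predictor actually put there — exactly the
    evaluation situation the schemes exist to resolve.  Baseline and
    unpredicted-parts LLGs are recorded per target for I scores.
    """
    from .config import RunConfig
    from .refine import quick_llg
    from .score import EvaluationTable
    from .weighting import BScheme

    cfg = config or RunConfig(rigid_body=False, compute_gdt=False,
                              base_b=20.0)
    rows, baseline_llg, unpredicted_llg = [], {}, {}
    for entry in bench["targets"]:
        context = prep.analyze_target(entry["model"])
        refl = entry["reflections"]
        if include_baseline:
            rec = quick_llg(entry["baseline"], context, refl,
                            BScheme("constant", cfg.constant_b), cfg)
            baseline_llg[entry["id"]] = rec.llg
            unpredicted_llg[entry["id"]] = 0.0  # no unpredicted extras
        for name, p in entry["predictions"].items():
            for kind in schemes:
                model = p["model"].copy()
                if kind in ("rms", "rms_no3"):
                    model.b_column_meaning = "error_estimate"
                elif model.b_column_meaning == "error_estimate":
                    model.b_column_meaning = "unknown"
                rec = quick_llg(model, context, refl, BScheme(kind,
                                cfg.constant_b), cfg)
                rows.append({"target": entry["id"], "predictor": name,
                             "prediction": f"{name}_1", "scheme": kind,
                             "llg": rec.llg, "valid": rec.valid,
                             "vrms": rec.vrms, "gdt_ts": rec.gdt_ts,
                             "f_p": rec.f_p})
    return EvaluationTable.from_records(rows, baseline_llg, unpredicted_llg)
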