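"""Maximization of the LLG over vrms, overall B and rigid-body parameters.

The effective coordinate error (vrms) is refined by bounded local
optimization from several starting values, because the LLG surface over
vrms is occasionally multimodal; a restart spread above tolerance flags the
pathology rather than silently returning a local maximum.  Rigid-body
refinement perturbs each chain (rotation about its centroid, bounded, plus
a bounded translation) by quasi-Newton ascent with numeric gradients,
alternating with vrms and overall-B refinement.

``quick_llg`` wires the full protocol: superpose -> trim -> apply B
scheme -> reconstitute -> structure factors -> normalize -> refine ->
score record.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.transform import Rotation

from . import prep, sfcalc, weighting
from .config import RunConfig
from .iohub import AtomicModel, ReflectionSet, ScoreRecord, TargetContext, ValidationError
from .likelihood import SigmaAParams, llg

__all__ = [
    "RefinementResult",
    "refine_vrms",
    "refine_overall_b",
    "refine_rigid_body",
    "quick_llg",
]


@dataclasses.dataclass
class RefinementResult:
    vrms: float
    overall_b: float
    per_chain: list          # [(rotvec deg (3,), translation (3,))]
    llg: float
    n_restarts_used: int
    converged: bool


def multi_start_maximize(fun, starts, bounds, restart_tol: float = 0.01):
    """Bounded 1-D maximization of ``fun`` polished from several starts.

    Each start is refined by a local bounded quasi-Newton ascent; the best
    polished point wins.  Returns (x*, f*, converged) where ``converged``
    is False when the polished restarts disagree by more than
    ``restart_tol`` relative — the signature of a multimodal surface, where
    a single start can terminate on a minor maximum.
    """
    results = []
    for x0 in starts:
        res = minimize(lambda x: -fun(float(x[0])),
                       x0=[float(np.clip(x0, *bounds))], bounds=[bounds],
                       method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-10})
        results.append((float(res.x[0]), -float(res.fun)))
    best_x, best_f = max(results, key=lambda r: r[1])
    spread = max(r[1] for r in results) - min(r[1] for r in results)
    converged = spread <= restart_tol * max(abs(best_f), 1.0)
    return best_x, best_f, converged


def refine_vrms(Eobs, Ecalc, s, f_p, centric_flags,
                starts=(0.4, 0.8, 1.5), bounds=(0.01, 3.0),
                restart_tol: float = 0.01):
    """Maximize the LLG over vrms from several starting values.

    Returns (vrms*, LLG*, n_restarts_used, converged); ``converged`` is
    False when the restarts disagree by more than ``restart_tol`` relative
    LLG after polishing, which flags a multimodal surface.
    """
    Eobs = np.asarray(Eobs, dtype=float)
    if Eobs.size == 0:
        raise ValidationError("no reflections to refine against")

    def f(v):
        return llg(Eobs, Ecalc, s, SigmaAParams(v, f_p), centric_flags)

    best_v, best_llg, converged = multi_start_maximize(
        f, starts, bounds, restart_tol)
    # The sigmaA family contains the Wilson null as the vrms -> infinity
    # limit (LLG -> 0), which the bounded search cannot reach.  A model
    # whose bounded optimum is below the null carries no usable signal, so
    # the supremum over the closed family is 0 at effectively infinite
    # coordinate error.
    if best_llg < 0.0:
        return bounds[1], 0.0, len(starts), converged
    return best_v, best_llg, len(starts), converged


def refine_overall_b(Eobs, Fcalc_abs, reflections, bins, f_p, centric_flags,
                     vrms, bounds=(-30.0, 100.0), flat_tol: float = 0.5):
    """Maximize the LLG over a uniform B offset applied to the model.

    The offset damps the calculated amplitudes by exp(-dB s^2/4) relative
    to bin means held fixed from the starting model.  Because per-bin
    E-normalization absorbs any uniform B change almost completely, the
    surface is typically flat; in that case 0 is returned with
    ``converged`` False (the degenerate contract).  Returns
    (dB, LLG at dB, converged).
    """
    s = reflections.s
    s2 = s * s
    means0 = sfcalc.bin_means(Fcalc_abs, reflections, bins)
    params = SigmaAParams(vrms, f_p)

    def score(db):
        damped = Fcalc_abs * np.exp(-0.25 * db * s2)
        Ec = sfcalc.normalize(damped, reflections, bins, means=means0)
        return llg(Eobs, Ec, s, params, centric_flags)

    probe = [score(bounds[0]), score(0.0), score(bounds[1])]
    if max(probe) - min(probe) < flat_tol:
        return 0.0, probe[1], False
    res = minimize_scalar(lambda db: -score(db), bounds=bounds, method="bounded",
                          options={"xatol": 0.1})
    db = float(res.x)
    best = -float(res.fun)
    if best < probe[1]:  # optimizer never returns a worse point than the start
        return 0.0, probe[1], True
    return db, best, True


def _chain_params_apply(model: AtomicModel, chain_ids, params: np.ndarray,
                        centroids) -> AtomicModel:
    """Apply per-chain axis-angle (radians) + translation parameters."""
    out = model.copy()
    for i, cid in enumerate(chain_ids):
        rotvec = params[6 * i: 6 * i + 3]
        trans = params[6 * i + 3: 6 * i + 6]
        mask = model.chain == cid
        R = Rotation.from_rotvec(rotvec).as_matrix()
        c = centroids[i]
        out.xyz[mask] = (model.xyz[mask] - c) @ R.T + c + trans
    return out


def refine_rigid_body(context_model: AtomicModel, reflections: ReflectionSet,
                      f_p: float, config: RunConfig | None = None):
    """Alternate rigid-body, vrms and overall-B refinement of a model.

    Each chain gets a bounded rotation about its centroid (axis-angle,
    +-rb_rot_bound_deg) and a bounded translation (+-rb_trans_bound A),
    optimized per chain by L-BFGS-B with numeric gradients; vrms and the
    overall B offset are re-refined after each rigid-body pass.  Iterates
    until the LLG improves by less than ``llg_tol`` or ``rb_max_cycles`` is
    reached.  The LLG never decreases across cycles.
    """
    cfg = config or RunConfig()
    bins = sfcalc.make_bins(reflections, cfg.n_bins, cfg.min_per_bin)
    Eobs = sfcalc.normalize(reflections.f, reflections, bins)
    s = reflections.s
    centric = reflections.centric
    chain_ids = context_model.chains()
    centroids = [context_model.xyz[context_model.chain == c].mean(axis=0)
                 for c in chain_ids]
    rot_bound = np.deg2rad(cfg.rb_rot_bound_deg)
    nchain = len(chain_ids)
    params = np.zeros(6 * nchain)
    bounds = ([(-rot_bound, rot_bound)] * 3 + [(-cfg.rb_trans_bound,
                                                cfg.rb_trans_bound)] * 3) * nchain

    # the inner search runs on a resolution-stratified subsample of
    # reflections (the argmax is insensitive to this); reported LLG values
    # always come from the full set
    max_sub = 1200
    if reflections.n_reflections > max_sub:
        step = int(np.ceil(reflections.n_reflections / max_sub))
        sub_mask = np.zeros(reflections.n_reflections, dtype=bool)
        sub_mask[np.argsort(reflections.d, kind="stable")[::step]] = True
        sub = reflections.subset(sub_mask)
    else:
        sub = reflections
    bins_sub = sfcalc.make_bins(sub, cfg.n_bins, cfg.min_per_bin)
    Eobs_sub = sfcalc.normalize(sub.f, sub, bins_sub)

    def ecalc_for(p, refl=reflections, b=bins):
        model = _chain_params_apply(context_model, chain_ids, p, centroids)
        F = np.abs(sfcalc.calc_sf(model, refl))
        return sfcalc.normalize(F, refl, b)

    vrms, best_llg, n_restarts, conv = refine_vrms(
        Eobs, ecalc_for(params), s, f_p, centric,
        starts=cfg.vrms_starts, bounds=cfg.vrms_bounds,
        restart_tol=cfg.restart_tol)
    overall_b = 0.0
    for _cycle in range(cfg.rb_max_cycles):
        llg_start = best_llg
        params_start = params.copy()
        # rigid-body pass, one chain at a time
        for i in range(nchain):
            sl = slice(6 * i, 6 * i + 6)
            sap = SigmaAParams(vrms, f_p)

            def neg(subp):
                p = params.copy()
                p[sl] = subp
                val = llg(Eobs_sub, ecalc_for(p, sub, bins_sub), sub.s, sap,
                          sub.centric)
                return -val if np.isfinite(val) else 1e12

            res = minimize(neg, x0=params[sl], bounds=bounds[sl],
                           method="L-BFGS-B",
                           options={"ftol": 1e-9, "eps": 1e-4, "maxiter": 40})
            trial = params.copy()
            trial[sl] = res.x
            if llg(Eobs, ecalc_for(trial), s, sap, centric) > best_llg:
                params[sl] = res.x
        Ec = ecalc_for(params)
        vrms, best_llg, n_restarts, conv = refine_vrms(
            Eobs, Ec, s, f_p, centric, starts=cfg.vrms_starts,
            bounds=cfg.vrms_bounds, restart_tol=cfg.restart_tol)
        model_now = _chain_params_apply(context_model, chain_ids, params, centroids)
        Fabs = np.abs(sfcalc.calc_sf(model_now, reflections))
        db, llg_db, _ = refine_overall_b(
            Eobs, Fabs, reflections, bins, f_p, centric, vrms,
            bounds=cfg.overall_b_bounds, flat_tol=cfg.overall_b_flat_tol)
        if llg_db > best_llg:
            overall_b, best_llg = db, llg_db
        if (best_llg - llg_start < cfg.llg_tol
                or np.max(np.abs(params - params_start)) < 1e-4):
            break
    per_chain = [(np.rad2deg(params[6 * i:6 * i + 3]).tolist(),
                  params[6 * i + 3:6 * i + 6].tolist()) for i in range(nchain)]
    return RefinementResult(vrms=vrms, overall_b=overall_b, per_chain=per_chain,
                            llg=best_llg, n_restarts_used=n_restarts,
                            converged=conv)


def quick_llg(prediction: AtomicModel, context: TargetContext,
              reflections: ReflectionSet, scheme: weighting.BScheme,
              config: RunConfig | None = None) -> ScoreRecord:
    """Score one prediction against one target: the full quick-LLG protocol.

    Superposes the prediction on the reference chain, trims the variable
    parts, applies the B-factor scheme, reconstitutes the asymmetric unit,
    computes and normalizes structure factors, refines (rigid body if
    enabled, vrms, overall B) and returns a ScoreRecord.  A prediction that
    cannot be superposed within ``max_superpose_rmsd`` is outside the
    convergence radius of refinement, so the record is flagged invalid
    rather than reported as a meaningful score.
    """
    cfg = config or RunConfig()

    def invalid(reason):
        return ScoreRecord(llg=0.0, vrms=float("nan"), overall_b=0.0, f_p=0.0,
                           gdt_ts=0.0, scheme=scheme.kind, valid=False,
                           invalid_reason=reason)

    try:
        R, t, rmsd = prep.superpose(prediction, context.reference_chain)
    except ValidationError as exc:
        return invalid(f"superposition failed: {exc}")
    if rmsd > cfg.max_superpose_rmsd:
        return invalid(f"superposition rmsd {rmsd:.1f} A exceeds "
                       f"{cfg.max_superpose_rmsd} A (out of convergence radius)")
    placed = prediction.transformed(R, t)
    placed.cell = context.cell
    placed.space_group = context.space_group
    if cfg.compute_gdt:
        try:
            gdt = prep.gdt_ts(placed, context.reference_chain)
        except ValidationError:
            gdt = float("nan")
    else:
        gdt = float("nan")
    try:
        trimmed = prep.trim(placed, context)
    except ValidationError as exc:
        return invalid(str(exc))
    completeness = (len(set(trimmed.resnum.tolist()))
                    / max(len(context.trim_selection), 1))
    base_b = cfg.base_b
    if base_b is None:
        base_b = sfcalc.wilson_b(reflections, context.reference_chain)
    try:
        weighted = weighting.apply_scheme(trimmed, scheme, base_b=base_b,
                                          b_min=cfg.b_min_clamp)
    except ValidationError as exc:
        return invalid(str(exc))
    asu = prep.reconstitute(weighted, context)
    f_p = sfcalc.fraction_scattering(asu, context)
    f_p = max(f_p, 1e-6)
    if cfg.rigid_body:
        result = refine_rigid_body(asu, reflections, f_p, cfg)
        rb_rot = max(float(np.linalg.norm(r)) for r, _ in result.per_chain)
        rb_trans = max(float(np.linalg.norm(tr)) for _, tr in result.per_chain)
    else:
        bins = sfcalc.make_bins(reflections, cfg.n_bins, cfg.min_per_bin)
        Eobs = sfcalc.normalize(reflections.f, reflections, bins)
        Fabs = np.abs(sfcalc.calc_sf(asu, reflections))
        Ec = sfcalc.normalize(Fabs, reflections, bins)
        vrms, best_llg, n_restarts, conv = refine_vrms(
            Eobs, Ec, reflections.s, f_p, reflections.centric,
            starts=cfg.vrms_starts, bounds=cfg.vrms_bounds,
            restart_tol=cfg.restart_tol)
        db, llg_db, _ = refine_overall_b(
            Eobs, Fabs, reflections, bins, f_p, reflections.centric, vrms,
            bounds=cfg.overall_b_bounds, flat_tol=cfg.overall_b_flat_tol)
        best_llg = max(best_llg, llg_db)
        result = RefinementResult(vrms=vrms, overall_b=db, per_chain=[],
                                  llg=best_llg, n_restarts_used=n_restarts,
                                  converged=conv)
        rb_rot = rb_trans = 0.0
    return ScoreRecord(
        llg=result.llg, vrms=result.vrms, overall_b=result.overall_b,
        f_p=f_p, gdt_ts=gdt, scheme=scheme.kind, valid=True,
        n_restarts_used=result.n_restarts_used,
        rb_rotation_deg=rb_rot, rb_translation=rb_trans,
        completeness=completeness)
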