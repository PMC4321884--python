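"""Core crystallographic data types and file I/O.

Atomic models are read from PDB/mmCIF and held as flat numpy arrays in
orthogonal angstrom coordinates; reflection data are read from mmCIF
``_refln`` loops or whitespace ``h k l F [sigF]`` text and reduced to the
asymmetric unit of reciprocal space with Friedel mates merged.  Space-group
operations (centric flags, epsilon factors, ASU mapping) come from gemmi.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomicModel",
    "ReflectionSet",
    "TargetContext",
    "ScoreRecord",
    "SUPPORTED_SPACE_GROUPS",
    "get_space_group",
    "read_model",
    "write_model",
    "read_reflections",
    "build_reflection_set",
]

#: Space groups this package supports (synthetic benchmarks and toy cases).
SUPPORTED_SPACE_GROUPS = ("P 1", "P 1 21 1", "P 21 21 21")

_SG_ALIASES = {
    "P1": "P 1",
    "P 1": "P 1",
    "P21": "P 1 21 1",
    "P 21": "P 1 21 1",
    "P 1 21 1": "P 1 21 1",
    "P212121": "P 21 21 21",
    "P 21 21 21": "P 21 21 21",
}

B_COLUMN_MEANINGS = ("b_factor", "error_estimate", "unknown")


class FormatError(ValueError):
    """Unparseable or unsupported input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


def get_space_group(symbol: str) -> gemmi.SpaceGroup:
    """Resolve a space-group symbol from the supported set.

    Raises
    ------
    ValidationError
        If the symbol does not name one of the supported groups.
    """
    key = symbol.strip()
    hm = _SG_ALIASES.get(key) or _SG_ALIASES.get(key.upper().replace(" ", ""))
    if hm is None:
        raise ValidationError(
            f"unsupported space group {symbol!r}; supported: {SUPPORTED_SPACE_GROUPS}"
        )
    return gemmi.SpaceGroup(hm)


def _unit_cell(cell) -> gemmi.UnitCell:
    if isinstance(cell, gemmi.UnitCell):
        return cell
    return gemmi.UnitCell(*cell)


@dataclasses.dataclass
class AtomicModel:
    """A flat atomic model in orthogonal angstrom coordinates.

    The ``b`` column is interpreted according to ``b_column_meaning``:
    isotropic B factors (A^2), per-atom expected positional errors |dr| (A),
    or unknown (numbers of unstated meaning, as submitted by predictors).
    """

    element: np.ndarray  # (n,) str
    xyz: np.ndarray      # (n, 3) float, orthogonal A
    b: np.ndarray        # (n,) float
    occ: np.ndarray      # (n,) float in [0, 1]
    chain: np.ndarray    # (n,) str
    resnum: np.ndarray   # (n,) int
    resname: np.ndarray  # (n,) str
    atomname: np.ndarray  # (n,) str
    cell: tuple          # (a, b, c, alpha, beta, gamma)
    space_group: str
    b_column_meaning: str = "unknown"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = self.xyz.shape[0]
        self.element = np.asarray(self.element, dtype="U2")
        self.b = np.asarray(self.b, dtype=float)
        self.occ = np.asarray(self.occ, dtype=float)
        self.chain = np.asarray(self.chain, dtype="U4")
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype="U4")
        self.atomname = np.asarray(self.atomname, dtype="U5")
        for name in ("element", "b", "occ", "chain", "resnum", "resname", "atomname"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"field {name} length mismatch with coordinates")
        self.cell = tuple(float(v) for v in self.cell)
        if self.b_column_meaning not in B_COLUMN_MEANINGS:
            raise ValidationError(f"bad b_column_meaning {self.b_column_meaning!r}")
        self.validate()

    def validate(self):
        a, b_, c, al, be, ga = self.cell
        if min(a, b_, c) <= 0:
            raise ValidationError("cell lengths must be positive")
        if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
            raise ValidationError("cell angles must be in (0, 180) degrees")
        if self.n_atoms and self.b.min() < 0:
            raise ValidationError("negative values in the B column are rejected")
        if self.n_atoms and (self.occ.min() < 0 or self.occ.max() > 1):
            raise ValidationError("occupancies must lie in [0, 1]")
        get_space_group(self.space_group)

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return _unit_cell(self.cell)

    def frac_coords(self) -> np.ndarray:
        """Fractional coordinates, (n, 3)."""
        m = np.array(self.gemmi_cell.frac.mat.tolist())
        return self.xyz @ m.T

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            element=self.element.copy(), xyz=self.xyz.copy(), b=self.b.copy(),
            occ=self.occ.copy(), chain=self.chain.copy(), resnum=self.resnum.copy(),
            resname=self.resname.copy(), atomname=self.atomname.copy(),
            cell=self.cell, space_group=self.space_group,
            b_column_meaning=self.b_column_meaning,
        )

    def select(self, mask) -> "AtomicModel":
        mask = np.asarray(mask)
        return AtomicModel(
            element=self.element[mask], xyz=self.xyz[mask], b=self.b[mask],
            occ=self.occ[mask], chain=self.chain[mask], resnum=self.resnum[mask],
            resname=self.resname[mask], atomname=self.atomname[mask],
            cell=self.cell, space_group=self.space_group,
            b_column_meaning=self.b_column_meaning,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        """Apply ``x -> R x + t`` (orthogonal coordinates) to all atoms."""
        out = self.copy()
        out.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def ca_dict(self) -> dict:
        """Map residue number -> CA position for the model's first chain only
        if unique, else over all atoms named CA (last wins is prevented by
        taking the first occurrence)."""
        out = {}
        for i in np.flatnonzero(self.atomname == "CA"):
            key = (str(self.chain[i]), int(self.resnum[i]))
            out.setdefault(key, self.xyz[i])
        return out

    def chains(self) -> list:
        """Chain ids in order of first appearance."""
        seen, order = set(), []
        for c in self.chain:
            if c not in seen:
                seen.add(c)
                order.append(str(c))
        return order

    def chain_model(self, chain_id: str) -> "AtomicModel":
        return self.select(self.chain == chain_id)


@dataclasses.dataclass
class ReflectionSet:
    """Symmetry-unique reflections with amplitudes.

    One entry per reflection in the reciprocal-space asymmetric unit,
    Friedel mates merged.  ``d`` is resolution in angstroms, ``centric``
    marks phase-restricted reflections and ``epsilon`` is the multiplicity
    factor used in normalization.
    """

    hkl: np.ndarray       # (n, 3) int
    f: np.ndarray         # (n,) float, amplitude >= 0
    sigf: np.ndarray      # (n,) float or nan
    d: np.ndarray         # (n,) float, A
    centric: np.ndarray   # (n,) bool
    epsilon: np.ndarray   # (n,) int
    cell: tuple
    space_group: str

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float)
        self.sigf = np.asarray(self.sigf, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.centric = np.asarray(self.centric, dtype=bool)
        self.epsilon = np.asarray(self.epsilon, dtype=int)
        self.cell = tuple(float(v) for v in self.cell)
        if self.n_reflections and self.f.min() < 0:
            raise ValidationError("negative amplitudes are rejected")

    @property
    def n_reflections(self) -> int:
        return self.hkl.shape[0]

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    @property
    def s(self) -> np.ndarray:
        """Reciprocal resolution s = 1/d (A^-1)."""
        return 1.0 / self.d

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return _unit_cell(self.cell)

    def replace_f(self, f: np.ndarray) -> "ReflectionSet":
        out = dataclasses.replace(self, f=np.asarray(f, dtype=float))
        return out

    def subset(self, mask) -> "ReflectionSet":
        mask = np.asarray(mask)
        return ReflectionSet(hkl=self.hkl[mask], f=self.f[mask],
                             sigf=self.sigf[mask], d=self.d[mask],
                             centric=self.centric[mask],
                             epsilon=self.epsilon[mask],
                             cell=self.cell, space_group=self.space_group)


@dataclasses.dataclass
class TargetContext:
    """Analyzed asymmetric unit of a target structure.

    ``reference_chain`` is the chain every prediction is superposed on;
    ``copy_transforms`` maps it onto each copy in the ASU (first transform is
    the identity); ``trim_selection`` lists residue numbers retained after
    excluding conformationally variable parts; ``extra_components`` holds ASU
    contents that are not part of the predicted entity.
    """

    reference_chain: AtomicModel
    copy_transforms: list  # [(R 3x3, t 3)]
    trim_selection: set    # residue numbers (ints)
    extra_components: AtomicModel
    cell: tuple
    space_group: str

    def __post_init__(self):
        if not self.copy_transforms:
            raise ValidationError("copy_transforms must be non-empty")
        r0, t0 = self.copy_transforms[0]
        if not (np.allclose(r0, np.eye(3), atol=1e-8) and np.allclose(t0, 0, atol=1e-8)):
            raise ValidationError("first copy transform must be the identity")
        residues = set(int(r) for r in self.reference_chain.resnum)
        if not set(self.trim_selection) <= residues:
            raise ValidationError("trim_selection must be a subset of reference residues")


@dataclasses.dataclass
class ScoreRecord:
    """Result of one quick-LLG scoring of a (prediction, B-scheme) pair."""

    llg: float
    vrms: float
    overall_b: float
    f_p: float
    gdt_ts: float
    scheme: str
    valid: bool = True
    n_restarts_used: int = 0
    rb_rotation_deg: float = 0.0
    rb_translation: float = 0.0
    completeness: float = 1.0
    invalid_reason: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# model I/O


def _structure_to_model(st: gemmi.Structure, b_column_meaning: str) -> AtomicModel:
    st.setup_entities()
    elements, xyz, bvals, occ, chains, resnums, resnames, atomnames = (
        [], [], [], [], [], [], [], [])
    model = st[0]
    for ch in model:
        for res in ch:
            seen_names = set()
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                # keep only the first altloc of each atom name
                if atom.name in seen_names:
                    continue
                seen_names.add(atom.name)
                if atom.occ <= 0:
                    continue
                elements.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                bvals.append(atom.b_iso)
                occ.append(min(atom.occ, 1.0))
                chains.append(ch.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atomnames.append(atom.name)
    if not elements:
        raise ValidationError("model contains no atoms after filtering")
    cell = st.cell
    sg = st.spacegroup_hm or "P 1"
    return AtomicModel(
        element=elements, xyz=xyz, b=bvals, occ=occ, chain=chains,
        resnum=resnums, resname=resnames, atomname=atomnames,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        space_group=sg, b_column_meaning=b_column_meaning,
    )


def read_model(path, b_column_meaning: str = "unknown") -> AtomicModel:
    """Read a PDB or mmCIF coordinate file.

    Hydrogens, zero-occupancy atoms and alternate locations beyond the first
    are dropped.  ``b_column_meaning`` states how the numbers in the B-factor
    column are to be interpreted; it is never guessed from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if b_column_meaning not in B_COLUMN_MEANINGS:
        raise ValidationError(f"bad b_column_meaning {b_column_meaning!r}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return _structure_to_model(st, b_column_meaning)


def _model_to_structure(model: AtomicModel) -> gemmi.Structure:
    # gemmi containers copy on add_*, so children are filled before being
    # added to their parents
    groups: dict = {}
    for i in range(model.n_atoms):
        cid = str(model.chain[i])
        key = (int(model.resnum[i]), str(model.resname[i]))
        groups.setdefault(cid, {}).setdefault(key, []).append(i)
    st = gemmi.Structure()
    st.cell = model.gemmi_cell
    st.spacegroup_hm = get_space_group(model.space_group).hm
    md = gemmi.Model("1")
    for cid, residues in groups.items():
        chain = gemmi.Chain(cid)
        for (num, name), idxs in residues.items():
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(num, " ")
            for i in idxs:
                atom = gemmi.Atom()
                atom.name = str(model.atomname[i])
                atom.element = gemmi.Element(str(model.element[i]))
                atom.pos = gemmi.Position(*model.xyz[i])
                atom.b_iso = float(model.b[i])
                atom.occ = float(model.occ[i])
                res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    return st


def write_model(model: AtomicModel, path) -> None:
    """Write a model as a fixed-column PDB file (positions to 3 decimals,
    B factors to 2)."""
    if model.n_atoms == 0:
        raise ValidationError("refusing to write an empty model")
    st = _model_to_structure(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# reflection I/O


def _annotate(hkl: np.ndarray, cell, sg: gemmi.SpaceGroup):
    """d-spacings, centric flags and epsilon factors for an index array."""
    uc = _unit_cell(cell)
    ops = sg.operations()
    d = np.array([uc.calculate_d(list(map(int, h))) for h in hkl])
    centric = np.array([ops.is_reflection_centric(list(map(int, h))) for h in hkl],
                       dtype=bool)
    epsilon = np.array([ops.epsilon_factor(list(map(int, h))) for h in hkl], dtype=int)
    return d, centric, epsilon


def build_reflection_set(hkl, f, sigf, cell, space_group) -> ReflectionSet:
    """Reduce raw (hkl, F) data to a merged asymmetric-unit ReflectionSet.

    Symmetry-equivalent observations (including Friedel mates) are mapped to
    a canonical ASU index and merged by averaging; systematic absences are
    dropped.  Entries are sorted lexicographically by (h, k, l).
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    f = np.asarray(f, dtype=float)
    if f.size and f.min() < 0:
        raise ValidationError("negative amplitudes are rejected")
    if sigf is None:
        sigf = np.full(len(f), np.nan)
    sigf = np.asarray(sigf, dtype=float)
    sg = get_space_group(space_group)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    merged = {}
    for (h, k, l), fv, sv in zip(hkl.tolist(), f, sigf):
        if ops.is_systematically_absent([h, k, l]):
            continue
        new_hkl, _ = asu.to_asu([h, k, l], ops)
        merged.setdefault(tuple(new_hkl), []).append((fv, sv))
    if not merged:
        raise ValidationError("no reflections left after reduction")
    keys = sorted(merged)
    hkl_out = np.array(keys, dtype=int)
    f_out = np.array([np.mean([v[0] for v in merged[k]]) for k in keys])
    sig_out = np.array([np.nanmean([v[1] for v in merged[k]]) if
                        np.any(np.isfinite([v[1] for v in merged[k]])) else np.nan
                        for k in keys])
    d, centric, epsilon = _annotate(hkl_out, cell, sg)
    return ReflectionSet(hkl=hkl_out, f=f_out, sigf=sig_out, d=d,
                         centric=centric, epsilon=epsilon,
                         cell=tuple(_unit_cell(cell).parameters),
                         space_group=sg.hm)


def _read_refln_cif(path: Path):
    doc = gemmi.cif.read(str(path))
    for block in doc:
        hs = block.find_loop("_refln.index_h")
        if not hs:
            hs = block.find_loop("_refln_index_h")
        if hs:
            def col(*names):
                for n in names:
                    loop = block.find_loop(n)
                    if loop:
                        return [x for x in loop]
                return None
            h = col("_refln.index_h", "_refln_index_h")
            k = col("_refln.index_k", "_refln_index_k")
            l = col("_refln.index_l", "_refln_index_l")
            fm = col("_refln.F_meas_au", "_refln.F_meas", "_refln_F_meas_au")
            sf = col("_refln.F_meas_sigma_au", "_refln.F_meas_sigma",
                     "_refln_F_meas_sigma_au")
            if fm is None:
                raise FormatError(f"{path}: refln loop lacks F_meas")
            hkl = np.array([h, k, l], dtype=int).T
            f = np.array(fm, dtype=float)
            sigf = np.array(sf, dtype=float) if sf is not None else None
            return hkl, f, sigf
    raise FormatError(f"{path}: no _refln loop found")


def read_reflections(path, cell, space_group) -> ReflectionSet:
    """Read reflections from an mmCIF ``_refln`` loop or plain text.

    The text format is whitespace-separated ``h k l F [sigF]``, one
    reflection per line; ``#`` starts a comment.  A ``# cell a b c al be
    ga`` header comment, when present, is checked against the supplied
    cell and a disagreement beyond 0.1 A / 0.1 deg is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if "_refln" in text:
        hkl, f, sigf = _read_refln_cif(path)
    else:
        rows = []
        for line in text.splitlines():
            stripped = line.strip()
            if stripped.startswith("# space_group"):
                continue
            if stripped.startswith("# cell"):
                file_cell = [float(x) for x in stripped.split()[2:8]]
                given = _unit_cell(cell).parameters
                if any(abs(a - b) > 0.1 for a, b in zip(file_cell, given)):
                    raise ValidationError(
                        f"unit cell in {path} ({file_cell}) disagrees with "
                        f"the supplied cell {tuple(round(v, 3) for v in given)}")
                continue
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise FormatError(f"{path}: bad hkl line {line!r}")
            rows.append([float(x) for x in parts] + [np.nan] * (5 - len(parts)))
        if not rows:
            raise FormatError(f"{path}: no reflections")
        arr = np.array(rows)
        hkl = arr[:, :3].astype(int)
        f = arr[:, 3]
        sigf = arr[:, 4]
    return build_reflection_set(hkl, f, sigf, cell, space_group)


def write_reflections(refl: ReflectionSet, path) -> None:
    """Write a ReflectionSet as plain ``h k l F sigF`` text."""
    with open(path, "w") as fh:
        a, b, c, al, be, ga = refl.cell
        fh.write(f"# cell {a:.4f} {b:.4f} {c:.4f} {al:.3f} {be:.3f} {ga:.3f}\n")
        fh.write(f"# space_group {refl.space_group}\n")
        fh.write("# h k l F sigF\n")
        for i in range(refl.n_reflections):
            h, k, l = refl.hkl[i]
            sig = refl.sigf[i]
            if np.isfinite(sig):
                fh.write(f"{h} {k} {l} {refl.f[i]:.6g} {sig:.6g}\n")
            else:
                fh.write(f"{h} {k} {l} {refl.f[i]:.6g}\n")
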