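"""Cumulative cross-target evaluation of LLG records.

LLG scores computed against different X-ray data sets are not directly
comparable, so predictors are compared through (a) per-target Z scores of
the LLG, averaged per predictor, and (b) improvement (I) scores of each
predictor's best prediction relative to a baseline model, normalized by
the baseline's margin over the unpredicted structure alone:

    Z_structure = (LLG_structure - mean_target) / sd_target
    Z_predictor = mean over structures from the predictor
    I_predictor = mean over targets of
        (LLG_best - LLG_baseline) / (LLG_baseline - LLG_unpredicted)

Predictors that submit genuine coordinate-error estimates are detected
from the Z-score gap between the error-estimate ('rms') B-factor scheme
and the best of the other two schemes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .iohub import ValidationError

__all__ = [
    "EvaluationTable",
    "z_scores",
    "i_score",
    "detect_error_estimates",
    "best_scheme_census",
]

#: deterministic tie precedence for the best-scheme census
_SCHEME_PRECEDENCE = ("original", "rms", "constant", "rms_no3")


@dataclasses.dataclass
class EvaluationTable:
    """Per-(target, predictor, prediction, scheme) LLG records.

    ``records`` is a DataFrame with columns target, predictor, prediction,
    scheme, llg, valid.  ``baseline`` and ``unpredicted`` map target id ->
    LLG of the baseline model and of the unpredicted extra structure alone.
    Invalid records are excluded from every aggregate.
    """

    records: pd.DataFrame
    baseline: dict = dataclasses.field(default_factory=dict)
    unpredicted: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        required = {"target", "predictor", "prediction", "scheme", "llg", "valid"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"records missing columns {sorted(missing)}")
        key = ["target", "predictor", "prediction", "scheme"]
        if self.records.duplicated(subset=key).any():
            raise ValidationError("duplicate (target, predictor, prediction, scheme)")

    @property
    def valid(self) -> pd.DataFrame:
        return self.records[self.records["valid"]]

    @classmethod
    def from_records(cls, rows, baseline=None, unpredicted=None) -> "EvaluationTable":
        return cls(pd.DataFrame(rows), baseline or {}, unpredicted or {})


def z_scores(table: EvaluationTable, scheme: str):
    """Per-structure and per-predictor Z scores for one B-factor scheme.

    Z is computed per target over all valid records of that target and
    scheme, using the population standard deviation; a target where all
    LLGs are equal contributes Z = 0 for every structure.  The per-predictor
    score is the mean of that predictor's structure Z scores.  Returns
    (per_structure DataFrame with a ``z`` column, per_predictor Series).
    """
    df = table.valid
    df = df[df["scheme"] == scheme].copy()
    if df.empty:
        return df.assign(z=[]), pd.Series(dtype=float)

    g = df.groupby("target")["llg"]
    mu = g.transform("mean")
    sd = g.transform("std", ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (df["llg"] - mu) / sd
    df["z"] = np.where((sd > 0) & np.isfinite(sd), z, 0.0)
    per_predictor = df.groupby("predictor")["z"].mean()
    return df, per_predictor


def i_score(table: EvaluationTable, predictor: str, schemes=None) -> float:
    """Improvement score of one predictor (mean over targets attempted).

    For each target, only the predictor's best valid LLG (optionally
    restricted to a subset of schemes) contributes:
    (best - baseline) / (baseline - unpredicted).  Targets with a zero
    denominator are excluded with a warning; targets the predictor skipped
    simply do not contribute.
    """
    df = table.valid
    df = df[df["predictor"] == predictor]
    if schemes is not None:
        df = df[df["scheme"].isin(schemes)]
    contributions = []
    for target, group in df.groupby("target"):
        if target not in table.baseline:
            continue
        base = table.baseline[target]
        unpred = table.unpredicted.get(target, 0.0)
        denom = base - unpred
        if denom == 0:
            warnings.warn(f"target {target}: baseline equals unpredicted LLG, "
                          "excluded from I score")
            continue
        best = group["llg"].max()
        contributions.append((best - base) / denom)
    if not contributions:
        return float("nan")
    return float(np.mean(contributions))


def detect_error_estimates(table: EvaluationTable, min_targets: int = 4,
                           z_cutoff: float = 0.1) -> pd.DataFrame:
    """Flag predictors whose submitted B-column values are real error
    estimates.

    A predictor is flagged iff its mean Z score under the 'rms' scheme
    exceeds the better of the 'original' and 'constant' schemes by at least
    ``z_cutoff`` and it was scored on at least ``min_targets`` targets
    (small samples are excluded as unreliable).  Returns a DataFrame
    indexed by predictor with columns z_original, z_rms, z_constant,
    n_targets, pct_rms_best, flagged.
    """
    z_by_scheme = {}
    for scheme in ("original", "rms", "constant"):
        _, per_pred = z_scores(table, scheme)
        z_by_scheme["z_" + scheme] = per_pred
    out = pd.DataFrame(z_by_scheme)
    df = table.valid
    n_targets = df.groupby("predictor")["target"].nunique()
    out["n_targets"] = n_targets.reindex(out.index).fillna(0).astype(int)
    # frequency with which a predictor's best-scoring record per target
    # came from the rms scheme
    census = best_scheme_census(table, per_predictor=True)
    pct = census.groupby("predictor")["best_scheme"].apply(
        lambda sc: 100.0 * (sc == "rms").mean())
    out["pct_rms_best"] = pct.reindex(out.index)
    gap = out["z_rms"] - out[["z_original", "z_constant"]].max(axis=1)
    out["flagged"] = (gap >= z_cutoff) & (out["n_targets"] >= min_targets)
    out["flagged"] = out["flagged"].fillna(False)
    return out


def best_scheme_census(table: EvaluationTable, per_predictor: bool = False):
    """Which B-factor scheme yields the best record per target.

    With ``per_predictor`` the maximum is taken per (target, predictor)
    pair.  Exact LLG ties are broken by the fixed precedence original >
    rms > constant > rms_no3.  Returns a DataFrame with the winning scheme
    per group (column ``best_scheme``); aggregate counts are available via
    ``.value_counts()``.
    """
    df = table.valid.copy()
    if df.empty:
        raise ValidationError("no valid records")
    prec = {s: i for i, s in enumerate(_SCHEME_PRECEDENCE)}
    df["_prec"] = df["scheme"].map(lambda s: prec.get(s, len(prec)))
    keys = ["target", "predictor"] if per_predictor else ["target"]
    df = df.sort_values(["llg", "_prec"], ascending=[False, True],
                        kind="stable")
    best = df.groupby(keys, as_index=False).first()
    best = best.rename(columns={"scheme": "best_scheme"})
    return best[keys + ["best_scheme", "llg"]]


def improvements_over_baseline(table: EvaluationTable) -> pd.Series:
    """Number of targets, per predictor, where any scheme beat the baseline."""
    df = table.valid
    counts = {}
    for pred, group in df.groupby("predictor"):
        n = 0
        for target, g in group.groupby("target"):
            if target in table.baseline and g["llg"].max() > table.baseline[target]:
                n += 1
        counts[pred] = n
    return pd.Series(counts, dtype=int)
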