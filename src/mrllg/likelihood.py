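"""Log-likelihood gain under the Luzzati/sigmaA error model.

The LLG measures how much better than a random (Wilson) model an atomic
model explains the observed amplitudes.  Observed and calculated
normalized amplitudes (E-values) are linked through the resolution-
dependent correlation

    sigmaA(s) = sqrt(f_p) * exp(-2 pi^2 s^2 vrms^2 / 3),

where f_p is the fraction of the asymmetric-unit scattering covered by the
model and vrms the effective (3-D rms) coordinate error.  Acentric
reflections follow a Rice density, centric ones the Woolfson (folded
normal) density; the Wilson null is obtained at sigmaA = 0, which makes
the LLG of an uninformative model exactly zero.

Note the Luzzati damping equals a Debye-Waller factor exp(-dB s^2/4) with
dB = (8 pi^2 / 3) vrms^2 — inflating every B by that amount smears the
model identically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import i0e

__all__ = [
    "SigmaAParams",
    "sigma_a",
    "loglik_reflection",
    "loglik_wilson",
    "llg",
]


@dataclasses.dataclass
class SigmaAParams:
    """Luzzati error-model parameters: vrms (A, >= 0) and f_p in (0, 1]."""

    vrms: float
    f_p: float = 1.0

    def __post_init__(self):
        if self.vrms < 0:
            raise ValueError("vrms must be >= 0")
        if not (0.0 < self.f_p <= 1.0):
            raise ValueError("f_p must be in (0, 1]")


def sigma_a(s, params: SigmaAParams) -> np.ndarray:
    """sigmaA(s) = sqrt(f_p) exp(-2 pi^2 s^2 vrms^2 / 3)."""
    s = np.asarray(s, dtype=float)
    return np.sqrt(params.f_p) * np.exp(
        -2.0 * np.pi ** 2 * s ** 2 * params.vrms ** 2 / 3.0)


def _log_i0(x: np.ndarray) -> np.ndarray:
    # i0e(x) = exp(-|x|) I0(x): stable for arbitrarily large arguments
    return np.log(i0e(x)) + np.abs(x)


def _log_cosh(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return ax - np.log(2.0) + np.log1p(np.exp(-2.0 * ax))


def loglik_reflection(Eo, Ec, sig_a, centric) -> np.ndarray:
    """Log-density of an observed E given the model E and sigmaA.

    Acentric: Rice density
        p(Eo|Ec) = 2 Eo/(1-sA^2) exp(-(Eo^2 + sA^2 Ec^2)/(1-sA^2))
                   I0(2 Eo sA Ec/(1-sA^2))
    Centric: Woolfson density
        p(Eo|Ec) = sqrt(2/(pi (1-sA^2))) exp(-(Eo^2 + sA^2 Ec^2)/(2(1-sA^2)))
                   cosh(Eo sA Ec/(1-sA^2))

    All arguments broadcast; sigmaA must satisfy 0 <= sigmaA < 1.
    """
    Eo = np.asarray(Eo, dtype=float)
    Ec = np.asarray(Ec, dtype=float)
    sig_a = np.asarray(sig_a, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    if np.any(sig_a >= 1.0) or np.any(sig_a < 0.0):
        raise ValueError("sigmaA must lie in [0, 1)")
    var = 1.0 - sig_a ** 2
    cross = Eo * sig_a * Ec / var
    with np.errstate(divide="ignore"):
        acen = (np.log(2.0 * Eo / var)
                - (Eo ** 2 + sig_a ** 2 * Ec ** 2) / var
                + _log_i0(2.0 * cross))
        cen = (0.5 * np.log(2.0 / (np.pi * var))
               - (Eo ** 2 + sig_a ** 2 * Ec ** 2) / (2.0 * var)
               + _log_cosh(cross))
    return np.where(centric, cen, acen)


def loglik_wilson(Eo, centric) -> np.ndarray:
    """Wilson (random-model) log-density: the sigmaA = 0 limit."""
    Eo = np.asarray(Eo, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    with np.errstate(divide="ignore"):
        acen = np.log(2.0 * Eo) - Eo ** 2
        cen = 0.5 * np.log(2.0 / np.pi) - Eo ** 2 / 2.0
    return np.where(centric, cen, acen)


def llg(Eobs, Ecalc, s, params, centric_flags) -> float:
    """Total log-likelihood gain over the Wilson null.

    ``params`` is either a :class:`SigmaAParams` (sigmaA evaluated from the
    resolution array ``s``) or a precomputed per-reflection sigmaA array (in
    which case ``s`` may be None).  A model with sigmaA -> 0 everywhere has
    LLG -> 0 by construction.
    """
    Eobs = np.asarray(Eobs, dtype=float)
    Ecalc = np.asarray(Ecalc, dtype=float)
    centric_flags = np.asarray(centric_flags, dtype=bool)
    if Eobs.shape != Ecalc.shape or Eobs.shape != centric_flags.shape:
        raise ValueError("Eobs, Ecalc and centric_flags must be aligned")
    if isinstance(params, SigmaAParams):
        sig_a = sigma_a(np.asarray(s, dtype=float), params)
    else:
        sig_a = np.asarray(params, dtype=float)
        if sig_a.shape != Eobs.shape:
            raise ValueError("per-reflection sigmaA must be aligned with Eobs")
    ll = loglik_reflection(Eobs, Ecalc, sig_a, centric_flags)
    return float(np.sum(ll - loglik_wilson(Eobs, centric_flags)))
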