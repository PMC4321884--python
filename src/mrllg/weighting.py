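"""Conversion of coordinate-error estimates to B-factor weights.

An expected positional error |dr| (absolute scale, angstroms) is turned
into an isotropic B increment

    dB = (8 pi^2 / 3) <|dr|^2>,

the Fourier transform of the assumed Gaussian error distribution.  The
factor of 3 accounts for the 1-D component (parallel to the diffraction
vector) of the 3-D mean-square error; the frequently seen variant without
it (dB = 8 pi^2 <|dr|^2>) over-smears and is provided for comparison.

Four B-factor schemes are supported for scoring a prediction:
``original`` (B column used as-is), ``rms`` (B column read as error
estimates, converted with the factor-of-3 formula), ``rms_no3`` (the
comparison variant), and ``constant``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .iohub import AtomicModel, ValidationError

__all__ = ["BScheme", "SCHEME_KINDS", "error_to_b", "error_to_b_no3", "apply_scheme"]

SCHEME_KINDS = ("original", "rms", "constant", "rms_no3")


@dataclasses.dataclass
class BScheme:
    """Named B-factor scheme; ``constant_value`` applies to kind='constant'."""

    kind: str
    constant_value: float = 20.0

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise ValidationError(f"unknown B scheme {self.kind!r}")


def error_to_b(delta_r) -> np.ndarray:
    """dB = (8 pi^2 / 3) delta_r^2, angstrom^2."""
    delta_r = np.asarray(delta_r, dtype=float)
    if np.any(delta_r < 0):
        raise ValidationError("coordinate errors must be >= 0")
    return (8.0 * np.pi ** 2 / 3.0) * delta_r ** 2


def error_to_b_no3(delta_r) -> np.ndarray:
    """The variant omitting the factor of 3: dB = 8 pi^2 delta_r^2."""
    delta_r = np.asarray(delta_r, dtype=float)
    if np.any(delta_r < 0):
        raise ValidationError("coordinate errors must be >= 0")
    return 8.0 * np.pi ** 2 * delta_r ** 2


def apply_scheme(model: AtomicModel, scheme: BScheme, base_b: float = 20.0,
                 b_min: float = 2.0) -> AtomicModel:
    """Return a copy of *model* with B factors set according to *scheme*.

    For the error-estimate schemes the B column must carry |dr| values
    (``b_column_meaning == 'error_estimate'``); the converted increment is
    added onto ``base_b`` (the error transform fixes only B *differences*
    between confident and unconfident regions — normalization absorbs the
    average).  All resulting B values are clamped to at least ``b_min`` to
    avoid unphysically sharp atoms in the forward model.  The returned
    model's ``b_column_meaning`` is 'b_factor'.
    """
    out = model.copy()
    if scheme.kind == "original":
        pass
    elif scheme.kind == "constant":
        out.b = np.full(model.n_atoms, float(scheme.constant_value))
    elif scheme.kind in ("rms", "rms_no3"):
        if model.b_column_meaning != "error_estimate":
            raise ValidationError(
                f"scheme {scheme.kind!r} needs a model whose B column holds "
                "error estimates (b_column_meaning='error_estimate')")
        conv = error_to_b if scheme.kind == "rms" else error_to_b_no3
        out.b = base_b + conv(model.b)
    out.b = np.maximum(out.b, b_min)
    out.b_column_meaning = "b_factor"
    return out
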