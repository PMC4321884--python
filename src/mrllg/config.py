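"""Run configuration: every tunable of the scoring pipeline in one place.

Serializable to/from YAML; unknown keys are rejected so a typo in a config
file fails loudly.  The effective configuration is echoed into every output
record for provenance.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict
import yaml

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # normalization
    n_bins: int = 20
    min_per_bin: int = 50
    # vrms refinement
    vrms_bounds: tuple[float, float] = (0.01, 3.0)
    vrms_starts: tuple[float, ...] = (0.4, 0.8, 1.5)
    restart_tol: float = 0.01          # relative LLG spread flagging multimodality
    # overall-B refinement
    overall_b_bounds: tuple[float, float] = (-30.0, 100.0)
    overall_b_flat_tol: float = 0.5    # LLG range below which the surface is flat
    # rigid-body refinement
    rigid_body: bool = True
    rb_rot_bound_deg: float = 5.0
    rb_trans_bound: float = 3.0
    rb_max_cycles: int = 10
    llg_tol: float = 0.01
    # target analysis
    trim_threshold: float = 3.0        # A, inter-copy Calpha deviation cutoff
    max_superpose_rmsd: float = 10.0   # A, beyond this the score is invalid
    # B-factor schemes
    base_b: float | None = None        # None -> Wilson B of the data (fallback 20)
    constant_b: float = 20.0
    b_min_clamp: float = 2.0
    # error-estimate scale search is deliberately off by default
    error_scale_factors: tuple[float, ...] = (1.0,)
    compute_gdt: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
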