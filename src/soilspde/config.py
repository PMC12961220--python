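"""Structured pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Run-level settings: cleaning thresholds, mesh heuristics, priors, seeds.

    Outlier site ids are user-supplied: extreme values are identified
    against prior maps by the analyst, then removed programmatically for
    reproducibility.
    """

    outlier_sites: list[str] = field(default_factory=list)
    collinearity_threshold: float = 0.7
    cell_area_km2: float = 6.0
    mesh_fraction: float = 1.0 / 10.0
    cutoff_override: float | None = None
    family: str = "lognormal"
    sigma_prior: tuple[float, float] = (0.5, 0.5)
    range_prior: tuple[float, float] | None = None
    state_prec_prior: tuple[float, float] = (1.0, 5e-5)
    intercept_prior: tuple[float, float] = (0.0, 1e-4)
    fixed_prior: tuple[float, float] = (0.0, 1e-4)
    n_posterior_draws: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for name in ("sigma_prior", "range_prior", "state_prec_prior",
                     "intercept_prior", "fixed_prior"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
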