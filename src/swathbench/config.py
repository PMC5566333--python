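"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All thresholds and generator knobs for one pipeline execution.

    FDR threshold alpha and Storey lambda follow the reference analysis
    (1% consecutive filtering, lambda 0.4); the LLOQ criteria are the
    bioanalytical standards (CV < 20%, S/N > 20, accuracy 80-120%).
    """

    alpha: float = 0.01
    lam: float = 0.4
    cv_max: float = 20.0
    sn_min: float = 20.0
    accuracy_band: tuple[float, float] = (80.0, 120.0)
    completeness_threshold: float = 0.8
    seed: int = 0
    # synthetic-study generator
    n_sites: int = 11
    n_proteins: int = 500
    mean_peptides: float = 8.0
    span_orders: float = 4.5
    absent_fraction: float = 0.5
    dropout: int = 2
    offset_range: tuple[float, float] = (0.5, 2.0)
    subsample_ratio: float = 1.0
    n_iterations: int = 5
    out_dir: str | None = None
    input_peakgroups: str | None = None
    input_sis: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.lam < 1:
            raise ValueError("lambda must be in (0, 1)")
        if not 0 < self.completeness_threshold < 1:
            raise ValueError("completeness threshold must be in (0, 1)")
        if self.cv_max <= 0 or self.sn_min <= 0:
            raise ValueError("cv_max and sn_min must be positive")
        lo, hi = self.accuracy_band
        if not 0 < lo < hi:
            raise ValueError("accuracy band must be an increasing positive pair")
        self.accuracy_band = (float(lo), float(hi))
        self.offset_range = tuple(self.offset_range)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy_band"] = list(self.accuracy_band)
        d["offset_range"] = list(self.offset_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "accuracy_band" in data:
            data["accuracy_band"] = tuple(data["accuracy_band"])
        if "offset_range" in data:
            data["offset_range"] = tuple(data["offset_range"])
        return cls(**data)
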