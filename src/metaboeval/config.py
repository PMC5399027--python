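"""Pipeline configuration: one flat, serialisable record of every threshold."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, with study-standard defaults."""

    seed: int = 0
    input_dir: str | None = None  # None -> simulate
    outdir: str = "results"

    # preprocessing
    background_min_ratio: float = 3.0
    rule80_fraction: float = 0.8
    qc_max_rsd: float = 0.15
    fusion_enabled: bool = False
    fusion_min_correlation: float = 0.9

    # screening
    control_group: str = "C"
    toxin_group: str = "T"
    absence_fraction: float = 0.1
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted_p: bool = True
    spearman_cutoff: float = 0.5

    # deregulation
    pc_variance_target: float = 0.85
    curve_span: float = 0.3
    curve_tol: float = 1e-4
    curve_max_iter: int = 50
    fit_on_healthy_only: bool = False

    # rauc
    rauc_window: tuple = (4, 10)
    rauc_scale: str = "log2"
    rauc_alpha: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            (self.background_min_ratio > 1, "background_min_ratio must exceed 1"),
            (0 < self.rule80_fraction <= 1, "rule80_fraction in (0,1]"),
            (0 < self.qc_max_rsd < 1, "qc_max_rsd in (0,1)"),
            (0 < self.fusion_min_correlation <= 1, "fusion_min_correlation in (0,1]"),
            (0 < self.absence_fraction < 0.5, "absence_fraction in (0,0.5)"),
            (self.vip_threshold >= 0, "vip_threshold must be >= 0"),
            (0 < self.p_threshold < 1, "p_threshold in (0,1)"),
            (0 <= self.spearman_cutoff <= 1, "spearman_cutoff in [0,1]"),
            (0 < self.pc_variance_target <= 1, "pc_variance_target in (0,1]"),
            (0 < self.curve_span <= 1, "curve_span in (0,1]"),
            (self.curve_tol > 0, "curve_tol must be positive"),
            (self.curve_max_iter >= 1, "curve_max_iter must be >= 1"),
            (self.rauc_scale in ("log2", "fc"), "rauc_scale is 'log2' or 'fc'"),
            (0 < self.rauc_alpha < 1, "rauc_alpha in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        self.rauc_window = tuple(self.rauc_window)

    # -- serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rauc_window"] = list(self.rauc_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
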