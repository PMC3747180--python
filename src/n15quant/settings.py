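"""Run settings: the knobs of the quantification pipeline.

Every tolerance the pipeline uses is collected here and can be loaded from
a YAML settings file, mirroring how the original workflow kept mass
tolerance, labeling efficiency and envelope thresholds in a settings panel.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["Settings", "SettingsError"]


class SettingsError(ValueError):
    """Raised when settings violate their invariants."""


@dataclass(frozen=True)
class Settings:
    """Pipeline configuration.

    ppm_tol
        m/z matching window in parts per million (±30 ppm default, the
        database-search tolerance adopted for MS-only pair matching).
    ratio_threshold
        Maximum allowed difference between experimental and theoretical
        adjacent-peak intensity ratios (bounded r-statistic, see quant).
    enrichment
        ¹⁵N fraction of the labeled sample (0.982 default).
    natural_n15
        ¹⁵N fraction of the unlabeled sample (natural abundance).
    grid_lo / grid_hi / grid_step
        Enrichment-estimation search grid (90–100% at 0.1% steps).
    elution_tol_min
        Maximum allowed retention-time difference (minutes) between the
        identification and quantification runs of a peptide.
    min_matched
        Minimum consecutive matched envelope slots, counted through the
        theoretically most intense slot.
    max_peaks
        Envelope truncation length (most intense contiguous peaks).
    uncertainty_low / uncertainty_high
        q-values below/above these bounds are flagged uncertain (low
        signal on one side) and may be read as 0 or 1.
    multimers
        Oligomeric states considered when checking that a protein could
        band in a gel segment (monomer and dimer by default).
    segment_neighborhood
        Allowed gel-segment offset between identification and
        quantification runs.
    max_missed / min_length / max_length
        Digestion settings for library construction.
    label_swap
        Interpret the labels as swapped (¹⁵N-leaf/¹⁴N-root experiment);
        maps every q to 1 − q.
    """

    ppm_tol: float = 30.0
    ratio_threshold: float = 0.05
    enrichment: float = 0.982
    natural_n15: float = 0.00364
    grid_lo: float = 0.90
    grid_hi: float = 1.00
    grid_step: float = 0.001
    elution_tol_min: float = 1.5
    min_matched: int = 3
    max_peaks: int = 8
    uncertainty_low: float = 0.2
    uncertainty_high: float = 0.8
    multimers: tuple[int, ...] = (1, 2)
    segment_neighborhood: int = 1
    max_missed: int = 1
    min_length: int = 5
    max_length: int = 35
    label_swap: bool = False

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise SettingsError("ppm_tol must be > 0")
        if self.ratio_threshold <= 0:
            raise SettingsError("ratio_threshold must be > 0")
        for name in ("enrichment", "natural_n15", "grid_lo", "grid_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SettingsError(f"{name}={v} outside [0, 1]")
        if not self.grid_lo < self.grid_hi:
            raise SettingsError("grid_lo must be < grid_hi")
        if self.grid_step <= 0:
            raise SettingsError("grid_step must be > 0")
        if self.min_matched < 2:
            raise SettingsError("min_matched must be >= 2")
        if self.max_peaks < 2:
            raise SettingsError("max_peaks must be >= 2")
        if not 0 <= self.uncertainty_low < self.uncertainty_high <= 1:
            raise SettingsError("uncertainty bounds must satisfy 0 <= lo < hi <= 1")
        if not self.multimers or any(k < 1 for k in self.multimers):
            raise SettingsError("multimers must be a non-empty set of ints >= 1")
        if self.max_missed < 0 or self.min_length < 1:
            raise SettingsError("invalid digestion bounds")
        if self.min_length > self.max_length:
            raise SettingsError("min_length > max_length")
        object.__setattr__(self, "multimers", tuple(int(k) for k in self.multimers))

    def replace(self, **kwargs) -> "Settings":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["multimers"] = list(self.multimers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Settings":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SettingsError(f"unknown settings keys: {sorted(unknown)}")
        if "multimers" in d:
            d = dict(d, multimers=tuple(d["multimers"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Settings":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SettingsError(f"settings file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
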