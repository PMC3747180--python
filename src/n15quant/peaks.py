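"""Centroided peak-list I/O and extraction of experimental isotope
envelopes around theoretical target masses.

Each spectrum is one MALDI target spot, annotated with the LC fraction it
was collected in and the SDS-gel segment its proteins came from; both
annotations feed the positional consistency filters downstream.  The
canonical on-disk dialect is one tab-separated file per spectrum
(``m/z<TAB>intensity`` lines under a ``#``-prefixed metadata header), one
directory per run; a minimal MGF container is also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import IsotopeEnvelope

__all__ = [
    "PeakList",
    "FractionSchedule",
    "GelModel",
    "ExperimentalEnvelope",
    "SCHEDULE_ID_48",
    "SCHEDULE_QUANT_192",
    "read_peaklist",
    "read_peaklists",
    "write_peaklist",
    "read_mgf",
    "extract_envelope",
    "fraction_time",
    "default_gel_model",
]


class PeakListError(ValueError):
    """Raised for malformed peak-list files or metadata."""


@dataclass(frozen=True)
class FractionSchedule:
    """LC fraction-collection schedule: ``n_fractions`` spots collected from
    ``start_min`` at ``interval_min`` spacing."""

    n_fractions: int
    start_min: float
    interval_min: float

    def time(self, fraction_index: int) -> float:
        """Mid-fraction retention time in minutes."""
        if not 0 <= fraction_index < self.n_fractions:
            raise PeakListError(
                f"fraction index {fraction_index} outside schedule "
                f"0..{self.n_fractions - 1}"
            )
        return self.start_min + (fraction_index + 0.5) * self.interval_min

    def index_for_time(self, minutes: float) -> int:
        """Fraction that a peptide eluting at ``minutes`` lands in (clipped)."""
        idx = int((minutes - self.start_min) / self.interval_min)
        return min(max(idx, 0), self.n_fractions - 1)


#: 48-spot identification-run schedule: 28–61 min at 0.7 min intervals.
SCHEDULE_ID_48 = FractionSchedule(48, 28.0, 0.7)
#: 192-spot quantification-run schedule: 28–56.5 min at 0.15 min intervals.
SCHEDULE_QUANT_192 = FractionSchedule(192, 28.0, 0.15)


def fraction_time(schedule: FractionSchedule, fraction_index: int) -> float:
    """Mid-fraction retention time; comparable across the 48- and 192-spot
    schedules because both are expressed in gradient minutes."""
    return schedule.time(fraction_index)


@dataclass(frozen=True)
class GelModel:
    """Maps SDS-gel segment index → apparent molecular-weight window (kDa).

    Segment 0 is the top of the gel (highest MW).
    """

    windows: tuple[tuple[float, float], ...]

    @property
    def n_segments(self) -> int:
        return len(self.windows)

    def interval(self, segment: int) -> tuple[float, float]:
        if not 0 <= segment < len(self.windows):
            raise PeakListError(
                f"gel segment {segment} outside model 0..{len(self.windows) - 1}"
            )
        return self.windows[segment]

    def segment_for_mass(self, kda: float) -> int:
        """Segment whose window contains ``kda`` (nearest window if outside)."""
        for i, (lo, hi) in enumerate(self.windows):
            if lo <= kda < hi:
                return i
        centers = [0.5 * (lo + hi) for lo, hi in self.windows]
        return int(np.argmin([abs(c - kda) for c in centers]))


def default_gel_model(
    n_segments: int = 36, lo_kda: float = 10.0, hi_kda: float = 260.0
) -> GelModel:
    """A 36-segment gel with log-spaced MW windows from 260 kDa (top) down
    to 10 kDa, emulating the apparent-MW scale of a 12% gel."""
    edges = np.geomspace(hi_kda, lo_kda, n_segments + 1)
    return GelModel(
        windows=tuple((float(edges[i + 1]), float(edges[i])) for i in range(n_segments))
    )


@dataclass
class PeakList:
    """One centroided spectrum with its positional annotations."""

    spectrum_id: str
    run_id: str
    lc_fraction: int
    gel_segment: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise PeakListError(
                f"spectrum {self.spectrum_id}: m/z and intensity length mismatch"
            )
        if np.any(self.intensity < 0):
            raise PeakListError(f"spectrum {self.spectrum_id}: negative intensity")
        if self.lc_fraction < 0 or self.gel_segment < 0:
            raise PeakListError(
                f"spectrum {self.spectrum_id}: negative fraction/segment index"
            )
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spectrum: {peaklist.spectrum_id}\n")
        fh.write(f"# run: {peaklist.run_id}\n")
        fh.write(f"# lc_fraction: {peaklist.lc_fraction}\n")
        fh.write(f"# gel_segment: {peaklist.gel_segment}\n")
        for mz, inten in zip(peaklist.mz, peaklist.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def read_peaklist(path: str | Path) -> PeakList:
    path = Path(path)
    meta: dict[str, str] = {}
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, value = body.split(":", 1)
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PeakListError(f"{path}:{lineno}: expected 'm/z<TAB>intensity'")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError:
                raise PeakListError(f"{path}:{lineno}: non-numeric peak line {line!r}")
    for key in ("spectrum", "run", "lc_fraction", "gel_segment"):
        if key not in meta:
            raise PeakListError(f"{path}: missing metadata field {key!r}")
    return PeakList(
        spectrum_id=meta["spectrum"],
        run_id=meta["run"],
        lc_fraction=int(meta["lc_fraction"]),
        gel_segment=int(meta["gel_segment"]),
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def read_mgf(path: str | Path) -> list[PeakList]:
    """Read a minimal MGF container; TITLE carries the positional tags, e.g.
    ``TITLE=spectrum=s001 run=quant lc_fraction=12 gel_segment=5``."""
    from pyteomics import mgf

    peaklists = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"].get("title", "")
            tags = dict(
                tok.split("=", 1) for tok in title.split() if "=" in tok
            )
            missing = {"spectrum", "run", "lc_fraction", "gel_segment"} - set(tags)
            if missing:
                raise PeakListError(
                    f"{path}: TITLE {title!r} missing tags {sorted(missing)}"
                )
            peaklists.append(
                PeakList(
                    spectrum_id=tags["spectrum"],
                    run_id=tags["run"],
                    lc_fraction=int(tags["lc_fraction"]),
                    gel_segment=int(tags["gel_segment"]),
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                )
            )
    return peaklists


def read_peaklists(source: str | Path) -> list[PeakList]:
    """Load spectra from a directory of per-spectrum TSV files (recursing
    into per-run subdirectories), a single TSV file, or an MGF file."""
    source = Path(source)
    if not source.exists():
        raise PeakListError(f"peak-list source {source} does not exist")
    if source.is_dir():
        files = sorted(source.rglob("*.tsv"))
        if not files:
            raise PeakListError(f"no .tsv peak lists under {source}")
        return [read_peaklist(f) for f in files]
    if source.suffix.lower() == ".mgf":
        return read_mgf(source)
    return [read_peaklist(source)]


@dataclass
class ExperimentalEnvelope:
    """Experimental peaks aligned to the slots of a theoretical envelope.

    ``matched`` marks filled slots; ``peak_indices`` point back into the
    source peak list (−1 for missing slots), enabling overlap detection
    when light and heavy windows compete for the same signal.
    """

    peptide: str
    side: str  # "light" | "heavy"
    spectrum_id: str
    slot_mz: np.ndarray
    theoretical_intensity: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    matched: np.ndarray
    peak_indices: np.ndarray

    @property
    def total_intensity(self) -> float:
        return float(self.intensity[self.matched].sum())

    @property
    def n_matched(self) -> int:
        return int(self.matched.sum())


def _longest_run_through(mask: np.ndarray, index: int) -> int:
    """Length of the run of True values in ``mask`` containing ``index``."""
    if not mask[index]:
        return 0
    lo = index
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = index
    while hi < len(mask) - 1 and mask[hi + 1]:
        hi += 1
    return hi - lo + 1


def extract_envelope(
    peaklist: PeakList,
    theoretical: IsotopeEnvelope,
    ppm_tol: float = 30.0,
    min_matched: int = 3,
    peptide: str = "",
    side: str = "light",
) -> ExperimentalEnvelope | None:
    """Match spectrum peaks to the theoretical envelope slots.

    For each slot the nearest peak within ``ppm_tol`` is taken (ties going
    to the higher intensity).  Returns ``None`` unless at least
    ``min_matched`` consecutive slots are filled in the run containing the
    theoretically most intense slot — absence is a valid outcome, not an
    error.
    """
    if ppm_tol <= 0:
        raise PeakListError("ppm_tol must be > 0")
    n_slots = len(theoretical)
    mz = np.full(n_slots, np.nan)
    intensity = np.zeros(n_slots)
    matched = np.zeros(n_slots, dtype=bool)
    indices = np.full(n_slots, -1, dtype=int)

    for k, slot in enumerate(theoretical.mz):
        tol = slot * ppm_tol * 1e-6
        lo = np.searchsorted(peaklist.mz, slot - tol, side="left")
        hi = np.searchsorted(peaklist.mz, slot + tol, side="right")
        if hi <= lo:
            continue
        cand = np.arange(lo, hi)
        dist = np.abs(peaklist.mz[cand] - slot)
        # nearest peak; on (near-)ties prefer the more intense one
        best_dist = dist.min()
        tied = cand[dist <= best_dist + 1e-12]
        best = tied[np.argmax(peaklist.intensity[tied])]
        mz[k] = peaklist.mz[best]
        intensity[k] = peaklist.intensity[best]
        matched[k] = True
        indices[k] = best

    if _longest_run_through(matched, theoretical.apex_index) < min_matched:
        return None
    return ExperimentalEnvelope(
        peptide=peptide,
        side=side,
        spectrum_id=peaklist.spectrum_id,
        slot_mz=theoretical.mz.copy(),
        theoretical_intensity=theoretical.intensity.copy(),
        mz=mz,
        intensity=intensity,
        matched=matched,
        peak_indices=indices,
    )
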