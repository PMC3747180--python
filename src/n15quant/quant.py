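"""Envelope quality control, q-value computation, labeling-efficiency
estimation, positional consistency filters, and aggregation.

The q-value of a peptide pair is the heavy-isotope fraction of the total
signal, ``q = ΣI(¹⁵N) / (ΣI(¹⁴N) + ΣI(¹⁵N))``: 0.5 means equal abundance in
the two samples, 0.8 means the heavy sample carries four times more of the
peptide, and values outside (0.2, 0.8) are flagged uncertain because one
side of the pair is weak.  Because pair matching in the quantification run
is mass-only, false positives are weeded out by (1) an envelope-shape test
comparing adjacent-peak intensity ratios against theory, and (2) positional
consistency: the match must come from a gel segment where the parent
protein (as monomer or dimer) would band and from an LC elution time close
to where the peptide eluted in the identification run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    ElementComposition,
    IsotopeEnvelope,
    composition_of,
    isotope_envelope,
)
from .peaks import (
    ExperimentalEnvelope,
    FractionSchedule,
    GelModel,
    PeakList,
    SCHEDULE_ID_48,
    SCHEDULE_QUANT_192,
    extract_envelope,
)
from .settings import Settings

__all__ = [
    "QualityVerdict",
    "PairMeasurement",
    "PeptideQuant",
    "ProteinQuant",
    "LibraryEntry",
    "EnrichmentEstimate",
    "RunManifest",
    "QuantResult",
    "envelope_quality",
    "q_value",
    "fold_change",
    "percent_excess",
    "estimate_enrichment",
    "collect_heavy_envelopes",
    "positional_filters",
    "measure_pair",
    "aggregate",
    "quantify",
    "read_library",
    "write_library",
    "write_output_tree",
]


class QuantError(ValueError):
    """Raised for invalid quantification inputs."""


# --------------------------------------------------------------------------
# peptide library (identification-run results)


@dataclass(frozen=True)
class LibraryEntry:
    """One identified peptide: where it was seen in the identification run.

    ``gel_segment`` and ``lc_fraction`` index the SDS-gel slice and the
    48-spot LC schedule of the MS/MS identification; they anchor the
    positional consistency filters.
    """

    peptide: str
    accessions: tuple[str, ...]
    unique: bool
    gel_segment: int
    lc_fraction: int

    def __post_init__(self) -> None:
        assert self.unique == (len(self.accessions) == 1)


def write_library(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\taccessions\tunique\tgel_segment\tlc_fraction\n")
        for e in entries:
            fh.write(
                f"{e.peptide}\t{';'.join(e.accessions)}\t"
                f"{'yes' if e.unique else 'no'}\t{e.gel_segment}\t{e.lc_fraction}\n"
            )


def read_library(path: str | Path) -> list[LibraryEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["peptide", "accessions", "unique", "gel_segment", "lc_fraction"]
        if header != expected:
            raise QuantError(f"{path}: unexpected library header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise QuantError(f"{path}:{lineno}: expected 5 columns")
            accs = tuple(parts[1].split(";"))
            entries.append(
                LibraryEntry(
                    peptide=parts[0],
                    accessions=accs,
                    unique=parts[2] == "yes",
                    gel_segment=int(parts[3]),
                    lc_fraction=int(parts[4]),
                )
            )
    return entries


# --------------------------------------------------------------------------
# envelope quality


@dataclass(frozen=True)
class QualityVerdict:
    """Adjacent-pair ratio comparison of an experimental envelope vs theory.

    For each adjacent pair of filled slots (i, i+1) the bounded ratio
    ``r = I[i+1] / (I[i] + I[i+1])`` is compared between experiment and
    theory; the verdict passes iff every |difference| is at or below the
    threshold.  The ratio form is scale-free, so uniform intensity scaling
    cannot change a verdict.
    """

    differences: tuple[float, ...]
    max_difference: float
    passed: bool
    threshold: float


def _adjacent_ratios(intensity: np.ndarray, matched: np.ndarray):
    """Bounded adjacent ratios r_i = I[i+1]/(I[i]+I[i+1]) over filled pairs."""
    pairs = []
    for i in range(len(intensity) - 1):
        if matched[i] and matched[i + 1]:
            denom = intensity[i] + intensity[i + 1]
            if denom > 0:
                pairs.append((i, intensity[i + 1] / denom))
    return pairs


def envelope_quality(
    experimental: ExperimentalEnvelope,
    theoretical: IsotopeEnvelope,
    threshold: float = 0.05,
) -> QualityVerdict:
    """Shape test: does the experimental envelope look like the theory?"""
    if threshold <= 0:
        raise QuantError("threshold must be > 0")
    exp_pairs = dict(_adjacent_ratios(experimental.intensity, experimental.matched))
    all_true = np.ones(len(theoretical.intensity), dtype=bool)
    theo_pairs = dict(_adjacent_ratios(theoretical.intensity, all_true))
    common = sorted(set(exp_pairs) & set(theo_pairs))
    if len(common) < 1:
        raise QuantError(
            "envelope has <2 adjacent filled slots: shape is untestable"
        )
    differences = tuple(abs(exp_pairs[i] - theo_pairs[i]) for i in common)
    max_diff = max(differences)
    return QualityVerdict(
        differences=differences,
        max_difference=max_diff,
        passed=max_diff <= threshold,
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# q-value algebra


def q_value(light_sum: float, heavy_sum: float) -> float:
    """Heavy fraction of total pair signal: heavy / (light + heavy)."""
    if light_sum < 0 or heavy_sum < 0:
        raise QuantError("intensity sums must be non-negative")
    total = light_sum + heavy_sum
    if total == 0:
        raise QuantError("both intensity sums are zero: no pair signal")
    return heavy_sum / total


def fold_change(q: float) -> float:
    """Heavy:light abundance ratio implied by a q-value, q / (1 − q)."""
    if not 0.0 <= q <= 1.0:
        raise QuantError(f"q={q} outside [0, 1]")
    if q == 1.0:
        return math.inf
    return q / (1.0 - q)


def percent_excess(q: float) -> float:
    """How much more abundant the heavy sample is, in percent.

    q = 0.6 → the heavy-labeled sample carries 50% more of the peptide.
    """
    return (fold_change(q) - 1.0) * 100.0


# --------------------------------------------------------------------------
# labeling-efficiency (enrichment) estimation


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Grid-search result for the ¹⁵N incorporation level.

    ``at_boundary`` flags a poor fit: the minimum sits at a grid edge, or
    no adjacent-ratio pair overlapped between experiment and theory
    anywhere on the grid (``n_ratio_pairs`` == 0, e.g. unlabeled input
    whose envelope lies entirely outside every labeled window).
    """

    enrichment: float
    grid: np.ndarray
    objective: np.ndarray
    n_envelopes: int
    n_ratio_pairs: int
    at_boundary: bool


def estimate_enrichment(
    envelopes: Sequence[ExperimentalEnvelope],
    grid_lo: float = 0.90,
    grid_hi: float = 1.00,
    step: float = 0.001,
    max_peaks: int = 8,
) -> EnrichmentEstimate:
    """Estimate labeling efficiency from heavy experimental envelopes.

    Scans a grid of incorporation levels (90–100% by default, 0.1% steps),
    recomputes each peptide's theoretical heavy envelope at every level,
    and picks the level minimizing the summed squared adjacent-ratio
    differences — the same bounded r-statistic used by the quality test.
    Envelopes and theory are aligned on the nominal-mass grid so the
    comparison survives the truncation window drifting with enrichment.
    """
    envelopes = [e for e in envelopes if e.n_matched >= 3]
    if not envelopes:
        raise QuantError("no heavy envelopes with >=3 matched slots")
    grid = np.arange(grid_lo, grid_hi + step / 2, step)
    compositions: dict[str, ElementComposition] = {}
    exp_ratio_cache = []
    for env in envelopes:
        if env.peptide not in compositions:
            compositions[env.peptide] = composition_of(env.peptide)
        nominal = np.round(env.slot_mz).astype(int)
        ratios = {
            int(nominal[i]): r
            for i, r in _adjacent_ratios(env.intensity, env.matched)
        }
        exp_ratio_cache.append((env.peptide, ratios))

    objective = np.zeros(len(grid))
    pair_counts = np.zeros(len(grid), dtype=int)
    theo_cache: dict[tuple[str, float], dict[int, float]] = {}
    for gi, p in enumerate(grid):
        total = 0.0
        for peptide, exp_ratios in exp_ratio_cache:
            key = (peptide, round(float(p), 6))
            theo_ratios = theo_cache.get(key)
            if theo_ratios is None:
                theo = isotope_envelope(
                    compositions[peptide], enrichment=float(p), max_peaks=max_peaks
                )
                nominal = np.round(theo.mz).astype(int)
                all_true = np.ones(len(theo.intensity), dtype=bool)
                theo_ratios = {
                    int(nominal[i]): r
                    for i, r in _adjacent_ratios(theo.intensity, all_true)
                }
                theo_cache[key] = theo_ratios
            for n, r_exp in exp_ratios.items():
                r_theo = theo_ratios.get(n)
                if r_theo is not None:
                    total += (r_exp - r_theo) ** 2
                    pair_counts[gi] += 1
        objective[gi] = total

    best = int(np.argmin(objective))
    n_pairs = int(pair_counts[best])
    return EnrichmentEstimate(
        enrichment=float(grid[best]),
        grid=grid,
        objective=objective,
        n_envelopes=len(envelopes),
        n_ratio_pairs=n_pairs,
        at_boundary=best in (0, len(grid) - 1) or n_pairs == 0,
    )


def collect_heavy_envelopes(
    library: Sequence[LibraryEntry],
    peaklists: Sequence[PeakList],
    settings: Settings,
    id_schedule: FractionSchedule = SCHEDULE_ID_48,
    quant_schedule: FractionSchedule = SCHEDULE_QUANT_192,
    unambiguous_only: bool = True,
) -> list[ExperimentalEnvelope]:
    """Extract every heavy-side envelope of the library peptides from the
    spectra, the input to labeling-efficiency estimation.

    Only positionally consistent spectra are searched (gel segment within
    the neighborhood of the identification segment, elution time within
    tolerance), and by default spectra matching more than one library
    peptide are dropped: mass-only matching admits one-mass-many-sequences
    false positives — near-isobaric isoform variants in particular — whose
    foreign envelope shapes corrupt the incorporation fit.
    """
    envelopes = []
    for entry in library:
        comp = composition_of(entry.peptide)
        theo_heavy = isotope_envelope(
            comp, enrichment=settings.enrichment, max_peaks=settings.max_peaks
        )
        t_id = id_schedule.time(entry.lc_fraction)
        for pl in peaklists:
            if abs(pl.gel_segment - entry.gel_segment) > settings.segment_neighborhood:
                continue
            if abs(quant_schedule.time(pl.lc_fraction) - t_id) > settings.elution_tol_min:
                continue
            env = extract_envelope(
                pl, theo_heavy, settings.ppm_tol, settings.min_matched,
                peptide=entry.peptide, side="heavy",
            )
            if env is not None:
                envelopes.append(env)
    if unambiguous_only:
        counts: dict[str, int] = {}
        for env in envelopes:
            counts[env.spectrum_id] = counts.get(env.spectrum_id, 0) + 1
        envelopes = [e for e in envelopes if counts[e.spectrum_id] == 1]
    return envelopes


# --------------------------------------------------------------------------
# pair measurement and positional filters


@dataclass
class PairMeasurement:
    """One light/heavy envelope match in one spectrum."""

    peptide: str
    accessions: tuple[str, ...]
    unique: bool
    spectrum_id: str
    run_id: str
    gel_segment: int
    lc_fraction: int
    light_sum: float
    heavy_sum: float
    q: float
    light_verdict: QualityVerdict | None
    heavy_verdict: QualityVerdict | None
    overlap: bool
    uncertain: bool
    partial_partner: bool = False
    gel_ok: bool | None = None
    elution_ok: bool | None = None

    @property
    def quality_ok(self) -> bool:
        verdicts = [v for v in (self.light_verdict, self.heavy_verdict) if v]
        return bool(verdicts) and all(v.passed for v in verdicts)

    @property
    def accepted(self) -> bool:
        return (
            self.quality_ok
            and not self.overlap
            and not self.partial_partner
            and bool(self.gel_ok)
            and bool(self.elution_ok)
        )


def _any_peak_near_slots(
    peaklist: PeakList, theoretical: IsotopeEnvelope, ppm_tol: float
) -> bool:
    for slot in theoretical.mz:
        tol = slot * ppm_tol * 1e-6
        lo = np.searchsorted(peaklist.mz, slot - tol, side="left")
        hi = np.searchsorted(peaklist.mz, slot + tol, side="right")
        if hi > lo:
            return True
    return False


def _resolve_overlap(
    light: ExperimentalEnvelope, heavy: ExperimentalEnvelope
) -> bool:
    """Assign peaks claimed by both envelopes to the nearer theoretical slot.

    Returns True when any contest occurred; such spectra are flagged and
    excluded from aggregation (overlapping pair signals are unquantifiable).
    """
    claimed_light = {int(p): i for i, p in enumerate(light.peak_indices) if p >= 0}
    contested = [
        (p, claimed_light[p], hi)
        for hi, p in enumerate(heavy.peak_indices)
        if p >= 0 and int(p) in claimed_light
    ]
    for peak, li, hi in contested:
        d_light = abs(light.mz[li] - light.slot_mz[li])
        d_heavy = abs(heavy.mz[hi] - heavy.slot_mz[hi])
        loser = heavy if d_light <= d_heavy else light
        idx = hi if loser is heavy else li
        loser.matched[idx] = False
        loser.intensity[idx] = 0.0
        loser.peak_indices[idx] = -1
        loser.mz[idx] = np.nan
    return bool(contested)


def measure_pair(
    peaklist: PeakList,
    entry: LibraryEntry,
    theo_light: IsotopeEnvelope,
    theo_heavy: IsotopeEnvelope,
    settings: Settings,
) -> PairMeasurement | None:
    """Extract the light and heavy envelopes of one peptide from one
    spectrum and compute the pair's q-value.

    Returns None when neither envelope is found.  Single-sided detections
    (protein present in only one tissue) are reported as q exactly 0 or 1
    and carry the uncertainty flag; they still must pass the shape test on
    the present side and, downstream, both positional filters.
    """
    light = extract_envelope(
        peaklist, theo_light, settings.ppm_tol, settings.min_matched,
        peptide=entry.peptide, side="light",
    )
    heavy = extract_envelope(
        peaklist, theo_heavy, settings.ppm_tol, settings.min_matched,
        peptide=entry.peptide, side="heavy",
    )
    if light is None and heavy is None:
        return None

    # A one-sided detection is a single-tissue call (q exactly 0 or 1) only
    # when the partner window is genuinely empty; stray partial signal there
    # means an unquantifiable pair, not an absent one.
    partial_partner = False
    if light is None:
        partial_partner = _any_peak_near_slots(peaklist, theo_light, settings.ppm_tol)
    elif heavy is None:
        partial_partner = _any_peak_near_slots(peaklist, theo_heavy, settings.ppm_tol)

    overlap = False
    if light is not None and heavy is not None:
        overlap = _resolve_overlap(light, heavy)

    def verdict(env: ExperimentalEnvelope | None, theo: IsotopeEnvelope):
        if env is None or env.n_matched < 2:
            return None
        try:
            return envelope_quality(env, theo, settings.ratio_threshold)
        except QuantError:
            return None

    light_verdict = verdict(light, theo_light)
    heavy_verdict = verdict(heavy, theo_heavy)
    light_sum = light.total_intensity if light is not None else 0.0
    heavy_sum = heavy.total_intensity if heavy is not None else 0.0
    if light_sum + heavy_sum == 0:
        return None
    q = q_value(light_sum, heavy_sum)
    if settings.label_swap:
        q = 1.0 - q
        light_sum, heavy_sum = heavy_sum, light_sum
        light_verdict, heavy_verdict = heavy_verdict, light_verdict
    return PairMeasurement(
        peptide=entry.peptide,
        accessions=entry.accessions,
        unique=entry.unique,
        spectrum_id=peaklist.spectrum_id,
        run_id=peaklist.run_id,
        gel_segment=peaklist.gel_segment,
        lc_fraction=peaklist.lc_fraction,
        light_sum=light_sum,
        heavy_sum=heavy_sum,
        q=q,
        light_verdict=light_verdict,
        heavy_verdict=heavy_verdict,
        overlap=overlap,
        uncertain=q > settings.uncertainty_high or q < settings.uncertainty_low,
        partial_partner=partial_partner,
    )


def positional_filters(
    measurement: PairMeasurement,
    entry: LibraryEntry,
    protein_masses_kda: Mapping[str, float],
    gel_model: GelModel,
    settings: Settings,
    id_schedule: FractionSchedule = SCHEDULE_ID_48,
    quant_schedule: FractionSchedule = SCHEDULE_QUANT_192,
) -> PairMeasurement:
    """Apply the two false-positive criteria and record the flags.

    Gel consistency: the quantification-run segment must lie within
    ``segment_neighborhood`` of the identification segment AND the MW
    window of that neighborhood (the union of the segment's window with
    its allowed neighbors, absorbing run-to-run registration wobble) must
    contain k × (parent protein mass) for some oligomeric state k in
    ``multimers`` — PIP-like proteins band both as ~30 kDa monomers and
    ~60 kDa dimers.  For shared peptides any parent protein may satisfy
    the mass condition.

    Elution consistency: mid-fraction retention times of the two runs must
    agree within ``elution_tol_min`` minutes.
    """
    seg = measurement.gel_segment
    neighborhood = [
        s for s in range(seg - settings.segment_neighborhood,
                         seg + settings.segment_neighborhood + 1)
        if 0 <= s < gel_model.n_segments
    ]
    gel_model.interval(seg)  # reject segments outside the model
    lo = min(gel_model.interval(s)[0] for s in neighborhood)
    hi = max(gel_model.interval(s)[1] for s in neighborhood)

    def mass_bands_here(acc: str) -> bool:
        mass = protein_masses_kda.get(acc)
        if mass is None:
            raise QuantError(f"no protein mass for accession {acc!r}")
        return any(lo <= k * mass < hi for k in settings.multimers)

    segment_close = (
        abs(measurement.gel_segment - entry.gel_segment)
        <= settings.segment_neighborhood
    )
    measurement.gel_ok = segment_close and any(
        mass_bands_here(acc) for acc in entry.accessions
    )
    t_quant = quant_schedule.time(measurement.lc_fraction)
    t_id = id_schedule.time(entry.lc_fraction)
    measurement.elution_ok = abs(t_quant - t_id) <= settings.elution_tol_min
    return measurement


# --------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class PeptideQuant:
    """Per-peptide aggregate over all accepted spectra."""

    peptide: str
    accessions: tuple[str, ...]
    unique: bool
    mean_q: float
    sd: float
    n_spectra: int


@dataclass(frozen=True)
class ProteinQuant:
    """Per-protein aggregate over its unique peptides only."""

    accession: str
    mean_q: float
    sd: float
    n_unique_peptides: int
    n_spectra: int


def _sd(values: Sequence[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def aggregate(
    measurements: Iterable[PairMeasurement],
) -> tuple[list[PeptideQuant], list[ProteinQuant]]:
    """Roll accepted measurements up to peptides, and unique peptides up to
    proteins.

    Only measurements passing both shape verdicts and both positional
    filters (and free of envelope overlap) enter.  The peptide q is the
    arithmetic mean of its per-spectrum q values, with the sample SD over
    spectra (0.00 for a single spectrum).  The protein q is the mean over
    its unique-peptide means; shared peptides never contribute to a
    protein.  A protein with one unique peptide reports that peptide's own
    spectrum SD.
    """
    by_peptide: dict[tuple[str, tuple[str, ...]], list[PairMeasurement]] = {}
    for m in measurements:
        if m.accepted:
            by_peptide.setdefault((m.peptide, m.accessions), []).append(m)

    peptide_quants = []
    for (peptide, accessions), ms in sorted(by_peptide.items()):
        qs = [m.q for m in ms]
        peptide_quants.append(
            PeptideQuant(
                peptide=peptide,
                accessions=accessions,
                unique=ms[0].unique,
                mean_q=float(np.mean(qs)),
                sd=_sd(qs),
                n_spectra=len(qs),
            )
        )

    by_protein: dict[str, list[PeptideQuant]] = {}
    for pq in peptide_quants:
        if pq.unique:
            by_protein.setdefault(pq.accessions[0], []).append(pq)

    protein_quants = []
    for accession, pqs in sorted(by_protein.items()):
        means = [pq.mean_q for pq in pqs]
        sd = pqs[0].sd if len(pqs) == 1 else _sd(means)
        protein_quants.append(
            ProteinQuant(
                accession=accession,
                mean_q=float(np.mean(means)),
                sd=sd,
                n_unique_peptides=len(pqs),
                n_spectra=sum(pq.n_spectra for pq in pqs),
            )
        )
    return peptide_quants, protein_quants


# --------------------------------------------------------------------------
# full pipeline


@dataclass
class RunManifest:
    """Reproducibility record: settings, input checksums and the filter
    funnel (counts are non-increasing along the chain)."""

    settings: dict
    input_checksums: dict[str, str]
    version: str
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "settings": self.settings,
                    "input_checksums": self.input_checksums,
                    "version": self.version,
                    "counts": self.counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


@dataclass
class QuantResult:
    measurements: list[PairMeasurement]
    peptide_quants: list[PeptideQuant]
    protein_quants: list[ProteinQuant]
    manifest: RunManifest


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def checksum_tree(root: str | Path) -> dict[str, str]:
    root = Path(root)
    if root.is_file():
        return {root.name: _checksum(root)}
    return {
        str(p.relative_to(root)): _checksum(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def quantify(
    library: Sequence[LibraryEntry],
    peaklists: Sequence[PeakList],
    settings: Settings,
    protein_masses_kda: Mapping[str, float],
    gel_model: GelModel,
    id_schedule: FractionSchedule = SCHEDULE_ID_48,
    quant_schedule: FractionSchedule = SCHEDULE_QUANT_192,
    input_checksums: Mapping[str, str] | None = None,
) -> QuantResult:
    """Run the whole quantification chain: theoretical envelopes → pair
    extraction → shape QC → positional filters → aggregation."""
    from . import __version__

    measurements: list[PairMeasurement] = []
    for entry in library:
        comp = composition_of(entry.peptide)
        theo_light = isotope_envelope(
            comp, enrichment=settings.natural_n15, max_peaks=settings.max_peaks
        )
        theo_heavy = isotope_envelope(
            comp, enrichment=settings.enrichment, max_peaks=settings.max_peaks
        )
        for pl in peaklists:
            m = measure_pair(pl, entry, theo_light, theo_heavy, settings)
            if m is None:
                continue
            positional_filters(
                m, entry, protein_masses_kda, gel_model, settings,
                id_schedule, quant_schedule,
            )
            measurements.append(m)

    peptide_quants, protein_quants = aggregate(measurements)
    n_quality = sum(1 for m in measurements if m.quality_ok)
    n_positional = sum(
        1 for m in measurements if m.quality_ok and m.gel_ok and m.elution_ok
    )
    n_accepted = sum(1 for m in measurements if m.accepted)
    manifest = RunManifest(
        settings=settings.to_dict(),
        input_checksums=dict(input_checksums or {}),
        version=__version__,
        counts={
            "spectra": len(peaklists),
            "library_peptides": len(library),
            "pair_matches": len(measurements),
            "pass_quality": n_quality,
            "pass_quality_and_position": n_positional,
            "accepted": n_accepted,
        },
    )
    return QuantResult(measurements, peptide_quants, protein_quants, manifest)


def write_output_tree(result: QuantResult, out_dir: str | Path) -> None:
    """Write the per-protein output folders and flat summary tables.

    One subfolder per protein accession with per-peptide result files
    (per-spectrum q tables) and a q-plot data file; flat
    ``peptide_summary.tsv`` / ``protein_summary.tsv`` tables; a
    ``borderline_spectra.tsv`` export of flagged measurements in place of
    manual inspection; and the run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_accession: dict[str, list[PairMeasurement]] = {}
    for m in result.measurements:
        for acc in m.accessions:
            by_accession.setdefault(acc, []).append(m)

    for acc, ms in sorted(by_accession.items()):
        folder = out / acc
        folder.mkdir(exist_ok=True)
        by_pep: dict[str, list[PairMeasurement]] = {}
        for m in ms:
            by_pep.setdefault(m.peptide, []).append(m)
        with open(folder / "qplot.tsv", "w") as qplot:
            qplot.write("peptide\tspectrum\tq\n")
            for pep, pms in sorted(by_pep.items()):
                with open(folder / f"{pep}.tsv", "w") as fh:
                    fh.write(
                        "spectrum\trun\tq\tlight_sum\theavy_sum\tquality_ok\t"
                        "gel_ok\telution_ok\toverlap\tuncertain\taccepted\n"
                    )
                    for m in sorted(pms, key=lambda m: m.spectrum_id):
                        fh.write(
                            f"{m.spectrum_id}\t{m.run_id}\t{m.q:.4f}\t"
                            f"{m.light_sum:.2f}\t{m.heavy_sum:.2f}\t"
                            f"{m.quality_ok}\t{m.gel_ok}\t{m.elution_ok}\t"
                            f"{m.overlap}\t{m.uncertain}\t{m.accepted}\n"
                        )
                        if m.accepted:
                            qplot.write(f"{pep}\t{m.spectrum_id}\t{m.q:.4f}\n")

    with open(out / "peptide_summary.tsv", "w") as fh:
        fh.write("peptide\taccessions\tunique\tq\tsd\tn_spectra\n")
        for pq in result.peptide_quants:
            fh.write(
                f"{pq.peptide}\t{';'.join(pq.accessions)}\t"
                f"{'yes' if pq.unique else 'no'}\t"
                f"{pq.mean_q:.2f}\t{pq.sd:.2f}\t{pq.n_spectra}\n"
            )
    with open(out / "protein_summary.tsv", "w") as fh:
        fh.write("accession\tn_unique_peptides\tq\tsd\tn_spectra\n")
        for pr in result.protein_quants:
            fh.write(
                f"{pr.accession}\t{pr.n_unique_peptides}\t"
                f"{pr.mean_q:.2f}\t{pr.sd:.2f}\t{pr.n_spectra}\n"
            )
    with open(out / "borderline_spectra.tsv", "w") as fh:
        fh.write("peptide\tspectrum\tq\treason\n")
        for m in result.measurements:
            reasons = []
            if m.overlap:
                reasons.append("overlap")
            if m.partial_partner:
                reasons.append("partial_partner")
            if m.uncertain:
                reasons.append("uncertain")
            if not m.quality_ok:
                reasons.append("shape")
            if reasons:
                fh.write(
                    f"{m.peptide}\t{m.spectrum_id}\t{m.q:.4f}\t{','.join(reasons)}\n"
                )
    result.manifest.to_json(out / "manifest.json")
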