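"""Ground-truth simulator: synthetic proteomes, metabolic labeling, and
LC-MALDI peak lists exercising every pipeline stage without external data.

The simulator emulates the two-run design: an identification run whose
results become the peptide library (48-spot LC schedule, gel segment and
fraction recorded per peptide), and a quantification run of mixed
light/heavy samples (192-spot schedule) whose spectra contain ¹⁴N/¹⁵N
envelope pairs scaled to (1 − f) and f, where f is the true heavy fraction
(the true q) of the parent protein.  The default proteome contains a
13-member PIP-like isoform family generated by mutating a base sequence at
~5% of positions, so shared/unique peptide classification is exercised at
realistic (≥90%) identity.

The noise model is documented and deliberately simple: log-normal
multiplicative intensity error, uniform ppm m/z jitter, Bernoulli peak
dropout, and a detection floor.  Elution order comes from a fixed
hydropathy-sum proxy — any monotone proxy suffices, since only consistency
between the identification and quantification runs matters.  Peaks closer
than the centroiding resolution merge, which is what makes overlapping
light/heavy windows of short (low-nitrogen) peptides collide as they do on
a real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import average_mass, composition_of, isotope_envelope
from .digest import (
    ProteinRecord,
    build_peptide_map,
    classify_uniqueness,
    write_fasta,
)
from .peaks import (
    GelModel,
    PeakList,
    SCHEDULE_ID_48,
    SCHEDULE_QUANT_192,
    default_gel_model,
    write_peaklist,
)
from .quant import LibraryEntry, write_library
from .settings import Settings

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "Experiment",
    "MIXING_RATIOS",
    "elution_time",
    "generate_proteome",
    "build_library",
    "simulate_experiment",
    "inject_confounders",
    "write_experiment",
]

#: Heavy fractions of the mixing-series validation design
#: (1:9, 2:8, 3:7, 5:5, 7:3, 8:2, 9:1 light:heavy mixtures).
MIXING_RATIOS = (0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Kyte–Doolittle hydropathy, the fixed residue-weight sum behind the
# elution-order proxy.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


def elution_time(peptide: str) -> float:
    """Deterministic elution-time proxy in gradient minutes.

    Mean residue hydropathy mapped monotonically onto 28–56 min, inside
    the collection window of both fraction schedules.
    """
    h = sum(_HYDROPATHY[ch] for ch in peptide) / len(peptide)
    u = min(max((h + 4.5) / 9.0, 0.01), 0.99)
    return 28.0 + 28.0 * u


@dataclass(frozen=True)
class NoiseModel:
    """Peak-level noise: log-normal intensity error with coefficient of
    variation ``intensity_cv``, uniform m/z jitter of ±``mz_jitter_ppm``,
    Bernoulli dropout, and a detection floor in intensity units."""

    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 5.0
    dropout_prob: float = 0.01
    additive_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.mz_jitter_ppm < 0:
            raise SimulationError("noise magnitudes must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise SimulationError("dropout_prob must be in [0, 1)")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(intensity_cv=0.0, mz_jitter_ppm=0.0, dropout_prob=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated labeling experiment.

    ``heavy_fraction`` is the true q of every protein (or a per-accession
    mapping); ``enrichment`` the ¹⁵N incorporation of the heavy sample.
    ``family_size`` proteins are near-identical isoforms mutated from one
    base sequence at ``family_mutation_rate`` per position.
    """

    seed: int = 0
    family_size: int = 13
    family_mutation_rate: float = 0.05
    n_background_proteins: int = 4
    protein_length: tuple[int, int] = (150, 260)
    enrichment: float = 0.982
    heavy_fraction: float | Mapping[str, float] = 0.5
    n_spectra_per_peptide: int = 3
    base_intensity: float = 1000.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    resolution_da: float = 0.05
    dimer_fraction: float = 0.0
    n_position_decoys: int = 0
    n_shape_decoys: int = 0
    max_library_peptides: int | None = None

    def __post_init__(self) -> None:
        fs = self.heavy_fraction
        values = fs.values() if isinstance(fs, Mapping) else [fs]
        if any(not 0.0 <= f <= 1.0 for f in values):
            raise SimulationError("heavy_fraction outside [0, 1]")
        if not 0.0 <= self.enrichment <= 1.0:
            raise SimulationError("enrichment outside [0, 1]")
        if self.family_size < 1 or self.n_spectra_per_peptide < 1:
            raise SimulationError("family_size and n_spectra_per_peptide must be >= 1")
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise SimulationError("dimer_fraction outside [0, 1]")

    def heavy_fraction_for(self, accession: str) -> float:
        if isinstance(self.heavy_fraction, Mapping):
            return self.heavy_fraction[accession]
        return self.heavy_fraction


@dataclass
class Experiment:
    """A simulated experiment with its complete ground truth."""

    config: SimulationConfig
    proteins: list[ProteinRecord]
    library: list[LibraryEntry]
    peaklists: list[PeakList]
    truth: pd.DataFrame
    protein_masses_kda: dict[str, float]
    gel_model: GelModel

    @property
    def settings(self) -> Settings:
        return Settings(enrichment=self.config.enrichment)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_ALPHABET), size=length))


def generate_proteome(
    config: SimulationConfig, rng: np.random.Generator
) -> list[ProteinRecord]:
    """Isoform family (PIPL01..) plus unrelated background proteins (BGP01..).

    Family members share the base sequence's K/R pattern (mutations avoid
    K, R and P), so tryptic peptides align across isoforms and unmutated
    peptides are genuinely shared.
    """
    lo, hi = config.protein_length
    base = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
    substitutes = [c for c in _ALPHABET if c not in "KRP"]
    proteins = []
    for i in range(config.family_size):
        seq = list(base)
        for pos, ch in enumerate(seq):
            if ch in "KRP":
                continue
            if rng.random() < config.family_mutation_rate:
                choices = [c for c in substitutes if c != ch]
                seq[pos] = choices[int(rng.integers(len(choices)))]
        proteins.append(
            ProteinRecord(
                accession=f"PIPL{i + 1:02d}",
                sequence="".join(seq),
                annotation="simulated isoform-family member",
            )
        )
    for i in range(config.n_background_proteins):
        proteins.append(
            ProteinRecord(
                accession=f"BGP{i + 1:02d}",
                sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
                annotation="simulated background protein",
            )
        )
    return proteins


def build_library(
    proteins: Sequence[ProteinRecord],
    settings: Settings,
    gel_model: GelModel,
) -> tuple[list[LibraryEntry], dict[str, float]]:
    """Digest the proteome and place every peptide where the identification
    run would have seen it: the gel segment its (first) parent protein
    bands in as a monomer, and the 48-schedule fraction of its elution
    time."""
    masses = {
        p.accession: average_mass(composition_of(p.sequence, fixed_mods=None)) / 1000.0
        for p in proteins
    }
    peptide_map = build_peptide_map(
        list(proteins),
        max_missed=settings.max_missed,
        min_length=settings.min_length,
        max_length=settings.max_length,
    )
    entries = []
    for a in classify_uniqueness(peptide_map):
        parent_mass = masses[a.parents[0]]
        entries.append(
            LibraryEntry(
                peptide=a.sequence,
                accessions=a.parents,
                unique=a.unique,
                gel_segment=gel_model.segment_for_mass(parent_mass),
                lc_fraction=SCHEDULE_ID_48.index_for_time(elution_time(a.sequence)),
            )
        )
    return entries, masses


def _apply_noise(
    mz: np.ndarray,
    intensity: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    keep = rng.random(len(mz)) >= noise.dropout_prob
    mz, intensity = mz[keep], intensity[keep]
    if noise.mz_jitter_ppm > 0:
        mz = mz * (1.0 + rng.uniform(-noise.mz_jitter_ppm, noise.mz_jitter_ppm,
                                     size=len(mz)) * 1e-6)
    if noise.intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.intensity_cv**2)))
        intensity = intensity * rng.lognormal(-sigma**2 / 2, sigma, size=len(intensity))
    if noise.additive_floor > 0:
        keep = intensity >= noise.additive_floor
        mz, intensity = mz[keep], intensity[keep]
    return mz, intensity


def _merge_peaks(
    mz: np.ndarray, intensity: np.ndarray, resolution_da: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centroiding: peaks closer than the resolution merge into one, at the
    intensity-weighted mean m/z."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    cur_mz, cur_int = mz[0] * intensity[0], intensity[0]
    last = mz[0]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - last < resolution_da:
            cur_mz += m * i
            cur_int += i
        else:
            out_mz.append(cur_mz / cur_int if cur_int > 0 else last)
            out_int.append(cur_int)
            cur_mz, cur_int = m * i, i
        last = m
    out_mz.append(cur_mz / cur_int if cur_int > 0 else last)
    out_int.append(cur_int)
    return np.array(out_mz), np.array(out_int)


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> Experiment:
    """Generate proteome, library, and quantification-run spectra.

    Every library peptide gets ``n_spectra_per_peptide`` spectra, each
    containing its light envelope scaled to (1 − f) and its heavy envelope
    (at the configured enrichment) scaled to f, with noise.  At f = 0 or 1
    only one side is written (single-tissue proteins).  The truth table
    records every placement; with a fixed seed the output is byte-identical
    between runs.
    """
    rng = np.random.default_rng(config.seed)
    gel_model = default_gel_model()
    settings = Settings(enrichment=config.enrichment)
    proteins = generate_proteome(config, rng)
    library, masses = build_library(proteins, settings, gel_model)
    if config.max_library_peptides is not None:
        library = library[: config.max_library_peptides]

    peaklists: list[PeakList] = []
    truth_rows = []
    for ei, entry in enumerate(library):
        comp = composition_of(entry.peptide)
        theo_light = isotope_envelope(comp, enrichment=settings.natural_n15,
                                      max_peaks=settings.max_peaks)
        theo_heavy = isotope_envelope(comp, enrichment=config.enrichment,
                                      max_peaks=settings.max_peaks)
        f = config.heavy_fraction_for(entry.accessions[0])
        t = elution_time(entry.peptide)
        fraction = SCHEDULE_QUANT_192.index_for_time(t)
        monomer_segment = entry.gel_segment
        parent_mass = masses[entry.accessions[0]]
        for rep in range(config.n_spectra_per_peptide):
            segment = monomer_segment
            if config.dimer_fraction > 0 and rng.random() < config.dimer_fraction:
                segment = gel_model.segment_for_mass(2.0 * parent_mass)
            mzs = np.concatenate([
                theo_light.mz if f < 1.0 else np.empty(0),
                theo_heavy.mz if f > 0.0 else np.empty(0),
            ])
            ints = np.concatenate([
                theo_light.intensity * (1.0 - f) * config.base_intensity
                if f < 1.0 else np.empty(0),
                theo_heavy.intensity * f * config.base_intensity
                if f > 0.0 else np.empty(0),
            ])
            mzs, ints = _apply_noise(mzs, ints, config.noise, rng)
            mzs, ints = _merge_peaks(mzs, ints, config.resolution_da)
            spectrum_id = f"q{ei:04d}r{rep}"
            peaklists.append(
                PeakList(
                    spectrum_id=spectrum_id,
                    run_id="quant",
                    lc_fraction=fraction,
                    gel_segment=segment,
                    mz=mzs,
                    intensity=ints,
                )
            )
            truth_rows.append(
                dict(
                    spectrum=spectrum_id, run="quant", peptide=entry.peptide,
                    accessions=";".join(entry.accessions), f_true=f,
                    enrichment=config.enrichment, gel_segment=segment,
                    lc_fraction=fraction, kind="target",
                )
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["spectrum", "run", "peptide", "accessions", "f_true",
                 "enrichment", "gel_segment", "lc_fraction", "kind"],
    )
    experiment = Experiment(
        config=config, proteins=proteins, library=library,
        peaklists=peaklists, truth=truth,
        protein_masses_kda=masses, gel_model=gel_model,
    )
    if out_dir is not None:
        write_experiment(experiment, out_dir)
    return experiment


def inject_confounders(
    experiment: Experiment,
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> Experiment:
    """Add decoy spectra with known labels, for measuring filter efficacy.

    Positional decoys are well-shaped envelope pairs placed in the wrong
    gel segment and at the wrong elution time — they violate both
    consistency criteria by construction.  Shape decoys emulate the
    one-mass-many-sequences false positive: an impostor peptide's
    natural-abundance envelope written at the target peptide's heavy slot
    positions, at the correct gel/elution position — only the envelope
    shape test can catch them.  A zero-confounder config returns the
    experiment unchanged.
    """
    config = config or experiment.config
    if config.n_position_decoys == 0 and config.n_shape_decoys == 0:
        return experiment
    rng = np.random.default_rng(config.seed + 10_007)
    library = experiment.library
    settings = experiment.settings
    gel_model = experiment.gel_model
    peaklists = list(experiment.peaklists)
    truth_rows = []

    def envelopes_for(entry: LibraryEntry):
        comp = composition_of(entry.peptide)
        light = isotope_envelope(comp, enrichment=settings.natural_n15,
                                 max_peaks=settings.max_peaks)
        heavy = isotope_envelope(comp, enrichment=config.enrichment,
                                 max_peaks=settings.max_peaks)
        return light, heavy

    for d in range(config.n_position_decoys):
        entry = library[d % len(library)]
        light, heavy = envelopes_for(entry)
        f = config.heavy_fraction_for(entry.accessions[0])
        f = min(max(f, 0.3), 0.7)  # keep both sides present and well-formed
        seg = (entry.gel_segment + settings.segment_neighborhood + 4) % gel_model.n_segments
        true_fraction = SCHEDULE_QUANT_192.index_for_time(elution_time(entry.peptide))
        shift = int(np.ceil(3 * settings.elution_tol_min / SCHEDULE_QUANT_192.interval_min))
        fraction = (true_fraction + shift) % SCHEDULE_QUANT_192.n_fractions
        mzs = np.concatenate([light.mz, heavy.mz])
        ints = np.concatenate([
            light.intensity * (1 - f) * config.base_intensity,
            heavy.intensity * f * config.base_intensity,
        ])
        mzs, ints = _apply_noise(mzs, ints, config.noise, rng)
        mzs, ints = _merge_peaks(mzs, ints, config.resolution_da)
        spectrum_id = f"dpos{d:04d}"
        peaklists.append(PeakList(spectrum_id, "quant", fraction, seg, mzs, ints))
        truth_rows.append(dict(
            spectrum=spectrum_id, run="quant", peptide=entry.peptide,
            accessions=";".join(entry.accessions), f_true=f,
            enrichment=config.enrichment, gel_segment=seg,
            lc_fraction=fraction, kind="decoy_position",
        ))

    for d in range(config.n_shape_decoys):
        entry = library[d % len(library)]
        _, heavy = envelopes_for(entry)
        # impostor: a different library peptide whose natural envelope shape
        # is written at the target's heavy slot positions
        impostor = library[(d + len(library) // 2 + 1) % len(library)]
        if impostor.peptide == entry.peptide:
            impostor = library[(d + 1) % len(library)]
        imp_env = isotope_envelope(composition_of(impostor.peptide),
                                   enrichment=settings.natural_n15,
                                   max_peaks=settings.max_peaks)
        n = len(heavy.mz)
        shape = np.zeros(n)
        k = min(n, len(imp_env.intensity))
        shape[:k] = imp_env.intensity[:k]
        shape = shape / shape.sum()
        mzs, ints = _apply_noise(
            heavy.mz.copy(), shape * config.base_intensity, config.noise, rng
        )
        mzs, ints = _merge_peaks(mzs, ints, config.resolution_da)
        spectrum_id = f"dshp{d:04d}"
        fraction = SCHEDULE_QUANT_192.index_for_time(elution_time(entry.peptide))
        peaklists.append(PeakList(spectrum_id, "quant", fraction,
                                  entry.gel_segment, mzs, ints))
        truth_rows.append(dict(
            spectrum=spectrum_id, run="quant", peptide=entry.peptide,
            accessions=";".join(entry.accessions), f_true=np.nan,
            enrichment=config.enrichment, gel_segment=entry.gel_segment,
            lc_fraction=fraction, kind="decoy_shape",
        ))

    truth = pd.concat(
        [experiment.truth, pd.DataFrame(truth_rows)], ignore_index=True
    )
    modified = Experiment(
        config=config, proteins=experiment.proteins, library=library,
        peaklists=peaklists, truth=truth,
        protein_masses_kda=experiment.protein_masses_kda,
        gel_model=gel_model,
    )
    if out_dir is not None:
        write_experiment(modified, out_dir)
    return modified


def write_experiment(experiment: Experiment, out_dir: str | Path) -> None:
    """Write FASTA, library table, truth table and the per-run peak-list
    directory in the canonical TSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(experiment.proteins, out / "proteome.fasta")
    write_library(experiment.library, out / "library.tsv")
    experiment.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    pl_dir = out / "peaklists" / "quant"
    pl_dir.mkdir(parents=True, exist_ok=True)
    for pl in experiment.peaklists:
        write_peaklist(pl, pl_dir / f"{pl.spectrum_id}.tsv")
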