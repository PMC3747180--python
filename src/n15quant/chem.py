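"""Peptide elemental compositions, monoisotopic masses, and theoretical
isotope envelopes at arbitrary ¹⁵N enrichment.

The isotope envelope of a peptide at charge 1 is a series of peaks spaced
roughly one Dalton apart, one per nominal-mass isotopologue class.  Under
metabolic ¹⁵N labeling the nitrogen isotope abundances are no longer natural:
a fraction ``p`` of all nitrogen atoms is ¹⁵N.  The envelope is computed by
per-element multinomial expansion followed by cross-element convolution on
the unit-mass (extra-neutron) grid, with the nitrogen abundances replaced by
``(1 - p, p)``.  Nominal-mass aggregation is appropriate for reflector
MALDI-TOF data, where fine isotopologue splitting is far below instrument
resolution; the centroid m/z reported for each peak is the abundance-weighted
mean mass of the isotopologues in that bin.

Reference data (residue compositions, isotope masses and abundances) are
shipped as plain-text tables under ``n15quant/data`` so that results are
reproducible independent of any external source.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "PROTON_MASS",
    "N15_N14_DELTA",
    "NATURAL_N15",
    "DEFAULT_LABELED_N15",
    "CARBAMIDOMETHYL",
    "ElementComposition",
    "IsotopeEnvelope",
    "composition_of",
    "monoisotopic_mass",
    "mh_mz",
    "average_mass",
    "heavy_mass_shift",
    "isotope_envelope",
    "residue_compositions",
    "isotope_table",
]

PROTON_MASS = 1.00727646688

#: Natural abundance of ¹⁵N (fraction of all nitrogen).
NATURAL_N15 = 0.00364

#: Labeling efficiency of the reference ¹⁵N growth protocol (fraction).
DEFAULT_LABELED_N15 = 0.982

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class CompositionError(ValueError):
    """Raised for invalid sequences or elemental compositions."""


@dataclass(frozen=True)
class ElementComposition:
    """Element → atom-count map for a peptide or modification delta.

    Counts are non-negative integers.  Compositions add with ``+`` and
    scale with ``*`` (integer factor), mirroring how residue formulas
    combine into peptide formulas.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {e: int(n) for e, n in self.counts.items() if n != 0}
        for element, n in clean.items():
            if n < 0:
                raise CompositionError(
                    f"negative count {n} for element {element}"
                )
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a formula like ``C2H3N1O1`` (counts may be omitted for 1)."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise CompositionError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise CompositionError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.counts))

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for e, n in other.counts.items():
            merged[e] = merged.get(e, 0) + n
        return ElementComposition(merged)

    def __mul__(self, factor: int) -> "ElementComposition":
        return ElementComposition({e: n * factor for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        return "".join(f"{e}{self.counts[e]}" for e in sorted(self.counts))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementComposition({self.formula()})"


WATER = ElementComposition({"H": 2, "O": 1})

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), the standard
#: fixed modification: +C2H3NO on every C residue.
CARBAMIDOMETHYL: Mapping[str, ElementComposition] = {
    "C": ElementComposition.from_formula("C2H3N1O1")
}


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("n15quant.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_residues() -> dict[str, ElementComposition]:
    table = {
        sym: ElementComposition.from_formula(formula)
        for sym, formula in _load_table("residues.tsv")
    }
    missing = set(_STANDARD_RESIDUES) - set(table)
    if missing:  # pragma: no cover - data-file integrity
        raise CompositionError(f"residue table missing {sorted(missing)}")
    return table


def _load_isotopes() -> dict[str, list[tuple[float, float]]]:
    table: dict[str, list[tuple[float, float]]] = {}
    for element, mass, abundance in _load_table("isotopes.tsv"):
        table.setdefault(element, []).append((float(mass), float(abundance)))
    for element, isotopes in table.items():
        masses = [m for m, _ in isotopes]
        if masses != sorted(masses):  # pragma: no cover - data-file integrity
            raise CompositionError(f"isotope masses not increasing for {element}")
        total = sum(a for _, a in isotopes)
        if abs(total - 1.0) > 1e-9:  # pragma: no cover - data-file integrity
            raise CompositionError(
                f"isotope abundances for {element} sum to {total}"
            )
    return table


_RESIDUES = _load_residues()
_ISOTOPES = _load_isotopes()

#: Mass difference between ¹⁵N and ¹⁴N, from the embedded isotope table.
N15_N14_DELTA = _ISOTOPES["N"][1][0] - _ISOTOPES["N"][0][0]


def residue_compositions() -> Mapping[str, ElementComposition]:
    """The embedded residue (monomer) composition table."""
    return dict(_RESIDUES)


def isotope_table() -> Mapping[str, list[tuple[float, float]]]:
    """The embedded isotope (mass, natural abundance) table."""
    return {e: list(v) for e, v in _ISOTOPES.items()}


def validate_sequence(sequence: str) -> str:
    """Check that a peptide sequence uses only the 20 standard residues.

    Ambiguity codes (B, Z, X) and selenocysteine (U) are rejected rather
    than approximated.  Returns the uppercased sequence.
    """
    if not sequence:
        raise CompositionError("empty peptide sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _RESIDUES:
            raise CompositionError(
                f"unknown residue {ch!r} at position {i + 1} in {sequence!r}"
            )
    return seq


def composition_of(
    sequence: str,
    fixed_mods: Mapping[str, ElementComposition] | None = CARBAMIDOMETHYL,
) -> ElementComposition:
    """Elemental composition of a peptide: residue sum + one water.

    ``fixed_mods`` maps residue letters to composition deltas applied to
    every occurrence of that residue; the default is carbamidomethylation
    of cysteine.  Pass ``None`` (or ``{}``) for unmodified peptides.
    """
    seq = validate_sequence(sequence)
    total = WATER
    for ch in seq:
        total = total + _RESIDUES[ch]
        if fixed_mods and ch in fixed_mods:
            total = total + fixed_mods[ch]
    return total


def monoisotopic_mass(composition: ElementComposition) -> float:
    """Neutral monoisotopic mass: each element at its lightest isotope."""
    mass = 0.0
    for element in composition:
        try:
            isotopes = _ISOTOPES[element]
        except KeyError:
            raise CompositionError(f"no isotope data for element {element!r}")
        mass += composition[element] * isotopes[0][0]
    return mass


def mh_mz(composition: ElementComposition) -> float:
    """Singly protonated monoisotopic m/z ([M+H]+), the MALDI species."""
    return monoisotopic_mass(composition) + PROTON_MASS


def average_mass(composition: ElementComposition) -> float:
    """Abundance-weighted (average) mass, the scale relevant for apparent
    molecular weight on an SDS gel."""
    mass = 0.0
    for element in composition:
        isotopes = _ISOTOPES.get(element)
        if isotopes is None:
            raise CompositionError(f"no isotope data for element {element!r}")
        mass += composition[element] * sum(m * a for m, a in isotopes)
    return mass


def heavy_mass_shift(
    composition: ElementComposition, enrichment: float = 1.0
) -> float:
    """Mean mass shift of the ¹⁵N-labeled species relative to the light one.

    At full enrichment this is ``N_count × (m(¹⁵N) − m(¹⁴N))`` and positions
    the monoisotopic peak of the heavy envelope; at partial enrichment the
    intensity-weighted mean shift is proportionally smaller because intensity
    moves to lighter isotopologues.
    """
    n = composition["N"]
    if n < 1:
        raise CompositionError(
            "composition has no nitrogen: not a peptide, no heavy partner"
        )
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError(f"enrichment {enrichment} outside [0, 1]")
    return n * N15_N14_DELTA * enrichment


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Theoretical isotope envelope at charge 1.

    ``mz`` are centroid m/z values on the unit-mass grid ([M+H]+ scale),
    strictly increasing with ~1 Da spacing; ``intensity`` are relative
    intensities renormalized to sum to 1 after truncation to the most
    intense contiguous ``truncation_mass_count`` peaks.  ``coverage`` is
    the fraction of total isotopologue probability retained.
    """

    mz: np.ndarray
    intensity: np.ndarray
    enrichment: float
    truncation_mass_count: int
    coverage: float = 1.0

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def apex_index(self) -> int:
        """Index of the most intense theoretical peak."""
        return int(np.argmax(self.intensity))

    def __len__(self) -> int:
        return len(self.mz)


def _combine(pa, sa, pb, sb):
    # (p, s) with s[k] = sum of prob*mass inside bin k; product of
    # independent distributions convolves p and bilinearly combines s.
    p = np.convolve(pa, pb)
    s = np.convolve(sa, pb) + np.convolve(pa, sb)
    return p, s


def _element_distribution(
    isotopes: list[tuple[float, float]], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extra-neutron distribution of ``n`` atoms of one element.

    Computed by binary-powering convolution of the single-atom
    distribution; exact multinomial expansion on the unit-mass grid.
    """
    base_mass = isotopes[0][0]
    offsets = [int(round(m - base_mass)) for m, _ in isotopes]
    k_max = max(offsets)
    p1 = np.zeros(k_max + 1)
    s1 = np.zeros(k_max + 1)
    for (m, a), k in zip(isotopes, offsets):
        p1[k] += a
        s1[k] += a * m
    # result accumulators start at the identity (mass 0, prob 1)
    p, s = np.array([1.0]), np.array([0.0])
    pw, sw = p1, s1
    while n:
        if n & 1:
            p, s = _combine(p, s, pw, sw)
        n >>= 1
        if n:
            pw, sw = _combine(pw, sw, pw, sw)
    return p, s


def isotope_envelope(
    composition: ElementComposition,
    enrichment: float = NATURAL_N15,
    max_peaks: int = 8,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of ``composition`` at ¹⁵N fraction
    ``enrichment``, truncated to the ``max_peaks`` most intense contiguous
    peaks and renormalized.

    All elements use natural abundances except nitrogen, whose two-isotope
    abundances are replaced by ``(1 − p, p)``.  The pre-truncation
    distribution sums to 1 to within accumulated floating error (≤1e-6).
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError(f"enrichment {enrichment} outside [0, 1]")
    if max_peaks < 2:
        raise ValueError("max_peaks must be >= 2 (ratio tests need >=2 peaks)")
    if composition.n_atoms == 0:
        raise CompositionError("empty composition")

    p_total, s_total = np.array([1.0]), np.array([0.0])
    for element in composition:
        isotopes = _ISOTOPES.get(element)
        if isotopes is None:
            raise CompositionError(f"no isotope data for element {element!r}")
        if element == "N":
            (m14, _), (m15, _) = isotopes
            isotopes = [(m14, 1.0 - enrichment), (m15, enrichment)]
        pe, se = _element_distribution(isotopes, composition[element])
        p_total, s_total = _combine(p_total, s_total, pe, se)

    # drop numerically empty bins at the tails, keep the contiguous support
    nonzero = np.nonzero(p_total > 1e-15)[0]
    lo, hi = nonzero[0], nonzero[-1] + 1
    p_total, s_total = p_total[lo:hi], s_total[lo:hi]

    # most intense contiguous window of at most max_peaks bins
    if len(p_total) > max_peaks:
        window_sums = np.convolve(p_total, np.ones(max_peaks), mode="valid")
        start = int(np.argmax(window_sums))
        stop = start + max_peaks
    else:
        start, stop = 0, len(p_total)
    p_win = p_total[start:stop]
    s_win = s_total[start:stop]
    keep = p_win > 1e-15
    centroid = np.where(keep, s_win, np.nan) / np.where(keep, p_win, 1.0)
    coverage = float(p_win.sum() / p_total.sum())
    intensity = p_win / p_win.sum()
    return IsotopeEnvelope(
        mz=centroid + PROTON_MASS,
        intensity=intensity,
        enrichment=enrichment,
        truncation_mass_count=max_peaks,
        coverage=coverage,
    )
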