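"""Elemental compositions, masses and isotope envelopes.

The envelope convolution is checked against an independent brute-force
oracle that enumerates isotopologues element by element, and masses are
cross-checked against pyteomics.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n15quant.chem import (
    CARBAMIDOMETHYL,
    CompositionError,
    ElementComposition,
    NATURAL_N15,
    PROTON_MASS,
    average_mass,
    composition_of,
    heavy_mass_shift,
    isotope_envelope,
    isotope_table,
    mh_mz,
    monoisotopic_mass,
)

# ---------------------------------------------------------------------------
# brute-force isotopologue oracle


def _partitions(n, k):
    """All ways to put n atoms into k isotope classes."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _partitions(n - first, k - 1):
            yield (first,) + rest


def brute_force_envelope(composition, enrichment=NATURAL_N15, prune=0.0):
    """Exhaustive isotopologue enumeration aggregated on the unit-mass grid.

    Per element, every partition of its atoms over its isotopes is listed
    with its multinomial probability; the cross product over elements gives
    every isotopologue.  ``prune`` drops per-element partitions below a
    probability cutoff (the dropped total is bounded by cutoff x number of
    combinations, used only for large compositions).
    """
    table = isotope_table()
    per_element = []
    for element in sorted(composition.counts):
        isotopes = table[element]
        if element == "N":
            (m14, _), (m15, _) = isotopes
            isotopes = [(m14, 1.0 - enrichment), (m15, enrichment)]
        n = composition[element]
        options = []
        for part in _partitions(n, len(isotopes)):
            p = math.factorial(n)
            mass = 0.0
            for c, (m, a) in zip(part, isotopes):
                p = p // math.factorial(c)
                mass += c * m
            prob = p * math.prod(
                a**c for c, (_, a) in zip(part, isotopes)
            )
            if prob > prune:
                options.append((mass, prob))
        per_element.append(options)

    mono = monoisotopic_mass(composition)
    bins = {}
    for combo in itertools.product(*per_element):
        mass = sum(m for m, _ in combo)
        prob = math.prod(p for _, p in combo)
        k = round(mass - mono)
        acc = bins.setdefault(k, [0.0, 0.0])
        acc[0] += prob
        acc[1] += prob * mass
    return {
        k: (p, s / p) for k, (p, s) in sorted(bins.items()) if p > 0
    }  # offset -> (prob, centroid mass)


def _envelope_bins(env):
    out = {}
    for mz, inten in zip(env.mz, env.intensity):
        out[round(mz)] = (inten, mz - PROTON_MASS)
    return out


# ---------------------------------------------------------------------------
# compositions and masses


@pytest.mark.parametrize(
    "sequence, mods, formula",
    [
        ("G", None, "C2H5N1O2"),
        ("GG", None, "C4H8N2O3"),
        ("C", CARBAMIDOMETHYL, "C5H10N2O3S1"),
    ],
)
def test_composition_examples(sequence, mods, formula):
    assert composition_of(sequence, fixed_mods=mods) == ElementComposition.from_formula(
        formula
    )


def test_composition_nitrogen_count_of_reference_peptide():
    # DVEGPEGFQTR: one backbone N per residue plus Q and R side chains
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    assert comp["N"] == 15
    assert comp["C"] >= 2


def test_unknown_residue_named_with_position():
    with pytest.raises(CompositionError, match=r"'B' at position 3"):
        composition_of("GGBGG")
    with pytest.raises(CompositionError):
        composition_of("")


def test_masses_against_pyteomics_oracle():
    from pyteomics import mass as pmass

    for seq in ["DVEGPEGFQTR", "DRVYIHPF", "GG", "WSLYR", "VGANKFPER"]:
        ours = monoisotopic_mass(composition_of(seq, fixed_mods=None))
        ref = pmass.calculate_mass(sequence=seq)
        assert ours == pytest.approx(ref, abs=1e-5)
    assert monoisotopic_mass(ElementComposition({"H": 2, "O": 1})) == pytest.approx(
        18.010565, abs=1e-6
    )


def test_angiotensin_ii_calibration_mass():
    # MALDI calibration standard, printed m/z 1046.541
    mz = mh_mz(composition_of("DRVYIHPF", fixed_mods=None))
    assert abs(mz - 1046.541) / 1046.541 < 30e-6


def test_average_mass_exceeds_monoisotopic():
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    assert average_mass(comp) > monoisotopic_mass(comp)


# ---------------------------------------------------------------------------
# heavy mass shift


def test_heavy_shift_one_nitrogen():
    assert heavy_mass_shift(ElementComposition({"N": 1, "H": 3})) == pytest.approx(
        0.9970349, abs=1e-6
    )


def test_heavy_shift_reference_peptide():
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    assert heavy_mass_shift(comp) == pytest.approx(15 * 0.9970349, abs=1e-5)
    # partial labeling moves intensity toward lighter isotopologues
    assert heavy_mass_shift(comp, 0.982) < heavy_mass_shift(comp, 1.0)


def test_heavy_shift_rejects_nitrogen_free():
    with pytest.raises(CompositionError):
        heavy_mass_shift(ElementComposition({"C": 2, "H": 6}))


# ---------------------------------------------------------------------------
# isotope envelopes


def test_single_nitrogen_binomial():
    env = isotope_envelope(ElementComposition({"N": 1}), enrichment=0.9)
    assert np.allclose(env.intensity, [0.1, 0.9])


@pytest.mark.parametrize("p", [0.0, 0.5, 0.9, 0.982, 1.0])
def test_envelope_normalization(p):
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    env = isotope_envelope(comp, enrichment=p, max_peaks=60)
    # untruncated distribution retains all probability
    assert env.coverage == pytest.approx(1.0, abs=1e-9)
    assert env.intensity.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.diff(env.mz) > 0)
    spacings = np.diff(env.mz)[np.diff(np.round(env.mz)) == 1]
    assert np.all(np.abs(spacings - 1.0) < 0.01)


def test_full_label_shift_equals_nitrogen_count_times_delta():
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    light = isotope_envelope(comp, enrichment=0.0)
    heavy = isotope_envelope(comp, enrichment=1.0)
    assert heavy.mz[0] - light.mz[0] == pytest.approx(15 * 0.9970349, abs=1e-5)


@pytest.mark.parametrize(
    "formula, p",
    [("C4H8N2O3", NATURAL_N15), ("C4H8N2O3", 0.982), ("N2O3S1", 0.5),
     ("C2H5N1O2", 0.9)],
)
def test_convolution_matches_brute_force_small(formula, p):
    comp = ElementComposition.from_formula(formula)
    assert comp.n_atoms <= 17
    env = isotope_envelope(comp, enrichment=p, max_peaks=60)
    oracle = brute_force_envelope(comp, enrichment=p)
    got = _envelope_bins(env)
    mono = monoisotopic_mass(comp)
    for k, (prob, centroid) in oracle.items():
        if prob < 1e-12:
            continue
        nominal = round(mono + k + PROTON_MASS)
        assert nominal in got
        assert got[nominal][0] == pytest.approx(prob, abs=1e-9)
        assert got[nominal][1] == pytest.approx(centroid, abs=1e-9)


def test_convolution_matches_pruned_enumeration_full_peptide():
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    env = isotope_envelope(comp, enrichment=0.982, max_peaks=60)
    oracle = brute_force_envelope(comp, enrichment=0.982, prune=1e-18)
    got = _envelope_bins(env)
    mono = monoisotopic_mass(comp)
    for k, (prob, _) in oracle.items():
        if prob < 1e-9:
            continue
        nominal = round(mono + k + PROTON_MASS)
        assert got[nominal][0] == pytest.approx(prob, abs=1e-8)


def test_mean_mass_strictly_increasing_in_enrichment():
    comp = composition_of("WSLYR", fixed_mods=None)
    means = []
    for p in [0.0, 0.25, 0.5, 0.75, 0.9, 0.982, 1.0]:
        env = isotope_envelope(comp, enrichment=p, max_peaks=60)
        means.append(float(np.dot(env.mz, env.intensity)))
    assert np.all(np.diff(means) > 0)


def test_truncation_renormalizes_and_keeps_most_intense_window():
    comp = composition_of("DVEGPEGFQTR", fixed_mods=None)
    env = isotope_envelope(comp, enrichment=NATURAL_N15, max_peaks=4)
    assert len(env) == 4
    assert env.intensity.sum() == pytest.approx(1.0, abs=1e-12)
    assert env.coverage > 0.99
    # apex retained
    full = isotope_envelope(comp, enrichment=NATURAL_N15, max_peaks=60)
    assert round(env.mz[env.apex_index]) == round(full.mz[full.apex_index])


def test_envelope_rejections():
    comp = composition_of("GG", fixed_mods=None)
    with pytest.raises(ValueError):
        isotope_envelope(comp, enrichment=1.5)
    with pytest.raises(ValueError):
        isotope_envelope(comp, max_peaks=1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    c=st.integers(0, 4),
    h=st.integers(0, 5),
    n=st.integers(1, 3),
    o=st.integers(0, 3),
    p=st.floats(0.0, 1.0),
)
def test_convolution_equals_enumeration_property(c, h, n, o, p):
    comp = ElementComposition({"C": c, "H": h, "N": n, "O": o})
    env = isotope_envelope(comp, enrichment=p, max_peaks=60)
    oracle = brute_force_envelope(comp, enrichment=p)
    total = sum(prob for prob, _ in oracle.values())
    assert total == pytest.approx(1.0, abs=1e-9)
    got = _envelope_bins(env)
    mono = monoisotopic_mass(comp)
    for k, (prob, _) in oracle.items():
        if prob < 1e-12:
            continue
        assert got[round(mono + k + PROTON_MASS)][0] == pytest.approx(prob, abs=1e-9)
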