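"""q-value algebra, envelope QC, enrichment estimation, positional filters
and aggregation."""

import numpy as np
import pytest

from n15quant.chem import composition_of, isotope_envelope
from n15quant.peaks import (
    PeakList,
    SCHEDULE_ID_48,
    SCHEDULE_QUANT_192,
    GelModel,
    extract_envelope,
)
from n15quant.quant import (
    LibraryEntry,
    PairMeasurement,
    QualityVerdict,
    QuantError,
    aggregate,
    envelope_quality,
    estimate_enrichment,
    fold_change,
    percent_excess,
    positional_filters,
    q_value,
    quantify,
    read_library,
    write_library,
)
from n15quant.settings import Settings
from n15quant.simulate import (
    NoiseModel,
    SimulationConfig,
    simulate_experiment,
)


# ---------------------------------------------------------------------------
# q-value algebra


def test_q_value_basics():
    assert q_value(100.0, 100.0) == 0.5
    assert q_value(20.0, 80.0) == pytest.approx(0.8)
    assert fold_change(0.8) == pytest.approx(4.0)
    assert percent_excess(0.6) == pytest.approx(50.0)
    assert q_value(5.0, 0.0) == 0.0
    assert q_value(0.0, 5.0) == 1.0


def test_q_value_rejections():
    with pytest.raises(QuantError):
        q_value(0.0, 0.0)
    with pytest.raises(QuantError):
        q_value(-1.0, 2.0)
    with pytest.raises(QuantError):
        fold_change(1.2)


# ---------------------------------------------------------------------------
# envelope quality


def _experimental_from(theory_slots, intensities, scale=1.0):
    """Build an ExperimentalEnvelope by extracting a synthetic spectrum whose
    peaks sit exactly on the theory slots with the given intensities."""
    pl = PeakList("s", "r", 0, 0, theory_slots.mz.copy(),
                  np.asarray(intensities) * scale)
    env = extract_envelope(pl, theory_slots, ppm_tol=30.0, min_matched=2)
    assert env is not None
    return env


def test_quality_of_theory_against_itself_passes():
    theo = isotope_envelope(composition_of("DVEGPEGFQTR"), 0.00364)
    env = _experimental_from(theo, theo.intensity)
    verdict = envelope_quality(env, theo, threshold=1e-9)
    assert verdict.passed
    assert verdict.max_difference == pytest.approx(0.0, abs=1e-12)


def test_wrong_enrichment_fails_tight_threshold():
    comp = composition_of("DVEGPEGFQTR")
    theo_982 = isotope_envelope(comp, 0.982)
    theo_900 = isotope_envelope(comp, 0.900)
    # envelope generated at 90% incorporation, tested against 98.2% theory
    n = len(theo_982.mz)
    shape = theo_900.intensity[:n]
    env = _experimental_from(theo_982, shape / shape.sum())
    verdict = envelope_quality(env, theo_982, threshold=0.02)
    assert not verdict.passed
    assert verdict.max_difference > 0.02


def test_quality_invariant_under_uniform_scaling():
    theo = isotope_envelope(composition_of("WSLYR"), 0.982)
    v1 = envelope_quality(_experimental_from(theo, theo.intensity, 1.0), theo, 0.05)
    v2 = envelope_quality(_experimental_from(theo, theo.intensity, 137.0), theo, 0.05)
    assert v1.differences == pytest.approx(v2.differences)
    assert v1.passed == v2.passed


def test_quality_needs_two_adjacent_slots():
    theo = isotope_envelope(composition_of("DVEGPEGFQTR"), 0.00364)
    env = _experimental_from(theo, theo.intensity)
    env.matched[:] = False
    env.matched[theo.apex_index] = True
    with pytest.raises(QuantError):
        envelope_quality(env, theo, 0.05)


# ---------------------------------------------------------------------------
# enrichment estimation


def test_enrichment_self_consistency_noiseless():
    comp = composition_of("DVEGPEGFQTR")
    theo_assumed = isotope_envelope(comp, 0.982)
    truth = isotope_envelope(comp, 0.950)
    pl = PeakList("s", "r", 0, 0, truth.mz.copy(), truth.intensity * 1000)
    env = extract_envelope(pl, theo_assumed, ppm_tol=60.0, min_matched=3,
                           peptide="DVEGPEGFQTR", side="heavy")
    assert env is not None
    est = estimate_enrichment([env])
    assert abs(est.enrichment - 0.950) <= 0.001


def test_grid_recovery_across_range_noiseless():
    comp = composition_of("DVEGPEGFQTR")
    theo_assumed = isotope_envelope(comp, 0.982)
    for p_true in (0.92, 0.95, 0.99):
        truth = isotope_envelope(comp, p_true)
        pl = PeakList("s", "r", 0, 0, truth.mz.copy(), truth.intensity * 1000)
        env = extract_envelope(pl, theo_assumed, ppm_tol=30.0, min_matched=3,
                               peptide="DVEGPEGFQTR", side="heavy")
        est = estimate_enrichment([env])
        assert abs(est.enrichment - p_true) <= 0.001
        assert not est.at_boundary


def test_natural_abundance_input_pins_to_grid_floor():
    # an unlabeled envelope lies entirely outside every labeled window on
    # the grid: the estimate degenerates to the floor and is flagged
    comp = composition_of("DVEGPEGFQTR")
    natural = isotope_envelope(comp, 0.00364)
    pl = PeakList("s", "r", 0, 0, natural.mz.copy(), natural.intensity * 1000)
    env = extract_envelope(pl, natural, ppm_tol=30.0, min_matched=3,
                           peptide="DVEGPEGFQTR", side="heavy")
    assert env is not None
    est = estimate_enrichment([env])
    assert est.enrichment == pytest.approx(0.90)
    assert est.at_boundary
    assert est.n_ratio_pairs == 0


def test_enrichment_requires_envelopes():
    with pytest.raises(QuantError):
        estimate_enrichment([])


# ---------------------------------------------------------------------------
# positional filters


def _measurement(segment=10, fraction=10, q=0.5):
    verdict = QualityVerdict((0.0,), 0.0, True, 0.05)
    return PairMeasurement(
        peptide="PEPTIDEK", accessions=("A",), unique=True,
        spectrum_id="s", run_id="r", gel_segment=segment, lc_fraction=fraction,
        light_sum=50.0, heavy_sum=50.0, q=q,
        light_verdict=verdict, heavy_verdict=verdict,
        overlap=False, uncertain=False,
    )


def _gel():
    # segment i spans [20 + 10i, 30 + 10i) kDa
    return GelModel(tuple((20.0 + 10 * i, 30.0 + 10 * i) for i in range(8)))


def test_gel_filter_monomer_in_window():
    gel = _gel()  # segment 1: 30-40 kDa
    m = _measurement(segment=1)
    entry = LibraryEntry("PEPTIDEK", ("A",), True, gel_segment=1, lc_fraction=10)
    settings = Settings()
    t_id = SCHEDULE_ID_48.time(10)
    idx = SCHEDULE_QUANT_192.index_for_time(t_id)
    m.lc_fraction = idx
    positional_filters(m, entry, {"A": 30.0}, gel, settings)
    assert m.gel_ok and m.elution_ok


def test_gel_filter_dimer_band_accepted():
    gel = _gel()
    # 30 kDa protein seen at 60-70 kDa (segment 4): dimer, k=2
    entry = LibraryEntry("PEPTIDEK", ("A",), True, gel_segment=4, lc_fraction=10)
    m = _measurement(segment=4)
    m.lc_fraction = SCHEDULE_QUANT_192.index_for_time(SCHEDULE_ID_48.time(10))
    positional_filters(m, entry, {"A": 30.0}, gel, Settings())
    assert m.gel_ok
    # without the dimer state it fails
    m2 = _measurement(segment=4)
    m2.lc_fraction = m.lc_fraction
    positional_filters(m2, entry, {"A": 30.0}, gel, Settings(multimers=(1,)))
    assert not m2.gel_ok


def test_gel_filter_segment_neighborhood():
    gel = _gel()
    entry = LibraryEntry("PEPTIDEK", ("A",), True, gel_segment=1, lc_fraction=10)
    t = SCHEDULE_QUANT_192.index_for_time(SCHEDULE_ID_48.time(10))
    near = _measurement(segment=2)
    near.lc_fraction = t
    positional_filters(near, entry, {"A": 35.0}, gel, Settings())
    assert near.gel_ok  # +-1 segment allowed; 35 kDa within the 30-60 union
    far = _measurement(segment=4)
    far.lc_fraction = t
    positional_filters(far, entry, {"A": 30.0}, gel, Settings(multimers=(1,)))
    assert not far.gel_ok


def test_elution_filter_tolerance():
    gel = _gel()
    entry = LibraryEntry("PEPTIDEK", ("A",), True, gel_segment=1, lc_fraction=17)
    t_id = SCHEDULE_ID_48.time(17)  # 40.25 min
    settings = Settings(elution_tol_min=1.5)
    close = _measurement(segment=1)
    close.lc_fraction = SCHEDULE_QUANT_192.index_for_time(t_id + 0.4)
    positional_filters(close, entry, {"A": 30.0}, gel, settings)
    assert close.elution_ok
    late = _measurement(segment=1)
    late.lc_fraction = SCHEDULE_QUANT_192.index_for_time(t_id + 5.0)
    positional_filters(late, entry, {"A": 30.0}, gel, settings)
    assert not late.elution_ok


def test_segment_outside_gel_model_rejected():
    gel = _gel()
    entry = LibraryEntry("PEPTIDEK", ("A",), True, gel_segment=1, lc_fraction=10)
    m = _measurement(segment=20)
    with pytest.raises(Exception):
        positional_filters(m, entry, {"A": 30.0}, gel, Settings())


# ---------------------------------------------------------------------------
# aggregation


def _accepted(peptide, accessions, q, spectrum):
    verdict = QualityVerdict((0.0,), 0.0, True, 0.05)
    return PairMeasurement(
        peptide=peptide, accessions=accessions, unique=len(accessions) == 1,
        spectrum_id=spectrum, run_id="r", gel_segment=0, lc_fraction=0,
        light_sum=100 * (1 - q), heavy_sum=100 * q, q=q,
        light_verdict=verdict, heavy_verdict=verdict,
        overlap=False, uncertain=not 0.2 <= q <= 0.8,
        gel_ok=True, elution_ok=True,
    )


def test_peptide_aggregation_mean_sd_n():
    ms = [_accepted("AK1", ("P",), q, f"s{i}")
          for i, q in enumerate([0.30, 0.29, 0.31])]
    peps, prots = aggregate(ms)
    assert len(peps) == 1
    assert peps[0].mean_q == pytest.approx(0.30)
    assert peps[0].n_spectra == 3
    assert peps[0].sd == pytest.approx(0.01, abs=1e-9)


def test_single_spectrum_sd_is_zero():
    peps, _ = aggregate([_accepted("AK1", ("P",), 0.42, "s0")])
    assert peps[0].sd == 0.0
    assert peps[0].n_spectra == 1


def test_protein_rollup_over_unique_peptides():
    # two unique peptides with means 0.30 and 0.29 -> protein q 0.295
    ms = (
        [_accepted("PEPA", ("P",), q, f"a{i}") for i, q in enumerate([0.30, 0.30])]
        + [_accepted("PEPB", ("P",), q, f"b{i}") for i, q in enumerate([0.29, 0.29])]
        + [_accepted("SHARED", ("P", "Q"), 0.9, "c0")]
    )
    peps, prots = aggregate(ms)
    assert len(prots) == 1  # Q has no unique peptide
    prot = prots[0]
    assert prot.accession == "P"
    assert prot.mean_q == pytest.approx(0.295)
    assert prot.sd == pytest.approx(np.std([0.30, 0.29], ddof=1))
    assert prot.n_unique_peptides == 2
    assert prot.n_spectra == 4


def test_shared_peptides_never_enter_protein_quant():
    ms = [_accepted("SHARED", ("P", "Q"), 0.5, "s0")]
    peps, prots = aggregate(ms)
    assert len(peps) == 1 and not peps[0].unique
    assert prots == []


def test_rejected_measurements_excluded():
    m = _accepted("AK1", ("P",), 0.5, "s0")
    m.gel_ok = False
    peps, prots = aggregate([m])
    assert peps == [] and prots == []


def test_protein_with_one_unique_peptide_reports_spectrum_sd():
    ms = [_accepted("PEPA", ("P",), q, f"s{i}") for i, q in enumerate([0.4, 0.5])]
    _, prots = aggregate(ms)
    assert prots[0].sd == pytest.approx(np.std([0.4, 0.5], ddof=1))


# ---------------------------------------------------------------------------
# measurement-level behavior on simulated data


def test_uncertainty_flag_rule(small_noiseless_experiment):
    exp = small_noiseless_experiment
    res = quantify(exp.library, exp.peaklists, exp.settings,
                   exp.protein_masses_kda, exp.gel_model)
    for m in res.measurements:
        assert m.uncertain == (m.q > 0.8 or m.q < 0.2)


def test_filter_monotonicity_threshold_and_tolerance():
    cfg = SimulationConfig(seed=9, family_size=3, n_background_proteins=1,
                           heavy_fraction=0.5, n_spectra_per_peptide=2,
                           noise=NoiseModel(intensity_cv=0.08, mz_jitter_ppm=8.0),
                           max_library_peptides=15)
    exp = simulate_experiment(cfg)

    def accepted(settings):
        res = quantify(exp.library, exp.peaklists, settings,
                       exp.protein_masses_kda, exp.gel_model)
        return {(m.peptide, m.spectrum_id) for m in res.measurements if m.accepted}

    loose = accepted(exp.settings.replace(ratio_threshold=0.10))
    tight = accepted(exp.settings.replace(ratio_threshold=0.02))
    assert tight <= loose
    wide_t = accepted(exp.settings.replace(elution_tol_min=3.0))
    narrow_t = accepted(exp.settings.replace(elution_tol_min=0.2))
    assert narrow_t <= wide_t


def test_label_swap_antisymmetry_on_accepted_set(small_noiseless_experiment):
    exp = small_noiseless_experiment
    plain = quantify(exp.library, exp.peaklists, exp.settings,
                     exp.protein_masses_kda, exp.gel_model)
    swapped = quantify(exp.library, exp.peaklists,
                       exp.settings.replace(label_swap=True),
                       exp.protein_masses_kda, exp.gel_model)
    q1 = {(m.peptide, m.spectrum_id): m.q for m in plain.measurements if m.accepted}
    q2 = {(m.peptide, m.spectrum_id): m.q for m in swapped.measurements if m.accepted}
    assert set(q1) == set(q2) and q1
    for key in q1:
        assert q1[key] + q2[key] == pytest.approx(1.0, abs=1e-9)


def test_manifest_funnel_counts_non_increasing(small_noiseless_experiment):
    exp = small_noiseless_experiment
    res = quantify(exp.library, exp.peaklists, exp.settings,
                   exp.protein_masses_kda, exp.gel_model)
    c = res.manifest.counts
    assert c["pair_matches"] >= c["pass_quality"] >= \
        c["pass_quality_and_position"] >= c["accepted"]


def test_library_round_trip(tmp_path):
    entries = [
        LibraryEntry("PEPTIDEK", ("A",), True, 3, 17),
        LibraryEntry("SHAREDK", ("A", "B"), False, 4, 20),
    ]
    path = tmp_path / "library.tsv"
    write_library(entries, path)
    assert read_library(path) == entries
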