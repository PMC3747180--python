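import numpy as np
import pytest

from n15quant.simulate import NoiseModel, SimulationConfig, simulate_experiment


@pytest.fixture
def small_noiseless_experiment():
    """A small labeled experiment with noise off: q recovery is exact."""
    config = SimulationConfig(
        seed=42,
        family_size=3,
        n_background_proteins=1,
        heavy_fraction=0.5,
        n_spectra_per_peptide=2,
        noise=NoiseModel.off(),
        max_library_peptides=20,
    )
    return simulate_experiment(config)


@pytest.fixture
def toy_spectrum_peaks():
    """Synthetic peak arrays builder: (mz, intensity) -> PeakList."""
    from n15quant.peaks import PeakList

    def build(mz, intensity, **kwargs):
        meta = dict(
            spectrum_id="s1", run_id="r1", lc_fraction=0, gel_segment=0
        )
        meta.update(kwargs)
        return PeakList(mz=np.asarray(mz), intensity=np.asarray(intensity), **meta)

    return build
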