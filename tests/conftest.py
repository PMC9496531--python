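import numpy as np
import pytest

from liqspec import MixtureSpec, Spectrum, render_spectrum
from liqspec.synth import DEFAULT_GRID


@pytest.fixture
def grid():
    return DEFAULT_GRID.copy()


@pytest.fixture
def lipid_spectrum():
    """Noise-free 1 ug pure-lipid model spectrum on the instrument grid."""
    return render_spectrum(MixtureSpec({"lipid_ester": 1.0}), sample_id="lipid")


def spectrum_with_heights(ch_max, ch_min, amide1, sugar, sample_id="x"):
    """A minimal baseline-corrected spectrum with prescribed heights at the
    four diagnostic wavenumbers (grid points placed exactly there, zero at
    padding points far away)."""
    w = np.array([700.0, 1034.0, 1300.0, 1645.0, 2000.0, 2888.0, 2905.0, 2922.0, 3500.0])
    a = np.array([0.0, sugar, 0.0, amide1, 0.0, ch_min, 0.0, ch_max, 0.0])
    return Spectrum(w, a, sample_id=sample_id, baseline_corrected=True)


@pytest.fixture
def make_scored_spectrum():
    return spectrum_with_heights
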