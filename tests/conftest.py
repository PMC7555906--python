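from __future__ import annotations

import pytest

from bloodpmf.spectrum_io import Peak, PeakList, filter_snr, restrict_range

# Synthetic protein contexts that release the diagnostic tryptic peptides as
# 0-missed-cleavage products (preceded by K, followed by a non-P residue).
CHICKEN_GAPDH_CONTEXT = "MAKLVSWYDNEFGYSNRSAK"
MAMMAL_GAPDH_CONTEXT = "MAKLISWYDNEFGYSNRSAK"
BETA_GLOBIN_CONTEXT = "MAKLLVVYPWTQRSAK"
ALPHA_GLOBIN_CONTEXT = "MAKVGGHAAEYGAEALERSAK"


def make_peaklist(
    mzs,
    sample_id: str = "test",
    intensity: float = 100.0,
    snr: float = 50.0,
) -> PeakList:
    """A preprocessed peak list with one peak per m/z value."""
    pl = PeakList(
        sample_id=sample_id,
        peaks=tuple(Peak(m, intensity, snr) for m in mzs),
    )
    return restrict_range(filter_snr(pl, 10.0), 600.0, 2000.0)


@pytest.fixture
def preprocessed_peaklist():
    return make_peaklist
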