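import numpy as np
import pytest

import granametry as g
from granametry.pipeline import roi_for_record

DARK_GAP, DARK_LM = 4.68, 12.22
LIGHT_GAP, LIGHT_LM = 4.20, 15.68


@pytest.fixture(scope="session")
def dark_geometry():
    return g.make_grana_truth(gap_nm=DARK_GAP, lm_nm=DARK_LM, n_layers=10,
                              diameter_nm=200.0)


@pytest.fixture(scope="session")
def clean_options():
    return g.RenderOptions(nm_per_px=0.5, psf_sigma_px=0.0, noise_model="none")


@pytest.fixture(scope="session")
def study_options():
    """Imaging conditions used throughout: 0.5 nm/px, PSF sigma 2 px, SNR 5."""
    return g.RenderOptions(nm_per_px=0.5, psf_sigma_px=2.0,
                           noise_model="poisson_gaussian", snr=5.0, seed=7)


@pytest.fixture(scope="session")
def dark_stack(dark_geometry, study_options):
    """One realistic dark-adapted granum image with its truth record and ROI."""
    img, rec = g.render_grana(dark_geometry, study_options, condition="dark")
    return img, rec, roi_for_record(rec, img)


@pytest.fixture(scope="session")
def clean_stack(dark_geometry, clean_options):
    img, rec = g.render_grana(dark_geometry, clean_options)
    return img, rec, roi_for_record(rec, img)


def column_run_lengths(column: np.ndarray, level: float):
    """Brute-force oracle: run lengths of above-level samples in a column."""
    above = column > level
    padded = np.r_[0, above.astype(int), 0]
    idx = np.flatnonzero(np.diff(padded))
    starts, stops = idx[0::2], idx[1::2]
    return stops - starts, starts
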