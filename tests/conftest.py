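import numpy as np
import pytest

import franzq as fq


# Table-shaped reference data used across tests: printed mass pairs and
# recoveries from the assay verification, and the six commercial patches'
# determined/labeled contents with their tabulated differences.
RECOVERY_ROWS = [
    # (calculated_mg, known_mg, printed_recovery_percent)
    (40.9, 43.1, 94.9),
    (35.2, 33.3, 105.7),
    (40.4, 36.6, 110.6),
    (34.0, 35.9, 94.7),
    (32.5, 33.8, 96.1),
]
PRINTED_RECOVERIES = [row[2] for row in RECOVERY_ROWS]

PATCH_ROWS = [
    # (brand, determined_mg, labeled_mg, tabulated_diff_percent)
    ("A", 27.7, 40.0, -36),
    ("B", 45.9, 40.0, 14),
    ("C 50 mg", 67.8, 50.0, 30),
    ("C 75 mg", 104.3, 75.0, 33),
    ("C 100 mg", 135.3, 100.0, 30),
    ("D", 36.0, 36.0, 0),
]

FRANZ_SCHEDULE_H = (4.0, 12.0, 24.0, 36.0, 48.0)


@pytest.fixture
def assay():
    """Whole-patch assay: 10 mg naphthalene calibrant."""
    return fq.default_assay(10.0)


@pytest.fixture
def franz_assay():
    """Franz-disc assay: 1 mg naphthalene calibrant."""
    return fq.default_franz_assay()


@pytest.fixture
def patch():
    return fq.PatchSpec(brand="D", labeled_mg=36.0, patch_area_cm2=41.9)


def make_profile(model_id, params, times=FRANZ_SCHEDULE_H, m0_mg=100.0, patch=None):
    """Release profile generated exactly from a kinetic law (no noise)."""
    pct = fq.predict_release_percent(model_id, params, times)
    return fq.profile_from_release_percent(times, pct, m0_mg=m0_mg, patch=patch)


def quantify_series(spectra, assay):
    """Remaining-mass observations from a list of Franz-cell spectra."""
    return [
        fq.ReleaseObservation(
            float(s.meta["time_h"]),
            fq.quantify_mass(
                fq.integral_ratio(s, assay.analyte.window, assay.calibrant.window),
                assay,
            ),
            replicate=str(s.meta.get("sample_id")),
        )
        for s in spectra
    ]


def fit_series_higuchi(spectra, truth, assay, patch_spec=None):
    """Full pipeline from simulated spectra to the fitted Higuchi model."""
    obs = quantify_series(spectra, assay)
    if patch_spec is None:
        patch_spec = fq.PatchSpec(brand="sim", labeled_mg=truth.initial_mg,
                                  patch_area_cm2=1.0)
    profile = fq.build_release_profile(truth.initial_mg, obs, patch_spec)
    return fq.fit_model(profile, "higuchi")


@pytest.fixture
def higuchi_profile():
    return make_profile("higuchi", {"KH": 14.3, "c": 0.0})
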