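"""Shared fixtures: bundled instrument sets, toy set builder, frozen values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from targetmr import HarmonizedSet, load_ovarian_instruments

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: IVW odds ratios as published for the 11 targets.  The CASP3 entry is the
#: value implied by the published confidence interval and p-value (their
#: geometric CI midpoint, 0.999272957); the separately printed CASP3 point
#: estimate (0.999417702) is inconsistent with both and is an evident typo.
PUBLISHED_IVW_OR = {
    "FNTA": 0.714571216,
    "HSPA5": 0.997892376,
    "NEU1": 0.996386436,
    "CCND1": 0.996798602,
    "CASP1": 0.914123044,
    "CASP3": 0.999272957,
    "HMGCR": 1.131314709,
    "PLA2G4A": 1.097906571,
    "ITGAL": 1.001353198,
    "PTGS1": 1.002096738,
    "FNTB": 1.000560816,
}

PUBLISHED_FNTA_CI = (0.597682908, 0.854319265)

EXPECTED_COUNTS = {
    "CASP1": 7, "FNTA": 4, "HMGCR": 5, "PLA2G4A": 6, "CASP3": 11,
    "CCND1": 9, "FNTB": 9, "HSPA5": 4, "ITGAL": 10, "NEU1": 4, "PTGS1": 8,
}

NEGATIVE_TARGETS = {"FNTA", "HSPA5", "NEU1", "CCND1", "CASP1", "CASP3"}
POSITIVE_TARGETS = {"HMGCR", "PLA2G4A", "ITGAL", "PTGS1", "FNTB"}


def make_hset(bx, by, sy, sx=None, target="toy", outcome_id="toy-outcome"):
    """Build a HarmonizedSet from plain effect arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    rows = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(len(bx))],
            "beta_exposure": bx,
            "se_exposure": sx,
            "p_exposure": np.full_like(bx, 1e-10),
            "beta_outcome": by,
            "se_outcome": sy,
            "p_outcome": np.full_like(bx, 0.5),
            "r2_exposure": np.nan,
            "f_stat": np.nan,
        }
    )
    return HarmonizedSet(target=target, rows=rows, outcome_id=outcome_id)


@pytest.fixture(scope="session")
def all_sets():
    return load_ovarian_instruments("all")


@pytest.fixture(scope="session")
def fnta(all_sets):
    return all_sets["FNTA"]
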