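"""Shared fixtures: bundled evidence-base files and structural networks.

The bundled CSVs carry only numbers printed in the source publication's
text.  The structural fixtures below reproduce the trial layout of the two
haemoglobin networks (trial names, arms, population tags) with synthetic
effect estimates, since the per-trial inputs were published only in
supplementary tables; they are used for graph-shape and filtering tests,
never for numerical acceptance checks.
"""

import numpy as np
import pytest

from hifnma import (
    DEFAULT_OUTCOMES,
    TrialContrast,
    bundled_path,
    load_analysis_sets,
)


@pytest.fixture(scope="session")
def analysis_sets():
    return load_analysis_sets(bundled_path("analysis_sets.yaml"))


@pytest.fixture(scope="session")
def nd_mace_path():
    return bundled_path("nd_mace.csv")


@pytest.fixture(scope="session")
def nd_sf36_path():
    return bundled_path("nd_sf36.csv")


@pytest.fixture(scope="session")
def dialysis_hgb_path():
    return bundled_path("dialysis_hgb.csv")


def _contrast(trial, treat, comp, outcome, est, se, tags):
    """Synthetic contrast with a CI consistent with the given SE."""
    from hifnma import se_to_ci

    scale = DEFAULT_OUTCOMES[outcome].analysis_scale
    y = np.log(est) if scale == "log" else est
    lo, hi = se_to_ci(se, y, scale)
    return TrialContrast(
        trial_id=trial,
        treatment=treat,
        comparator=comp,
        outcome_id=outcome,
        estimate=est,
        ci_lower=lo,
        ci_upper=hi,
        population_tags=frozenset(tags),
    )


@pytest.fixture(scope="session")
def nd_hgb_trials():
    """Non-dialysis Hgb evidence base: 4 trials, darbepoetin-centred star.

    Trial names and population tags follow the published evidence base;
    the effect estimates are synthetic.
    """
    return [
        _contrast("ASCEND-ND", "daprodustat", "darbepoetin", "hgb_cfb",
                  0.10, 0.05, {"all", "esa_nonuser", "esa_user"}),
        _contrast("DOLOMITES", "roxadustat", "darbepoetin", "hgb_cfb",
                  0.02, 0.11, {"all", "esa_nonuser"}),
        _contrast("PRO2TECT-CORRECTION", "vadadustat", "darbepoetin", "hgb_cfb",
                  0.01, 0.05, {"all", "esa_nonuser"}),
        _contrast("PRO2TECT-CONVERSION", "vadadustat", "darbepoetin", "hgb_cfb",
                  0.02, 0.04, {"all", "esa_user"}),
    ]


@pytest.fixture(scope="session")
def dialysis_trials():
    """Dialysis evidence base: 9 active-controlled trials, ESA-centred star.

    Trial names and prevalent/incident tags follow the published evidence
    base (incident-only: ASCEND-ID, HIMALAYAS, INNO2VATE-ID); comparator ESA
    labels and effect estimates are synthetic.
    """
    rows = [
        ("ASCEND-D", "daprodustat", "epoetin", 0.15, 0.05, {"all", "prevalent"}),
        ("ASCEND-TD", "daprodustat", "epoetin", 0.20, 0.09, {"all", "prevalent"}),
        ("ASCEND-ID", "daprodustat", "darbepoetin", 0.10, 0.10, {"all", "incident"}),
        ("ROCKIES", "roxadustat", "epoetin", 0.22, 0.06, {"all", "prevalent"}),
        ("SIERRAS", "roxadustat", "epoetin", 0.18, 0.07, {"all", "prevalent"}),
        ("PYRENEES", "roxadustat", "darbepoetin", 0.21, 0.08, {"all", "prevalent"}),
        ("HIMALAYAS", "roxadustat", "epoetin", 0.16, 0.08, {"all", "incident"}),
        ("INNO2VATE-PD", "vadadustat", "darbepoetin", -0.15, 0.06, {"all", "prevalent"}),
        ("INNO2VATE-ID", "vadadustat", "darbepoetin", -0.20, 0.07, {"all", "incident"}),
    ]
    return [_contrast(t, a, c, "hgb_cfb", e, s, tags) for t, a, c, e, s, tags in rows]


def make_nma_data(contrasts):
    """(y, se, treatment, comparator) rows on the analysis scale."""
    from hifnma import to_analysis_scale

    return [
        (*to_analysis_scale(c, DEFAULT_OUTCOMES[c.outcome_id]),
         c.treatment, c.comparator)
        for c in contrasts
    ]
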