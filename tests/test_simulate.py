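import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from casco import (
    CohortParams,
    SimulationError,
    cronbach_alpha,
    inject_missing,
    score_cohort,
    simulate_cohort,
)
from casco.simulate import maskable_columns


def test_seed_determinism():
    a = simulate_cohort(CohortParams(seed=7))
    b = simulate_cohort(CohortParams(seed=7))
    pd.testing.assert_frame_equal(a, b)
    c = simulate_cohort(CohortParams(seed=8))
    assert not a.equals(c)


def test_default_structure(default_cohort):
    assert len(default_cohort) == 186 + 95
    assert (default_cohort["group"] == "cancer").sum() == 186
    assert set(default_cohort["ecog"].unique()) <= set(range(5))
    assert default_cohort["clinician_rating"].between(0, 10).all()
    # controls carry ECOG 0 as in the study population
    assert (default_cohort.loc[default_cohort["group"] == "control", "ecog"] == 0).all()


def test_infeasible_targets_rejected():
    with pytest.raises(SimulationError):
        simulate_cohort(CohortParams(cancer_mean=150.0))
    with pytest.raises(SimulationError):
        simulate_cohort(CohortParams(control_sd=-1.0))


def test_noise_free_limit_total_is_monotone_in_severity(casco_inst):
    """With loading 1 and zero link noise the score is a deterministic
    monotone function of the latent severity."""
    cohort = simulate_cohort(
        CohortParams(seed=4, item_loading=1.0, marker_noise=0.0, missing_rate=0.0)
    )
    scores = score_cohort(cohort, casco_inst)
    order = np.argsort(cohort["severity"].to_numpy())
    totals = scores["total"].to_numpy()[order]
    assert (np.diff(totals) >= -1e-9).all()
    rho = stats.spearmanr(cohort["severity"], scores["total"]).statistic
    assert rho >= 0.95  # ties from ordinal quantisation keep it below 1


def test_mean_score_increases_across_severity_quartiles(casco_inst, default_cohort):
    scores = score_cohort(default_cohort, casco_inst)
    quartile = pd.qcut(default_cohort["severity"], 4, labels=False)
    means = scores["total"].groupby(quartile).mean()
    assert means.is_monotonic_increasing


def test_alpha_increases_with_item_loading():
    qol = [f"qol{i}" for i in range(1, 26)]
    alphas = []
    for loading in (0.3, 0.6, 0.9):
        cohort = simulate_cohort(
            CohortParams(seed=2, item_loading=loading, missing_rate=0.0)
        )
        alphas.append(cronbach_alpha(cohort[qol]).alpha)
    assert alphas[0] < alphas[1] < alphas[2]


def test_inject_missing_rates(default_cohort):
    clean = simulate_cohort(CohortParams(seed=3, missing_rate=0.0))
    same = inject_missing(clean, 0.0, seed=1)
    pd.testing.assert_frame_equal(clean, same)
    cols = maskable_columns(clean)
    full = inject_missing(clean, 1.0, seed=1)
    assert full[cols].isna().all().all()
    masked = inject_missing(clean, 0.05, seed=1)
    frac = masked[cols].isna().to_numpy().mean()
    n_cells = masked[cols].size
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_cells)  # binomial 99%
    assert abs(frac - 0.05) <= half_width
    # ids and groups never masked
    assert masked["subject_id"].notna().all() and masked["group"].notna().all()


def test_criterion_rank_correlation_recovery():
    """Severity-ECOG rank correlation recovers the generator parameter."""
    rhos = []
    for seed in range(25):
        cohort = simulate_cohort(CohortParams(seed=seed, criterion_rho=0.4))
        patients = cohort[cohort["group"] == "cancer"]
        rhos.append(
            stats.spearmanr(patients["severity"], patients["ecog"]).statistic
        )
    assert abs(np.mean(rhos) - 0.4) <= 0.15
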