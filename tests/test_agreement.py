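"""Reliability/agreement statistics against hand-computed and library oracles."""

import itertools
import math

import numpy as np
import pytest

from vo2row import (
    MethodPairs,
    MethodPairsSpec,
    bland_altman,
    build_agreement_report,
    cv_percent,
    generate_method_pairs,
    icc_consistency,
    ks_two_sample,
    rc,
    sem,
)
from vo2row.agreement import REPORT_ROW_LABELS, report_rows, two_way_anova


@pytest.fixture
def six_pairs() -> MethodPairs:
    return MethodPairs(
        measured=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        predicted=np.array([2.0, 1.0, 6.0, 5.0, 10.0, 9.0]),
    )


def hand_anova(measured, predicted):
    """Explicit sums-of-squares two-way ANOVA, written independently."""
    n = len(measured)
    k = 2
    data = [[m, p] for m, p in zip(measured, predicted)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(d[j] for d in data) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((v - grand) ** 2 for row in data for v in row)
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1)), grand


# ---------------------------------------------------------------------- ICC

def test_perfect_agreement_gives_icc_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = icc_consistency(MethodPairs(measured=x, predicted=x.copy()))
    assert res.icc == 1.0


@pytest.mark.parametrize("offset", [50.0, -123.4, 1e4])
def test_consistency_icc_ignores_constant_offset(offset):
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = icc_consistency(MethodPairs(measured=x, predicted=x + offset))
    assert res.icc == pytest.approx(1.0, abs=1e-12)


def test_icc_matches_hand_anova_oracle(six_pairs):
    msr, _, mse, _ = hand_anova(six_pairs.measured, six_pairs.predicted)
    expected = (msr - mse) / (msr + mse)
    res = icc_consistency(six_pairs)
    assert res.icc == pytest.approx(expected, abs=1e-9)
    assert res.anova_f == pytest.approx(msr / mse, abs=1e-9)


def test_icc_matches_pingouin_icc3():
    """Cross-check against an independent ICC implementation."""
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(5)
    measured = rng.normal(3900, 400, size=25)
    predicted = measured + rng.normal(-30, 90, size=25)
    pairs = MethodPairs(measured=measured, predicted=predicted)
    res = icc_consistency(pairs)

    long = pd.DataFrame(
        {
            "subject": list(range(25)) * 2,
            "rater": ["measured"] * 25 + ["predicted"] * 25,
            "score": np.concatenate([measured, predicted]),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    icc3 = table.loc["ICC(C,1)"] if "ICC(C,1)" in table.index else table.loc["ICC3"]
    assert res.icc == pytest.approx(float(icc3["ICC"]), abs=1e-9)
    assert res.anova_f == pytest.approx(float(icc3["F"]), abs=1e-9)
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = icc3[ci_col]  # pingouin rounds the CI to 2 decimals
    assert res.ci_low == pytest.approx(float(lo), abs=6e-3)
    assert res.ci_high == pytest.approx(float(hi), abs=6e-3)


def test_icc_requires_between_subject_variance():
    flat = MethodPairs(
        measured=np.array([5.0, 5.0, 5.0]), predicted=np.array([5.0, 5.0, 5.0])
    )
    with pytest.raises(ValueError, match="between-subject"):
        icc_consistency(flat)


def test_icc_decreases_monotonically_with_added_noise():
    """Scaling a fixed noise vector up strictly degrades consistency."""
    rng = np.random.default_rng(11)
    measured = rng.normal(3900, 500, size=400)
    z = rng.normal(size=400)
    iccs = []
    for sd in np.linspace(10, 600, 20):
        pairs = MethodPairs(measured=measured, predicted=measured + sd * z)
        iccs.append(icc_consistency(pairs).icc)
    assert all(a > b for a, b in zip(iccs, iccs[1:]))


# ---------------------------------------------------------------------- SEM

@pytest.mark.parametrize(
    "sd,icc_val,expected",
    [(709.47, 0.980, 100.33), (600.16, 0.985, 73.50)],
)
def test_sem_reproduces_published_values(sd, icc_val, expected):
    assert sem(sd, icc_val) == pytest.approx(expected, abs=0.01)


def test_sem_zero_at_perfect_icc_and_monotone():
    assert sem(500.0, 1.0) == 0.0
    values = [sem(500.0, i) for i in np.linspace(0.0, 1.0, 11)]
    assert all(a > b for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        sem(500.0, 1.1)


# ----------------------------------------------------------------------- CV

def test_cv_zero_for_identical_series():
    x = np.array([3.0, 4.0, 5.0])
    assert cv_percent(MethodPairs(measured=x, predicted=x.copy())) == 0.0


def test_cv_scale_invariance(six_pairs):
    doubled = MethodPairs(
        measured=2 * six_pairs.measured, predicted=2 * six_pairs.predicted
    )
    assert cv_percent(doubled) == pytest.approx(cv_percent(six_pairs), rel=1e-12)


def test_cv_matches_hand_anova_oracle(six_pairs):
    _, _, mse, grand = hand_anova(six_pairs.measured, six_pairs.predicted)
    assert cv_percent(six_pairs) == pytest.approx(
        math.sqrt(mse) / grand * 100, abs=1e-9
    )


# -------------------------------------------------------------- Bland–Altman

def pairs_with_sd_diff(sd: float, mean_diff: float = 0.0, n: int = 2) -> MethodPairs:
    """Two-point series whose sample SD of differences is exactly ``sd``."""
    measured = np.array([1000.0, 1000.0])
    predicted = measured + np.array([mean_diff - sd / math.sqrt(2),
                                     mean_diff + sd / math.sqrt(2)])
    return MethodPairs(measured=measured, predicted=predicted)


@pytest.mark.parametrize(
    "sd,rc_expected,width_expected",
    [(56.58, 156.83, 221.79), (64.32, 178.286, 252.13), (63.84, 176.96, 250.25),
     (53.61, 148.60, 210.15)],
)
def test_rc_and_width_closed_forms(sd, rc_expected, width_expected):
    res = bland_altman(pairs_with_sd_diff(sd))
    assert res.rc == pytest.approx(rc_expected, abs=0.01)
    assert res.loa_width == pytest.approx(width_expected, abs=0.01)
    assert rc(sd) == pytest.approx(rc_expected, abs=0.01)


def test_identical_series_collapse_to_zero():
    x = np.array([3.0, 4.0, 5.0])
    res = bland_altman(MethodPairs(measured=x, predicted=x.copy()))
    assert res.mean_diff == res.sd_diff == res.loa_width == res.rc == 0.0


def test_limits_and_cis_are_centered_on_mean_diff():
    pairs = generate_method_pairs(
        MethodPairsSpec(n=200, bias=-29.12, sd_diff=63.84, seed=13)
    )
    res = bland_altman(pairs)
    assert res.loa_low == pytest.approx(res.mean_diff - 1.96 * res.sd_diff)
    assert res.loa_high == pytest.approx(res.mean_diff + 1.96 * res.sd_diff)
    assert res.ciloa_low[0] < res.loa_low < res.ciloa_low[1]
    assert res.ciloa_high[0] < res.loa_high < res.ciloa_high[1]
    assert res.sel == pytest.approx(res.sd_diff * math.sqrt(3 / 200))


def test_sel_legacy_variant():
    pairs = pairs_with_sd_diff(50.0)
    legacy = bland_altman(pairs, sel_variant="legacy")
    assert legacy.sel == pytest.approx(math.sqrt(3) * legacy.sd_diff / (2 - 1))
    with pytest.raises(ValueError, match="sel_variant"):
        bland_altman(pairs, sel_variant="bogus")


def test_rc_width_ratio_identity():
    """rc/width ≡ √2/2 for any positive SD of differences."""
    for sd in (0.1, 1.0, 17.3, 56.58, 1e4):
        res = bland_altman(pairs_with_sd_diff(sd))
        assert res.rc / res.loa_width == pytest.approx(math.sqrt(2) / 2, rel=1e-12)


def test_rc_rejects_negative_input():
    with pytest.raises(ValueError):
        rc(-1.0)


def test_sample_diff_moments_converge_to_generating_parameters():
    pairs = generate_method_pairs(
        MethodPairsSpec(n=100_000, bias=-25.52, sd_diff=64.32, seed=21)
    )
    res = bland_altman(pairs)
    se_mean = 64.32 / math.sqrt(100_000)
    se_sd = 64.32 / math.sqrt(2 * 100_000)
    assert abs(res.mean_diff - (-25.52)) < 3 * se_mean
    assert abs(res.sd_diff - 64.32) < 3 * se_sd


# ------------------------------------------------------------------------ KS

def test_ks_identical_samples():
    x = [1.0, 2.0, 3.0]
    res = ks_two_sample(x, x)
    assert res.d == 0.0 and res.p_value == 1.0


def test_ks_disjoint_supports():
    res = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert res.d == 1.0


def naive_ks_enumeration(x, y):
    """Brute-force oracle: D and permutation p by explicit looping."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def ecdf_d(a, b):
        pts = sorted(a) + sorted(b)
        return max(
            abs(sum(v <= t for v in a) / len(a) - sum(v <= t for v in b) / len(b))
            for t in pts
        )

    d_obs = ecdf_d(list(x), list(y))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if ecdf_d(a, b) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


@pytest.mark.parametrize(
    "x,y",
    [
        ([1.0, 2.0], [1.5, 2.5]),
        ([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5]),
        ([0.1, 0.5, 0.9, 1.3, 2.0], [0.2, 0.4, 1.1, 1.9, 2.4]),
        ([1.0, 1.0, 2.0], [1.0, 3.0]),  # ties across samples
    ],
)
def test_ks_exact_matches_brute_force_enumeration(x, y):
    """Exact small-sample p agrees with an independent naive enumeration."""
    res = ks_two_sample(x, y, method="exact")
    d_oracle, p_oracle = naive_ks_enumeration(x, y)
    assert res.d == pytest.approx(d_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_ks_exact_agrees_with_scipy_where_available():
    from scipy import stats

    x, y = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5]
    res = ks_two_sample(x, y, method="exact")
    oracle = stats.ks_2samp(x, y, method="exact")
    assert res.d == pytest.approx(oracle.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-9)


def test_ks_asymptotic_for_large_samples():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    y = rng.normal(0.2, 1.0, size=80)
    res = ks_two_sample(x, y)
    assert res.method == "asymp"
    en = 60 * 80 / 140
    from scipy import special

    assert res.p_value == pytest.approx(
        float(special.kolmogorov(math.sqrt(en) * res.d)), abs=1e-12
    )


def test_ks_d_invariant_under_monotone_transforms():
    rng = np.random.default_rng(8)
    x = rng.normal(size=15)
    y = rng.normal(0.5, 1.2, size=12)
    base = ks_two_sample(x, y).d
    for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
        assert ks_two_sample(f(x), f(y)).d == pytest.approx(base, abs=1e-12)


def test_ks_empty_series_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


# ------------------------------------------------------------------- reports

def test_perfect_agreement_report_is_all_zero_error():
    x = np.array([3000.0, 3500.0, 4000.0, 4500.0])
    report = build_agreement_report(MethodPairs(measured=x, predicted=x.copy()))
    assert report.icc.icc == 1.0
    assert report.sem == 0.0
    assert report.cv_pct == 0.0
    assert report.bland_altman.rc == 0.0
    assert report.ks.d == 0.0


def test_report_internal_consistency_identities():
    pairs = generate_method_pairs(
        MethodPairsSpec(n=13, bias=-29.12, sd_diff=63.84, seed=77)
    )
    report = build_agreement_report(pairs)
    ba = report.bland_altman
    assert ba.loa_width == pytest.approx(2 * 1.96 * ba.sd_diff, rel=1e-12)
    assert ba.rc / ba.loa_width == pytest.approx(math.sqrt(2) / 2, rel=1e-12)
    assert report.grand_mean == pytest.approx(
        (report.measured_mean + report.predicted_mean) / 2, rel=1e-12
    )


def test_report_fields_match_individual_oracles(six_pairs):
    report = build_agreement_report(six_pairs)
    assert report.icc.icc == pytest.approx(icc_consistency(six_pairs).icc, abs=1e-12)
    assert report.cv_pct == pytest.approx(cv_percent(six_pairs), abs=1e-12)
    ba = bland_altman(six_pairs)
    assert report.bland_altman == ba
    pooled = six_pairs.pooled()
    assert report.sem == pytest.approx(
        sem(float(np.std(pooled, ddof=1)), report.icc.icc), abs=1e-12
    )
    assert report.ks.d == pytest.approx(
        ks_two_sample(six_pairs.measured, six_pairs.predicted).d, abs=1e-12
    )


def test_report_row_labels_are_stable(six_pairs):
    labels = [lab for lab, _ in report_rows(build_agreement_report(six_pairs))]
    assert tuple(labels) == REPORT_ROW_LABELS
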