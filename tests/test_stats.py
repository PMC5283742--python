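"""Effect sizes, magnitude bands, MBI labels, correlations, efficacy."""

import math

import numpy as np
import pytest

from pitchnet.stats import (EffectError, cohen_d_pooled, efficacy,
                            magnitude_of_d, magnitude_of_r, mbi_band_label,
                            mbi_label_from, pearson_ci, percent_difference)


# -- standardized differences -----------------------------------------------

def test_identical_groups_trivial_null():
    res = cohen_d_pooled([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.d == 0.0
    assert res.magnitude == "trivial"


def test_pooled_d_hand_computation():
    """Groups engineered to mean 10/12, sd 2, n 10 each: d = 1.0 exactly."""
    rng = np.random.default_rng(0)
    a = rng.standard_normal(10)
    a = (a - a.mean()) / a.std(ddof=1) * 2.0 + 10.0  # mean 10, sd 2
    b = (a - 10.0) + 12.0                            # mean 12, sd 2
    res = cohen_d_pooled(a, b)
    assert res.d == pytest.approx(1.0, abs=1e-12)
    assert res.magnitude == "moderate"  # 0.6 < |d| <= 1.2
    # SE formula: sqrt(1/nA + 1/nB + d^2/(2(nA+nB)))
    assert res.se == pytest.approx(math.sqrt(0.1 + 0.1 + 1.0 / 40.0))
    assert res.ci90[0] < res.d < res.ci90[1]


def test_d_antisymmetric_under_group_swap():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 9)
    assert cohen_d_pooled(a, b).d == pytest.approx(-cohen_d_pooled(b, a).d)


def test_zero_variance_unequal_means_errors():
    with pytest.raises(EffectError):
        cohen_d_pooled([1.0, 1.0], [2.0, 2.0])


def test_small_group_errors():
    with pytest.raises(EffectError):
        cohen_d_pooled([1.0], [1.0, 2.0])


@pytest.mark.parametrize("d,label", [
    (0.0, "trivial"), (0.2, "trivial"), (0.21, "small"), (0.6, "small"),
    (0.61, "moderate"), (1.2, "moderate"), (1.21, "large"), (2.0, "large"),
    (2.01, "very large"), (-0.7, "moderate"),
])
def test_d_magnitude_bands(d, label):
    assert magnitude_of_d(d) == label


@pytest.mark.parametrize("r,label", [
    (0.05, "trivial"), (0.1, "trivial"), (0.11, "small"), (0.3, "small"),
    (0.44, "moderate"), (0.5, "moderate"), (0.51, "large"), (0.7, "large"),
    (0.71, "very large"), (0.9, "very large"), (0.95, "almost perfect"),
    (-0.44, "moderate"),
])
def test_r_magnitude_bands(r, label):
    assert magnitude_of_r(r) == label


# -- percent differences ----------------------------------------------------

def test_percent_difference_null():
    a = np.array([2.0, 4.0, 6.0])
    assert percent_difference(a, a).pct_diff == pytest.approx(0.0)


def test_percent_difference_exact_ratio():
    a = np.array([10.0, 20.0, 5.0, 8.0])
    res = percent_difference(a, 1.2 * a)
    assert res.pct_diff == pytest.approx(20.0, abs=1e-9)


def test_percent_difference_hand_oracle():
    """Log-scale pooled-t interval computed by hand for two small lists."""
    a, b = np.array([10.0, 12.0, 14.0]), np.array([13.0, 15.0, 18.0])
    la, lb = np.log(a), np.log(b)
    diff = lb.mean() - la.mean()
    sp = math.sqrt((la.var(ddof=1) + lb.var(ddof=1)) / 2.0)
    se = sp * math.sqrt(2.0 / 3.0)
    from scipy.stats import t
    tc = t.ppf(0.95, df=4)
    res = percent_difference(a, b)
    assert res.pct_diff == pytest.approx(100 * (math.exp(diff) - 1))
    assert res.pct_ci90[0] == pytest.approx(100 * (math.exp(diff - tc * se) - 1))
    assert res.pct_ci90[1] == pytest.approx(100 * (math.exp(diff + tc * se) - 1))
    assert res.pct_limit == pytest.approx(100 * (math.exp(tc * se) - 1))


def test_percent_difference_ratio_inversion():
    a = np.array([3.0, 5.0, 9.0, 4.0])
    b = np.array([4.0, 7.0, 10.0, 6.0])
    p_ab = percent_difference(a, b).pct_diff
    p_ba = percent_difference(b, a).pct_diff
    assert (1 + p_ab / 100.0) * (1 + p_ba / 100.0) == pytest.approx(1.0)


def test_percent_difference_rejects_nonpositive():
    with pytest.raises(EffectError):
        percent_difference([0.0, 1.0], [1.0, 2.0])


# -- magnitude-based inference ----------------------------------------------

def test_mbi_clear_positive_very_likely():
    """d=1.0 with ci90=[0.5, 1.5]: P(d > +0.2) > 0.95 under the normal."""
    se = 0.5 / 1.6449  # implied by the interval half-width
    label, direction, probs = mbi_label_from(1.0, se, (0.5, 1.5))
    assert direction == "positive"
    assert probs["positive"] > 0.95
    assert label in ("very likely", "most likely")


def test_mbi_unclear_when_ci_spans_both_swd():
    label, direction, _ = mbi_label_from(0.05, 0.27, (-0.4, 0.5))
    assert label == "unclear" and direction == "unclear"


@pytest.mark.parametrize("p,label", [
    (0.10, None), (0.25, "possible"), (0.60, "possible"), (0.75, "possible"),
    (0.80, "likely"), (0.95, "likely"), (0.96, "very likely"),
    (0.99, "very likely"), (0.995, "most likely"),
])
def test_mbi_probability_bands(p, label):
    assert mbi_band_label(p) == label


def test_mbi_probabilities_sum_to_one():
    rng = np.random.default_rng(2)
    for _ in range(20):
        d, se = rng.normal(0, 1), rng.uniform(0.05, 1.0)
        _, _, probs = mbi_label_from(d, se, (d - 1.6 * se, d + 1.6 * se), df=18)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


def test_mbi_invalid_swd():
    with pytest.raises(EffectError):
        mbi_label_from(0.5, 0.1, (0.3, 0.7), swd=0.0)


# -- correlations -----------------------------------------------------------

def test_perfect_linear_correlation():
    x = np.arange(10.0)
    res = pearson_ci(x, 2.0 * x)
    assert res.r == pytest.approx(1.0)
    assert res.ci90 == (1.0, 1.0)
    assert res.magnitude == "almost perfect"


def test_fisher_interval_hand_computation():
    """r=-0.44, n=90: Fisher-z 90% interval is about [-0.57, -0.29]."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(90)
    zx = (x - x.mean()) / x.std()
    noise = rng.standard_normal(90)
    e = noise - noise.dot(zx) / zx.dot(zx) * zx  # orthogonal to centred x
    ze = (e - e.mean()) / e.std()
    target = -0.44
    y = target * zx + math.sqrt(1 - target**2) * ze
    res = pearson_ci(x, y)
    assert res.r == pytest.approx(-0.44, abs=1e-9)
    # hand computation: tanh(atanh(-0.44) -/+ 1.645/sqrt(87))
    assert res.ci90[0] == pytest.approx(-0.5707, abs=5e-4)
    assert res.ci90[1] == pytest.approx(-0.2876, abs=5e-4)
    assert res.magnitude == "moderate"
    assert res.clarity == "clear"


def test_fisher_interval_width_decreases_with_n():
    widths = []
    rng = np.random.default_rng(4)
    for n in (10, 30, 90, 300):
        x = rng.standard_normal(n)
        y = 0.5 * x + math.sqrt(0.75) * rng.standard_normal(n)
        # fix r exactly via construction-free route: use the formula directly
        z = math.atanh(0.5)
        half = 1.6448536269514722 / math.sqrt(n - 3)
        widths.append(math.tanh(z + half) - math.tanh(z - half))
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_interval_spanning_zero_is_unclear():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(30)
    y = 0.02 * x + rng.standard_normal(30)
    res = pearson_ci(x, y)
    if res.ci90[0] < 0.0 < res.ci90[1]:
        assert res.clarity == "unclear"


def test_zero_variance_correlation_errors():
    with pytest.raises(EffectError):
        pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_too_few_pairs_errors():
    with pytest.raises(EffectError):
        pearson_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


# -- efficacy ---------------------------------------------------------------

@pytest.mark.parametrize("goals,shots,expected", [
    (0, 5, 0.0), (1, 3, 33.3), (3, 3, 100.0), (1, 14, 7.1),
])
def test_efficacy_formula(goals, shots, expected):
    assert efficacy(goals, shots) == expected


def test_efficacy_errors():
    with pytest.raises(EffectError):
        efficacy(1, 0)
    with pytest.raises(EffectError):
        efficacy(5, 3)
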