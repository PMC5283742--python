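"""Effect sizes, magnitude-based inference and correlation statistics.

This layer reproduces the reporting style common in sports science:

* standardized mean differences with pooled SD (Cohen's d) and 90%
  confidence limits; magnitude bands |d| <= 0.2 trivial, <= 0.6 small,
  <= 1.2 moderate, <= 2.0 large, > 2.0 very large (a value exactly at a
  threshold takes the lower band's label);
* percent differences for count-type measures, analysed on the natural-log
  scale and back-transformed ("mean difference %; +/- 90% confidence
  limits");
* magnitude-based inference (MBI): the probabilities that the true effect
  exceeds +SWD, lies within +/-SWD, or falls below -SWD — SWD being the
  smallest worthwhile difference, 0.2 standardized units by default — with
  qualitative labels 25-75% possible, 75-95% likely, 95-99% very likely,
  > 99% most likely, and "unclear" whenever the 90% interval spans
  substantial values of both signs;
* Pearson correlations with Fisher-z 90% intervals and magnitude bands
  |r| <= 0.1 trivial, <= 0.3 small, <= 0.5 moderate, <= 0.7 large,
  <= 0.9 very large, > 0.9 almost perfect;
* shooting efficacy = goals * 100 / shots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

D_THRESHOLDS = (0.2, 0.6, 1.2, 2.0)
D_LABELS = ("trivial", "small", "moderate", "large", "very large")
R_THRESHOLDS = (0.1, 0.3, 0.5, 0.7, 0.9)
R_LABELS = ("trivial", "small", "moderate", "large", "very large", "almost perfect")
MBI_BANDS = (0.25, 0.75, 0.95, 0.99)
MBI_LABELS = ("possible", "likely", "very likely", "most likely")
SWD_FACTOR = 0.2
DEFAULT_CONF = 0.90


class EffectError(ValueError):
    """Raised for undefined or degenerate effect-size computations."""


def magnitude_of_d(d: float) -> str:
    """Band label of a standardized difference; thresholds right-closed."""
    a = abs(d)
    for thr, lab in zip(D_THRESHOLDS, D_LABELS):
        if a <= thr:
            return lab
    return D_LABELS[-1]


def magnitude_of_r(r: float) -> str:
    a = abs(r)
    for thr, lab in zip(R_THRESHOLDS, R_LABELS):
        if a <= thr:
            return lab
    return R_LABELS[-1]


def mbi_band_label(prob: float) -> str | None:
    """Label of the probability that an effect is substantial.

    Below 25% no qualitative label applies (returns None); a probability
    exactly at a band edge takes the lower band's label.
    """
    if prob < MBI_BANDS[0]:
        return None
    for hi, lab in zip(MBI_BANDS[1:], MBI_LABELS[:-1]):
        if prob <= hi:
            return lab
    return MBI_LABELS[-1]


@dataclass
class EffectResult:
    d: float
    ci90: tuple[float, float]
    se: float
    df: float | None
    magnitude: str
    mbi: str
    mbi_direction: str                    # "positive" | "negative" | "trivial"
    probs: dict[str, float] = field(default_factory=dict)
    pct_diff: float | None = None
    pct_ci90: tuple[float, float] | None = None
    pct_limit: float | None = None        # the "+/-" half-width on % scale
    method: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "d": self.d, "ci90": list(self.ci90), "se": self.se, "df": self.df,
            "magnitude": self.magnitude, "mbi": self.mbi,
            "mbi_direction": self.mbi_direction, "probs": self.probs,
            "pct_diff": self.pct_diff,
            "pct_ci90": None if self.pct_ci90 is None else list(self.pct_ci90),
            "pct_limit": self.pct_limit, "method": self.method,
        }


@dataclass
class CorrelationResult:
    r: float
    ci90: tuple[float, float]
    n: int
    magnitude: str
    clarity: str                          # "clear" | "unclear"

    def as_dict(self) -> dict:
        return {"r": self.r, "ci90": list(self.ci90), "n": self.n,
                "magnitude": self.magnitude, "clarity": self.clarity}


def cohen_d_pooled(group_a, group_b, conf: float = DEFAULT_CONF,
                   swd: float = SWD_FACTOR) -> EffectResult:
    """Standardized mean difference (B - A) / pooled SD with CI and MBI.

    The pooled variance is the df-weighted average of the two group
    variances.  Confidence limits use the large-sample normal approximation
    with SE(d) = sqrt(1/nA + 1/nB + d^2 / (2 (nA + nB))); MBI probabilities
    come from the t distribution with nA + nB - 2 degrees of freedom.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise EffectError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise EffectError("group values must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = b.mean() - a.mean()
    if sp2 == 0.0:
        if diff != 0.0:
            raise EffectError("zero pooled variance with unequal means: d undefined")
        d = 0.0
    else:
        d = diff / math.sqrt(sp2)
    se = math.sqrt(1.0 / na + 1.0 / nb + d * d / (2.0 * (na + nb)))
    zc = sps.norm.ppf(0.5 + conf / 2.0)
    ci = (d - zc * se, d + zc * se)
    df = na + nb - 2
    mbi, direction, probs = mbi_label_from(d, se, ci, swd=swd, df=df)
    return EffectResult(
        d=d, ci90=ci, se=se, df=df, magnitude=magnitude_of_d(d),
        mbi=mbi, mbi_direction=direction, probs=probs,
        method={"estimator": "pooled-variance standardized difference",
                "ci": f"normal approximation, {int(conf * 100)}%",
                "swd": swd})


def percent_difference(group_a, group_b, conf: float = DEFAULT_CONF) -> EffectResult:
    """Percent difference of B relative to A, analysed on the log scale.

    Both groups must be strictly positive (count-type measures).  The point
    estimate is the back-transformed difference of log means minus one,
    times 100; the +/- limit is the back-transformed half-width of the
    pooled two-sample t interval of the log difference.  The returned
    ``EffectResult`` also carries the standardized difference of the logs,
    which drives the magnitude and MBI labels.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise EffectError("percent differences need strictly positive values; "
                          "use raw-difference mode for data with zeros")
    base = cohen_d_pooled(np.log(a), np.log(b), conf=conf)
    na, nb = len(a), len(b)
    la, lb = np.log(a), np.log(b)
    sp2 = (((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1))
           / (na + nb - 2))
    diff = lb.mean() - la.mean()
    se = math.sqrt(sp2) * math.sqrt(1.0 / na + 1.0 / nb)
    tc = sps.t.ppf(0.5 + conf / 2.0, df=na + nb - 2)
    pct = 100.0 * (math.exp(diff) - 1.0)
    lo = 100.0 * (math.exp(diff - tc * se) - 1.0)
    hi = 100.0 * (math.exp(diff + tc * se) - 1.0)
    base.pct_diff = pct
    base.pct_ci90 = (lo, hi)
    base.pct_limit = 100.0 * (math.exp(tc * se) - 1.0)
    base.method.update({"scale": "natural log, back-transformed",
                        "interval": f"pooled t, {int(conf * 100)}%"})
    return base


def mbi_label_from(d: float, se: float, ci: tuple[float, float],
                   swd: float = SWD_FACTOR, df: float | None = None,
                   ) -> tuple[str, str, dict[str, float]]:
    """Magnitude-based inference label for an estimate with standard error.

    Returns ``(label, direction, probabilities)``.  The effect is *unclear*
    when the confidence interval spans both +swd and -swd; otherwise the
    label comes from the probability band of the most probable class
    (substantially positive / trivial / substantially negative).
    """
    if swd <= 0:
        raise EffectError("smallest worthwhile difference must be positive")
    if se == 0.0:
        p_pos, p_neg = float(d > swd), float(d < -swd)
        p_triv = 1.0 - p_pos - p_neg
    else:
        dist = sps.t(df=df) if df is not None else sps.norm()
        p_pos = float(dist.sf((swd - d) / se))
        p_neg = float(dist.cdf((-swd - d) / se))
        p_triv = 1.0 - p_pos - p_neg
    probs = {"positive": p_pos, "trivial": p_triv, "negative": p_neg}
    if ci[0] < -swd and ci[1] > swd:
        return "unclear", "unclear", probs
    direction = max(probs, key=probs.get)
    label = mbi_band_label(probs[direction])
    return (label or "possible"), direction, probs


def pearson_ci(x, y, conf: float = DEFAULT_CONF) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval and magnitude label.

    Pairs with a missing member are dropped; at least 4 complete pairs and
    non-zero variance on both sides are required.  The result is *unclear*
    when the interval contains correlations of both signs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise EffectError("need at least 4 complete pairs for a correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        raise EffectError("undefined correlation: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:  # numerically perfect: degenerate interval
        r = float(np.sign(r))
        ci = (r, r)
    else:
        z = math.atanh(r)
        zc = sps.norm.ppf(0.5 + conf / 2.0)
        half = zc / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    clarity = "unclear" if ci[0] < 0.0 < ci[1] else "clear"
    return CorrelationResult(r=r, ci90=ci, n=n,
                             magnitude=magnitude_of_r(r), clarity=clarity)


def efficacy(goals: int, shots: int) -> float:
    """Shooting efficacy: goals * 100 / shots (percent, one decimal)."""
    if shots < 1:
        raise EffectError("efficacy undefined without shots")
    if goals < 0 or goals > shots:
        raise EffectError("goals must lie between 0 and shots")
    return round(goals * 100.0 / shots, 1)
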