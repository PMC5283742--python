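"""Regularity classification of dyad ApEn values.

The 45 dyad ApEn values of a team are partitioned into regularity classes
with a one-dimensional Gaussian mixture fitted by expectation-maximisation;
the number of components is selected by the Bayesian information criterion
(BIC) over a small candidate range.  Components are relabelled by ascending
mean ApEn: the lowest-ApEn component is the *higher*-regularity class (low
ApEn = more repeatable positioning).  With three components the labels are
``higher`` / ``medium`` / ``lower`` regularity; a replication mode can
force k = 3 regardless of the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

LABELS_BY_K = {
    1: ["uniform"],
    2: ["higher", "lower"],
    3: ["higher", "medium", "lower"],
}


@dataclass
class RegularityClassification:
    labels: list[str]                   # per input value, in input order
    component: np.ndarray               # per input value, 0 = most regular
    k_selected: int
    bic_trace: dict[int, float]
    component_means: np.ndarray         # ascending ApEn
    forced_k: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_frame(self, dyads: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"regularity_class": self.labels,
                           "component": self.component})
        if dyads is not None:
            df = pd.concat([dyads.reset_index(drop=True), df], axis=1)
        return df


def class_labels(k: int) -> list[str]:
    if k in LABELS_BY_K:
        return list(LABELS_BY_K[k])
    return [f"class_{i + 1}" for i in range(k)]


def fit_regularity_classes(apen_values, k_candidates=range(1, 6),
                           n_restarts: int = 20, seed: int = 0,
                           force_k: int | None = None) -> RegularityClassification:
    """Fit a BIC-selected 1-D Gaussian mixture and label by regularity.

    Parameters
    ----------
    apen_values : array-like
        Finite ApEn values (>= 6 required for a meaningful fit).
    k_candidates : iterable of int
        Candidate component counts scored by BIC.
    n_restarts : int
        Random EM initialisations per candidate; a deterministic
        quantile-based initialisation is always included as a fallback.
    force_k : int, optional
        Skip selection and fit exactly this many components.
    """
    x = np.asarray(apen_values, float)
    if x.ndim != 1 or len(x) < 6:
        raise ValueError("need at least 6 one-dimensional ApEn values")
    if not np.all(np.isfinite(x)):
        raise ValueError("ApEn values must be finite")
    msgs: list[str] = []

    if np.ptp(x) == 0.0:
        msgs.append("all ApEn values identical; single class returned")
        warnings.warn(msgs[-1], stacklevel=2)
        return RegularityClassification(
            labels=[class_labels(1)[0]] * len(x),
            component=np.zeros(len(x), int), k_selected=1,
            bic_trace={1: float("nan")}, component_means=np.array([x[0]]),
            forced_k=force_k is not None, warnings=msgs)

    X = x.reshape(-1, 1)
    candidates = [force_k] if force_k is not None else \
        [k for k in k_candidates if k <= len(x)]
    # variance floor at 0.1% of the data variance: blocks the classic EM
    # singularity (a component collapsing onto near-coincident points)
    # without constraining genuine within-class spread
    reg_covar = max(1e-10, 1e-3 * float(np.var(x)))
    fits: dict[int, GaussianMixture] = {}
    bic: dict[int, float] = {}
    for k in candidates:
        fits[k] = _best_fit(X, k, n_restarts, seed, reg_covar)
        bic[k] = float(fits[k].bic(X))
    k_sel = min(bic, key=lambda k: (bic[k], k))
    gm = fits[k_sel]

    means = gm.means_.ravel()
    order = np.argsort(means)            # ascending ApEn = descending regularity
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(k_sel)
    comp = rank_of[gm.predict(X)]
    names = class_labels(k_sel)
    return RegularityClassification(
        labels=[names[c] for c in comp], component=comp, k_selected=k_sel,
        bic_trace=bic, component_means=means[order],
        forced_k=force_k is not None, warnings=msgs)


def _best_fit(X: np.ndarray, k: int, n_restarts: int, seed: int,
              reg_covar: float) -> GaussianMixture:
    best = None
    # deterministic quantile initialisation plus seeded random restarts
    q = np.quantile(X.ravel(), (np.arange(k) + 0.5) / k).reshape(-1, 1)
    for means_init, rs in [(q, seed)] + [(None, seed + 1)]:
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=1 if means_init is not None else n_restarts,
                             means_init=means_init, random_state=rs,
                             reg_covar=reg_covar, max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    return best
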