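"""Median-split Kaplan-Meier screening of radiomic features.

For each feature, treated subjects are split at the feature's median
(ties go to the "<= median" group), the two groups' time-to-treatment
curves are compared with the two-group log-rank test, and the p-values
are Benjamini-Hochberg adjusted across all screened features at 0.05.
The Kaplan-Meier estimator and log-rank statistic are delegated to
lifelines; right-censoring is supported throughout even though the
default screen keeps only treated (all-event) subjects, mirroring a
treated-only analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .harmonization import ALPHA, benjamini_hochberg
from .imaging_io import FeatureTable

log = logging.getLogger("petww")


def km_curve(times, events=None) -> pd.DataFrame:
    """Product-limit survival estimate S(t) with right-censoring.

    Returns a frame with columns ``time`` and ``survival`` (the step
    function value at and after each observed time; S(0) = 1).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    e = np.ones_like(t, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(times_a, times_b, events_a=None, events_b=None,
            n_permutations: int | None = None, rng=None) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    By default the p-value is the 1-df chi-square approximation; pass
    ``n_permutations`` for a group-label permutation p at small n.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    ea = np.ones_like(ta, dtype=bool) if events_a is None else np.asarray(events_a, dtype=bool)
    eb = np.ones_like(tb, dtype=bool) if events_b is None else np.asarray(events_b, dtype=bool)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank requires at least one event")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    if n_permutations is None:
        return stat, float(res.p_value)
    rng = np.random.default_rng(rng)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    na = len(ta)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(t))
        r = logrank_test(t[perm[:na]], t[perm[na:]],
                         event_observed_A=e[perm[:na]], event_observed_B=e[perm[na:]])
        if float(r.test_statistic) >= stat - 1e-12:
            count += 1
    return stat, (count + 1) / (n_permutations + 1)


@dataclasses.dataclass
class KmScreenResult:
    """Per-feature median-split log-rank screen with FDR adjustment."""

    results: pd.DataFrame  # index: feature; cutpoint, n_low, n_high, chi2, p_raw, p_adj, significant
    skipped: list[str]     # features with a degenerate split
    n_subjects: int
    alpha: float = ALPHA

    @property
    def significant_features(self) -> list[str]:
        return list(self.results.index[self.results["significant"]])


def median_split_screen(
    table: FeatureTable,
    ttt_months,
    events=None,
    treated_only: bool = True,
    alpha: float = ALPHA,
) -> KmScreenResult:
    """Screen every feature by median split + log-rank + BH adjustment.

    ``treated_only`` restricts the analysis to subjects whose treatment
    started (event=True), so the screened data are all-event.
    """
    feats = table.features()
    t = np.asarray(ttt_months, dtype=float)
    e = np.ones_like(t, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    if treated_only:
        keep = e
        feats, t, e = feats.loc[keep], t[keep], e[keep]
    n = len(t)
    if n < 4:
        raise ValueError("too few subjects after filtering for a median split")
    rows, skipped = [], []
    for col in feats.columns:
        x = feats[col].to_numpy(dtype=float)
        cut = float(np.median(x))
        low = x <= cut  # ties at the median fall in the low group
        if low.all() or not low.any():
            skipped.append(col)
            log.warning("feature %s skipped: degenerate median split", col)
            continue
        chi2, p = logrank(t[low], t[~low], e[low], e[~low])
        rows.append({"feature": col, "cutpoint": cut, "n_low": int(low.sum()),
                     "n_high": int((~low).sum()), "chi2": chi2, "p_raw": p})
    if not rows:
        raise ValueError("every feature produced a degenerate split")
    res = pd.DataFrame(rows).set_index("feature")
    res["p_adj"] = benjamini_hochberg(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] < alpha
    return KmScreenResult(results=res, skipped=skipped, n_subjects=n, alpha=alpha)


def km_curves_for_feature(
    table: FeatureTable, feature: str, ttt_months, events=None, treated_only: bool = True
) -> pd.DataFrame:
    """KM curves of the two median-split groups of one feature (for plots)."""
    feats = table.features()
    t = np.asarray(ttt_months, dtype=float)
    e = np.ones_like(t, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    if treated_only:
        feats, t, e = feats.loc[e], t[e], e[e]
    x = feats[feature].to_numpy(dtype=float)
    low = x <= np.median(x)
    frames = []
    for name, m in (("low", low), ("high", ~low)):
        c = km_curve(t[m], e[m])
        c.insert(0, "group", name)
        c.insert(0, "feature", feature)
        frames.append(c)
    return pd.concat(frames, ignore_index=True)
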