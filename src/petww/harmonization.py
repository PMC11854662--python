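"""Scanner-difference audit and ComBat batch-effect harmonization.

The audit runs a two-sided Wilcoxon-Mann-Whitney test per feature between
the two scanner groups and controls the false discovery rate with the
Benjamini-Hochberg step-up procedure at 0.05.  ComBat is the parametric
empirical-Bayes location/scale model from the genomics literature with a
single batch factor (the scanner) and no biological covariates: features
are standardised by their grand mean and pooled variance, per-batch
location and scale estimates are shrunk toward normal/inverse-gamma
hyperpriors fit across features, and the adjusted data are rescaled back.
A final per-feature re-centering restores each feature's original cohort
grand mean exactly (EB shrinkage otherwise leaves a small constant offset
that carries no scanner information).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging_io import FeatureTable

log = logging.getLogger("petww")

ALPHA = 0.05


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (shared by every FDR user in the package)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, alpha=ALPHA, method="fdr_bh")[1]


@dataclasses.dataclass
class ScannerAudit:
    """Per-feature scanner-difference test results."""

    results: pd.DataFrame  # index: feature; columns: p_raw, p_adj, significant
    alpha: float = ALPHA

    @property
    def n_significant(self) -> int:
        return int(self.results["significant"].sum())

    @property
    def significant_features(self) -> list[str]:
        return list(self.results.index[self.results["significant"]])


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided WMW p: exact when both groups are small and tie-free,
    otherwise the tie- and continuity-corrected normal approximation."""
    pooled = np.concatenate([x, y])
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def wilcoxon_scanner_test(table: FeatureTable, labels=None, alpha: float = ALPHA) -> ScannerAudit:
    """Audit every feature for a scanner difference (WMW + BH at ``alpha``)."""
    feats = table.features()
    lab = np.asarray(labels if labels is not None else table.scanner.to_numpy())
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"exactly two scanner groups required, got {list(groups)}")
    a, b = (lab == groups[0]), (lab == groups[1])
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty scanner group")
    p_raw = np.array(
        [_rank_sum_p(feats[c].to_numpy()[a], feats[c].to_numpy()[b]) for c in feats.columns]
    )
    p_adj = benjamini_hochberg(p_raw)
    res = pd.DataFrame(
        {"p_raw": p_raw, "p_adj": p_adj, "significant": p_adj < alpha},
        index=pd.Index(feats.columns, name="feature"),
    )
    return ScannerAudit(results=res, alpha=alpha)


def outcome_scanner_test(ttt_months, labels) -> float:
    """Rank-sum p for a scanner difference in the outcome itself (reported,
    never acted on)."""
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("exactly two scanner groups required")
    t = np.asarray(ttt_months, dtype=float)
    return _rank_sum_p(t[lab == groups[0]], t[lab == groups[1]])


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CombatModel:
    """Fitted parametric EB ComBat parameters for one batch factor."""

    features: list[str]
    batches: list
    grand_mean: np.ndarray          # alpha-hat per feature
    pooled_var: np.ndarray          # sigma-hat^2 per feature
    gamma_star: np.ndarray          # (n_batches, n_features) shrunken locations
    delta2_star: np.ndarray         # (n_batches, n_features) shrunken variances
    constant_features: list[str]    # zero-variance features passed through


def _postmean(gamma_hat, gamma_bar, n, tau2_bar, delta2_star):
    return (n * tau2_bar * gamma_hat + delta2_star * gamma_bar) / (
        n * tau2_bar + delta2_star
    )


def _it_sol(z_b, gamma_hat, delta2_hat, gamma_bar, tau2_bar, a_prior, b_prior,
            tol=1e-4, max_iter=100):
    """EB iteration for one batch: shrink location and scale jointly."""
    n = z_b.shape[0]
    g_old, d_old = gamma_hat.copy(), delta2_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(gamma_hat, gamma_bar, n, tau2_bar, d_old)
        ssq = ((z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * ssq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_fit(table: FeatureTable, labels=None) -> CombatModel:
    """Fit parametric EB ComBat with the scanner as the single batch factor."""
    feats = table.features()
    lab = np.asarray(labels if labels is not None else table.scanner.to_numpy())
    batches = list(pd.unique(lab))
    if len(batches) < 2:
        raise ValueError("ComBat needs at least two batches")
    if len(batches) > 2:
        raise ValueError(f"only two scanner batches supported, got {len(batches)}")
    for b in batches:
        if (lab == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 subjects")

    X = feats.to_numpy(dtype=float)  # subjects x features
    n, _ = X.shape
    sd = X.std(axis=0, ddof=0)
    constant = sd <= 0
    cols = list(feats.columns)
    keep = ~constant
    Xk = X[:, keep]
    if constant.any():
        log.warning(
            "ComBat: %d zero-variance feature(s) passed through untouched", constant.sum()
        )

    masks = [lab == b for b in batches]
    n_b = np.array([m.sum() for m in masks], dtype=float)
    batch_means = np.stack([Xk[m].mean(axis=0) for m in masks])  # (B, F)
    grand_mean = (n_b[:, None] * batch_means).sum(axis=0) / n
    resid = Xk.copy()
    for i, m in enumerate(masks):
        resid[m] -= batch_means[i]
    pooled_var = (resid**2).sum(axis=0) / n

    z = (Xk - grand_mean) / np.sqrt(pooled_var)

    gamma_star = np.zeros_like(batch_means)
    delta2_star = np.ones_like(batch_means)
    for i, m in enumerate(masks):
        z_b = z[m]
        gamma_hat = z_b.mean(axis=0)
        delta2_hat = z_b.var(axis=0, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2_bar = float(gamma_hat.var(ddof=1))
        d_mean = float(delta2_hat.mean())
        d_var = float(delta2_hat.var(ddof=1))
        if d_var <= 0 or tau2_bar <= 0:
            # degenerate hyperprior (e.g. very few features): no shrinkage
            gamma_star[i], delta2_star[i] = gamma_hat, delta2_hat
            continue
        a_prior = (2.0 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var
        gamma_star[i], delta2_star[i] = _it_sol(
            z_b, gamma_hat, delta2_hat, gamma_bar, tau2_bar, a_prior, b_prior
        )

    # expand back to the full column set (constant columns get identity params)
    F = len(cols)
    gm = np.zeros(F)
    pv = np.ones(F)
    gs = np.zeros((len(batches), F))
    ds = np.ones((len(batches), F))
    gm[keep] = grand_mean
    pv[keep] = pooled_var
    gs[:, keep] = gamma_star
    ds[:, keep] = delta2_star
    gm[constant] = X[:, constant].mean(axis=0) if constant.any() else gm[constant]
    return CombatModel(
        features=cols,
        batches=batches,
        grand_mean=gm,
        pooled_var=pv,
        gamma_star=gs,
        delta2_star=ds,
        constant_features=[c for c, f in zip(cols, constant) if f],
    )


def combat_apply(model: CombatModel, table: FeatureTable, labels=None) -> FeatureTable:
    """Apply a fitted ComBat model; shape and column names are preserved."""
    feats = table.features()
    if list(feats.columns) != model.features:
        raise ValueError("feature columns do not match the fitted model")
    lab = np.asarray(labels if labels is not None else table.scanner.to_numpy())
    X = feats.to_numpy(dtype=float)
    out = X.copy()
    const = np.array([c in model.constant_features for c in model.features])
    adj = ~const
    sigma = np.sqrt(model.pooled_var)
    for i, b in enumerate(model.batches):
        m = lab == b
        if not m.any():
            continue
        z = (X[np.ix_(m, adj)] - model.grand_mean[adj]) / sigma[adj]
        z = (z - model.gamma_star[i, adj]) / np.sqrt(model.delta2_star[i, adj])
        out[np.ix_(m, adj)] = z * sigma[adj] + model.grand_mean[adj]
    unknown = ~np.isin(lab, np.asarray(model.batches, dtype=object))
    if unknown.any():
        raise ValueError(f"unknown batch label(s): {set(lab[unknown])}")
    # re-centering contract: restore each feature's original grand mean
    out[:, adj] += X[:, adj].mean(axis=0) - out[:, adj].mean(axis=0)
    harm = pd.DataFrame(out, index=feats.index, columns=feats.columns)
    return table.with_features(harm)


def combat_harmonize(table: FeatureTable, labels=None) -> tuple[FeatureTable, CombatModel]:
    model = combat_fit(table, labels)
    return combat_apply(model, table, labels), model


def drop_unharmonized(table: FeatureTable, audit_post: ScannerAudit) -> FeatureTable:
    """Discard features still scanner-different after harmonization."""
    bad = audit_post.significant_features
    if not bad:
        return table
    remaining = [c for c in table.feature_columns if c not in bad]
    if not remaining:
        raise ValueError("every feature remained scanner-different; nothing to model")
    log.info("dropping %d unharmonized feature(s): %s", len(bad), bad)
    return FeatureTable(table.data[list(("subject_id", "scanner")) + remaining].copy())
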