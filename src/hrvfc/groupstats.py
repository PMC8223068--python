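"""Group-level inference: covariate adjustment, 2x2 mixed ANOVA, FDR,
post-hoc parcel-pair tests, and cardiac-metric group comparisons.

The headline test is a split-plot (mixed) ANOVA per network pair with group
as the between-subject factor and HRV state (low/high) as the within-subject
factor.  With two states the decomposition reduces to closed forms on the
per-subject state means ``S_i = (low_i + high_i)/2`` and differences
``D_i = high_i - low_i``:

* group:        one-way ANOVA on the subject means ``S_i``;
* state:        ``SS = N * Dbar^2 / 2`` against the subject-by-state error
                ``sum (D_i - Dbar_g)^2 / 2`` on ``N - 2`` df;
* interaction:  equals the squared two-sample t comparing ``D_i`` between
                groups (same error term).

Significance over the 66 network pairs (11 within + 55 between) is assessed
with Benjamini-Hochberg FDR at alpha = 0.0125 — 0.05 Bonferroni-divided over
the four cardiac metrics whose states are analysed (mean RR, RMSSD, LF-HRV,
HF-HRV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import permutation_two_sample
from .state_fc import NetworkPartition

__all__ = [
    "AnovaResult",
    "metric_family_alpha",
    "adjust_covariates",
    "mixed_anova_2x2",
    "fdr_bh",
    "network_pair_anova",
    "posthoc_parcel_interactions",
    "compare_cardiac_metrics",
]

#: number of cardiac metrics whose states enter the analysis family
N_STATE_METRICS = 4


def metric_family_alpha(alpha: float = 0.05,
                        n_metrics: int = N_STATE_METRICS) -> float:
    """Bonferroni-over-metrics significance level (0.05 / 4 = 0.0125)."""
    return alpha / n_metrics


@dataclass
class AnovaResult:
    """Mixed-ANOVA F and p per network pair, with FDR-adjusted interaction p."""

    table: pd.DataFrame
    alpha: float = 0.0125
    metric: str = ""
    degenerate_pairs: list = field(default_factory=list)

    def significant(self, effect: str = "interaction") -> pd.DataFrame:
        col = {"interaction": "sig_int", "group": "sig_group",
               "state": "sig_state"}[effect]
        return self.table[self.table[col]]


def adjust_covariates(values: np.ndarray, sex, age, mean_fd_low,
                      mean_fd_high, per_state: bool = False) -> np.ndarray:
    """Residualize subject-by-state values on sex, age, state-specific mean FD.

    ``values`` is (n_subjects, 2[, ...extra dims]) with state order (low,
    high).  A single regression pooled across both states is fitted (the
    state-specific FD covariate differs between the two rows of a subject);
    residuals are returned with the grand mean restored.  ``per_state`` fits
    the two states separately instead.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2, ...)")
    n = v.shape[0]
    sex = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    fd = np.column_stack([np.asarray(mean_fd_low, float),
                          np.asarray(mean_fd_high, float)])

    def _resid(Y, X):
        # mean-centered covariates: intercept keeps the grand mean in place
        X = np.column_stack([np.ones(len(X))] +
                            [c - c.mean() for c in X.T])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return resid + Y.mean(axis=0, keepdims=True)

    if per_state:
        out = np.empty_like(v)
        for s in range(2):
            X = np.column_stack([sex, age, fd[:, s]])
            Y = v[:, s].reshape(n, -1)
            out[:, s] = _resid(Y, X).reshape(v[:, s].shape)
        return out
    # stack (subject, state) rows: covariates repeat per subject, FD per state
    Ystack = v.reshape(n, 2, -1).reshape(n * 2, -1)
    Xstack = np.column_stack([
        np.repeat(sex, 2), np.repeat(age, 2), fd.reshape(-1)
    ])
    R = _resid(Ystack, Xstack)
    return R.reshape(v.shape)


def mixed_anova_2x2(y_low: np.ndarray, y_high: np.ndarray, groups):
    """Split-plot ANOVA: 2 groups (between) x 2 states (within).

    ``y_low`` / ``y_high`` are (n_subjects,) or (n_subjects, m) for m
    simultaneous response vectors.  Returns a dict of arrays with keys
    ``F_group, p_group, F_state, p_state, F_int, p_int, df``.  Zero residual
    variance yields NaN F (degenerate), never an exception.
    """
    yl = np.atleast_2d(np.asarray(y_low, dtype=float).T).T
    yh = np.atleast_2d(np.asarray(y_high, dtype=float).T).T
    if yl.shape != yh.shape:
        raise ValueError("state arrays must have equal shape")
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    m0, m1 = g == labels[0], g == labels[1]
    n0, n1 = int(m0.sum()), int(m1.sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least two subjects")
    N = n0 + n1

    S = (yl + yh) / 2.0
    D = yh - yl

    # between-subject stratum
    Sbar = S.mean(axis=0)
    Sbar_g = np.stack([S[m0].mean(axis=0), S[m1].mean(axis=0)])
    ss_group = 2.0 * (n0 * (Sbar_g[0] - Sbar) ** 2 + n1 * (Sbar_g[1] - Sbar) ** 2)
    ss_subj = 2.0 * (((S[m0] - Sbar_g[0]) ** 2).sum(axis=0)
                     + ((S[m1] - Sbar_g[1]) ** 2).sum(axis=0))

    # within-subject stratum
    Dbar = D.mean(axis=0)
    Dbar_g = np.stack([D[m0].mean(axis=0), D[m1].mean(axis=0)])
    ss_state = N * Dbar ** 2 / 2.0
    ss_int = (n0 * (Dbar_g[0] - Dbar) ** 2 + n1 * (Dbar_g[1] - Dbar) ** 2) / 2.0
    ss_err_w = (((D[m0] - Dbar_g[0]) ** 2).sum(axis=0)
                + ((D[m1] - Dbar_g[1]) ** 2).sum(axis=0)) / 2.0

    df_err = N - 2

    def _f(ss_effect, ss_error):
        # zero effect with zero error is an exact null (F = 0); a nonzero
        # effect with zero error variance is degenerate (NaN)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ss_effect / (ss_error / df_err)
        return np.where(ss_error > 0, F,
                        np.where(ss_effect == 0, 0.0, np.nan))

    F_group = _f(ss_group, ss_subj)
    F_state = _f(ss_state, ss_err_w)
    F_int = _f(ss_int, ss_err_w)
    out = {}
    for name, F in (("group", F_group), ("state", F_state), ("int", F_int)):
        p = stats.f.sf(F, 1, df_err)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["df"] = (1, df_err)
    return out


def fdr_bh(pvals, alpha: float = 0.0125):
    """Benjamini-Hochberg step-up over a p-value family.

    Returns ``(significant_mask, adjusted_p)``; adjusted p-values are the
    usual monotone (cumulative-minimum) BH values.
    """
    p = np.asarray(pvals, dtype=float)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def network_pair_anova(netfc_low: np.ndarray, netfc_high: np.ndarray,
                       groups, partition: NetworkPartition,
                       alpha: float = 0.0125, metric: str = "",
                       covariates=None) -> AnovaResult:
    """Mixed ANOVA over the 66 network pairs with FDR over the family.

    ``netfc_low`` / ``netfc_high`` are (n_subjects, n_networks, n_networks)
    per-state network connectivity tables.  ``covariates``, when given, is a
    dict with keys sex, age, mean_fd_low, mean_fd_high; values are then
    covariate-adjusted (pooled regression) before the ANOVA.
    """
    nl = np.asarray(netfc_low, dtype=float)
    nh = np.asarray(netfc_high, dtype=float)
    nn = partition.n_networks
    iu = np.triu_indices(nn)
    yl = nl[:, iu[0], iu[1]]
    yh = nh[:, iu[0], iu[1]]
    if covariates is not None:
        stacked = np.stack([yl, yh], axis=1)  # (subjects, 2, pairs)
        adj = adjust_covariates(stacked, covariates["sex"], covariates["age"],
                                covariates["mean_fd_low"],
                                covariates["mean_fd_high"])
        yl, yh = adj[:, 0], adj[:, 1]
    res = mixed_anova_2x2(yl, yh, groups)
    sig_int, p_int_adj = fdr_bh(res["p_int"], alpha)
    sig_group, p_group_adj = fdr_bh(res["p_group"], alpha)
    sig_state, p_state_adj = fdr_bh(res["p_state"], alpha)
    pairs = partition.pair_labels()
    table = pd.DataFrame({
        "network_a": [a for a, _ in pairs],
        "network_b": [b for _, b in pairs],
        "F_group": res["F_group"], "p_group": res["p_group"],
        "p_group_adj": p_group_adj, "sig_group": sig_group,
        "F_state": res["F_state"], "p_state": res["p_state"],
        "p_state_adj": p_state_adj, "sig_state": sig_state,
        "F_int": res["F_int"], "p_int": res["p_int"],
        "p_int_adj": p_int_adj, "sig_int": sig_int,
    })
    degenerate = table.index[~np.isfinite(table.F_int)].tolist()
    return AnovaResult(table, alpha, metric, degenerate)


def posthoc_parcel_interactions(fc_low: np.ndarray, fc_high: np.ndarray,
                                groups, partition: NetworkPartition,
                                network_pair, parcel_ids=None) -> pd.DataFrame:
    """Parcel-pair interaction F within one flagged network pair, ranked.

    ``fc_low`` / ``fc_high`` are (n_subjects, n_parcels, n_parcels) state FC
    stacks.  No inference is attached beyond the raw F and p (descriptive
    ranking, as for parcel-level maps).
    """
    fc_low = np.asarray(fc_low, dtype=float)
    fc_high = np.asarray(fc_high, dtype=float)
    n_parcels = fc_low.shape[1]
    if parcel_ids is None:
        parcel_ids = np.arange(1, n_parcels + 1)
    B = partition.indicator(parcel_ids)
    net_a, net_b = network_pair
    ia = np.flatnonzero(B[:, partition.networks.index(net_a)])
    ib = np.flatnonzero(B[:, partition.networks.index(net_b)])
    if net_a == net_b:
        pairs = [(ia[i], ia[j]) for i in range(len(ia))
                 for j in range(i + 1, len(ia))]
    else:
        pairs = [(i, j) for i in ia for j in ib]
    rows_i = np.array([p[0] for p in pairs])
    rows_j = np.array([p[1] for p in pairs])
    yl = fc_low[:, rows_i, rows_j]
    yh = fc_high[:, rows_i, rows_j]
    res = mixed_anova_2x2(yl, yh, groups)
    out = pd.DataFrame({
        "parcel_a": parcel_ids[rows_i],
        "parcel_b": parcel_ids[rows_j],
        "F_int": res["F_int"],
        "p_int": res["p_int"],
    })
    return out.sort_values("F_int", ascending=False).reset_index(drop=True)


def compare_cardiac_metrics(summaries: pd.DataFrame, group_col: str = "group",
                            metrics=("mean_rr", "rmssd", "lf_hrv", "hf_hrv"),
                            q: int = 10000, seed=None) -> pd.DataFrame:
    """Two-sample permutation tests on scan-level cardiac summaries.

    Sex and age are regressed out first (pooled OLS); the permutation test
    (|difference in adjusted means|, q draws) is applied per metric.
    ``summaries`` needs columns group, sex, age plus the metric columns.
    """
    rng = np.random.default_rng(seed)
    g = summaries[group_col].to_numpy()
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    X = np.column_stack([
        np.ones(len(summaries)),
        summaries["sex"].to_numpy(float) - summaries["sex"].to_numpy(float).mean(),
        summaries["age"].to_numpy(float) - summaries["age"].to_numpy(float).mean(),
    ])
    rows = []
    for metric in metrics:
        y = summaries[metric].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta + y.mean()
        p = permutation_two_sample(resid[g == labels[0]], resid[g == labels[1]],
                                   q=q, rng=rng)
        rows.append({
            "metric": metric,
            f"mean_{labels[0]}": y[g == labels[0]].mean(),
            f"mean_{labels[1]}": y[g == labels[1]].mean(),
            "p_perm": p,
        })
    return pd.DataFrame(rows)
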