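"""Cardiac-metric GLMs on parcel BOLD series and group-level tests.

Each 1-s cardiac metric course is convolved with the canonical double-gamma
hemodynamic response function, sampled at volume acquisition times, censored,
z-scored, and regressed against every parcel's cleaned series.  Group maps
are intercept / group-contrast tests on the per-subject betas with sex, age
and mean framewise displacement as covariates; multiplicity over parcels is
handled by Bonferroni or Benjamini-Hochberg (parcel-level resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preproc import ParcelTimeSeries

__all__ = [
    "GLMResult",
    "canonical_hrf",
    "build_metric_regressor",
    "subject_glm",
    "group_one_sample",
    "group_two_sample",
    "correct_parcels",
    "permutation_two_sample",
]


@dataclass
class GLMResult:
    """Per-parcel beta / t / p for one subject and one cardiac metric."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    parcel_ids: np.ndarray
    metric: str = ""
    subject: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parcel_id": self.parcel_ids, "beta": self.beta, "t": self.t,
             "p": self.p, "metric": self.metric, "subject": self.subject}
        )


def canonical_hrf(dt: float, length: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    ``g(t; delay, disp) - g(t; undershoot)/ratio`` with gamma-density lobes
    (shape delay/disp, scale disp); peak-normalized to maximum 1.
    """
    t = np.arange(0.0, length + dt / 2, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - under / ratio
    return h / h.max()


def build_metric_regressor(metric_1s: np.ndarray, tr: float, n_volumes: int,
                           censor: np.ndarray | None = None,
                           hrf: np.ndarray | None = None) -> np.ndarray:
    """HRF-convolved metric regressor at retained volume times, z-scored.

    ``metric_1s`` lives on the 1-s grid starting at scan time 0; NaN edges
    (half-window margins) are filled with the nearest finite value before
    convolution so the kernel does not smear missingness into the scan.
    """
    m = np.asarray(metric_1s, dtype=float).copy()
    finite = np.isfinite(m)
    if not finite.any():
        raise ValueError("metric course is all-missing")
    idx = np.arange(len(m))
    m = np.interp(idx, idx[finite], m[finite])
    if np.ptp(m) == 0:
        raise ValueError("degenerate (constant) metric regressor")
    if hrf is None:
        hrf = canonical_hrf(1.0)
    conv = np.convolve(m, hrf)[: len(m)]
    vol_times = np.arange(n_volumes) * tr
    reg = np.interp(vol_times, idx.astype(float), conv)
    if censor is not None:
        reg = reg[np.asarray(censor, bool)]
    sd = reg.std()
    if sd == 0:
        raise ValueError("degenerate (constant) metric regressor")
    return (reg - reg.mean()) / sd


def subject_glm(ts: ParcelTimeSeries, regressor: np.ndarray,
                metric: str = "", subject: str = "") -> GLMResult:
    """Per-parcel least squares of retained-volume series on
    ``[intercept, regressor]``; t = beta / SE."""
    y = ts.retained()
    x = np.asarray(regressor, dtype=float)
    if len(x) != y.shape[0]:
        raise ValueError("regressor length must match retained volumes")
    X = np.column_stack([np.ones(len(x)), x])
    beta_all, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_all
    dof = len(x) - 2
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta_all[1] / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return GLMResult(beta_all[1], t, np.clip(p, np.finfo(float).tiny, 1.0),
                     ts.parcel_ids, metric, subject)


def _covariate_design(n: int, covariates: pd.DataFrame | np.ndarray | None,
                      extra: np.ndarray | None = None) -> np.ndarray:
    cols = [np.ones(n)]
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C - C.mean(axis=0, keepdims=True)  # keeps intercept interpretable
        cols.append(C)
    return np.column_stack(cols)


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int):
    """t and p for one coefficient of an OLS fit, vectorized over Y columns."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough subjects for the covariate design")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    # an (essentially) exact fit has no error variance to test against
    degenerate = sigma2 <= 1e-24 * np.maximum(1.0, (Y ** 2).mean(axis=0))
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[col] / se, 0.0)
    t = np.where(degenerate, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return t, np.clip(p, np.finfo(float).tiny, 1.0)


def group_one_sample(betas: np.ndarray, covariates=None):
    """Covariate-adjusted one-sample test of per-subject betas.

    ``betas`` is (n_subjects, n_parcels); returns (t, p) per parcel testing
    the intercept after adjusting for mean-centered covariates.
    """
    Y = np.atleast_2d(np.asarray(betas, dtype=float))
    X = _covariate_design(Y.shape[0], covariates)
    return _ols_t(X, Y, col=0)


def group_two_sample(betas: np.ndarray, groups, covariates=None):
    """Covariate-adjusted group contrast (group 1 minus group 0) on betas."""
    Y = np.atleast_2d(np.asarray(betas, dtype=float))
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if min((g == labels[0]).sum(), (g == labels[1]).sum()) < 2:
        raise ValueError("each group needs at least two subjects")
    contrast = (g == labels[1]).astype(float)
    X = _covariate_design(Y.shape[0], covariates, extra=contrast)
    return _ols_t(X, Y, col=1)


def correct_parcels(pvals, method: str = "fdr", alpha: float = 0.05):
    """Multiplicity correction over parcels.

    Returns ``(significant_mask, adjusted_p)``; method ``"bonferroni"`` or
    ``"fdr"`` (Benjamini-Hochberg).
    """
    p = np.asarray(pvals, dtype=float)
    sm_method = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}[method]
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method=sm_method)
    return reject, p_adj


def permutation_two_sample(x, y, q: int = 10000, seed=None,
                           rng: np.random.Generator | None = None) -> float:
    """Two-sample permutation test on |difference in means|.

    ``p = (1 + #{permuted |diff| >= observed}) / (q + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n = len(x)
    observed = abs(x.mean() - y.mean())
    count = 0
    # draw permutations in blocks to bound memory at ~q/5 x len(pooled)
    block = max(1, min(q, 2000))
    done = 0
    while done < q:
        b = min(block, q - done)
        perms = rng.permuted(np.broadcast_to(pooled, (b, len(pooled))), axis=1)
        diffs = np.abs(perms[:, :n].mean(axis=1) - perms[:, n:].mean(axis=1))
        count += int((diffs >= observed - 1e-12).sum())
        done += b
    return (1 + count) / (q + 1)
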