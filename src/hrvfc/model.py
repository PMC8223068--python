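"""Model/Results front end for the HRV-state-dependent FC analysis.

:class:`HRVStateFC` is built from per-subject data (beat record, motion,
parcel BOLD, white-matter voxel series) plus the subject table and parcel
partition; :meth:`HRVStateFC.fit` runs the full pipeline for one cardiac
metric and returns an :class:`HRVStateFCResults` carrying the network-pair
mixed-ANOVA table, state masks, per-state network connectivity, and a
``summary()`` table.  :meth:`HRVStateFC.fit_glm` runs the companion
cardiac-metric GLM and group maps.

Pipeline per subject: framewise displacement -> subject exclusion (mean
FD > 0.25 mm) -> volume censoring (first five volumes, FD > 0.2 mm) ->
joint nuisance regression (discrete-cosine high-pass at 0.008 Hz, ten
white-matter PCs, six cardiac-pulsatility regressors, gray-matter mean) ->
windowed cardiac metrics (100-s windows), HRV metrics orthogonalized to
mean RR -> quartile state masks over retained volumes -> per-state Pearson
FC -> 11x11 network connectivity.  Group level: sex/age/state-FD covariate
adjustment, split-plot ANOVA per network pair, Benjamini-Hochberg FDR at
alpha = 0.0125.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cardiac, glm, preproc, state_fc
from .groupstats import network_pair_anova, posthoc_parcel_interactions
from .state_fc import NetworkPartition

__all__ = ["SubjectData", "HRVStateFC", "HRVStateFCResults", "GLMMapResults"]

HRV_METRICS = ("mean_rr", "rmssd", "lf_hrv", "hf_hrv")


@dataclass
class SubjectData:
    """One subject's raw inputs (any object with these attributes works)."""

    subject: str
    group: str
    sex: int
    age: float
    rr: cardiac.RRSeries
    motion: preproc.MotionParams
    bold: np.ndarray
    wm_voxels: np.ndarray | None = None


class HRVStateFC:
    """HRV-state-dependent functional connectivity model for a cohort.

    Parameters
    ----------
    subjects : sequence
        Per-subject data records (see :class:`SubjectData`).
    partition : NetworkPartition
        Parcel -> network assignment (246 parcels, 11 networks).
    tr : float
        Repetition time in seconds.
    mean_fd_limit, fd_censor_limit : float
        Subject-exclusion and volume-censoring FD thresholds (mm).
    quartile_fraction : float
        Fraction of retained volumes per state (0.25 = quartiles).
    """

    def __init__(self, subjects, partition: NetworkPartition, tr: float = 3.0,
                 mean_fd_limit: float = preproc.MEAN_FD_LIMIT,
                 fd_censor_limit: float = preproc.FD_CENSOR_LIMIT,
                 quartile_fraction: float = 0.25,
                 window: float = 100.0, n_wm_pcs: int = 10):
        if not 0 < quartile_fraction < 0.5:
            raise ValueError("quartile fraction must lie in (0, 0.5)")
        self.subjects = list(subjects)
        self.partition = partition
        self.tr = float(tr)
        self.mean_fd_limit = mean_fd_limit
        self.fd_censor_limit = fd_censor_limit
        self.quartile_fraction = quartile_fraction
        self.window = window
        self.n_wm_pcs = n_wm_pcs
        self._prepared = None

    @classmethod
    def from_simulation(cls, config=None, **kwargs) -> "HRVStateFC":
        """Build the model from :func:`hrvfc.simulate.gen_bold_dataset`."""
        from .simulate import SimConfig, gen_bold_dataset
        if config is None:
            config = SimConfig()
        subjects, table, partition, truth = gen_bold_dataset(config)
        model = cls(subjects, partition, tr=config.tr, **kwargs)
        model.ground_truth = truth
        model.sim_config = config
        return model

    # ------------------------------------------------------------------ prep

    def _prepare(self):
        """Motion screening, censoring, nuisance cleanup, windowed metrics.

        Runs once and is cached; metric courses are evaluated directly at
        volume acquisition times (state definition needs no finer grid).
        """
        if self._prepared is not None:
            return self._prepared
        kept, excluded = [], []
        for sub in self.subjects:
            fd = preproc.framewise_displacement(sub.motion)
            if not preproc.subject_passes_motion(fd, self.mean_fd_limit):
                excluded.append(sub.subject)
                continue
            censor = preproc.censor_mask(fd, self.fd_censor_limit)
            ts = preproc.ParcelTimeSeries(sub.bold, self.tr, censor=censor)

            regs = [preproc.cardiac_pulsatility_regressors(
                sub.rr, self.tr, ts.n_volumes)]
            if sub.wm_voxels is not None:
                pcs_ret = preproc.wm_pca_regressors(
                    sub.wm_voxels[censor], k=min(self.n_wm_pcs,
                                                 sub.wm_voxels.shape[1] - 1))
                pcs = np.zeros((ts.n_volumes, pcs_ret.shape[1]))
                pcs[censor] = pcs_ret
                regs.append(pcs)
            gm_mean = sub.bold.mean(axis=1, keepdims=True)
            regs.append(gm_mean)
            clean = preproc.nuisance_regress(ts, np.column_stack(regs))

            vol_times = ts.volume_times
            metrics = cardiac.sliding_metrics(sub.rr, window=self.window,
                                              timestamps=vol_times)
            metrics = metrics.orthogonalize_hrv()
            kept.append({"sub": sub, "fd": fd, "clean": clean,
                         "metrics": metrics})
        if len(kept) < 4:
            raise ValueError("too few subjects pass motion screening")
        self._prepared = (kept, excluded)
        return self._prepared

    # ------------------------------------------------------------------- fit

    def fit(self, metric: str = "lf_hrv", alpha: float = 0.0125,
            adjust: bool = True) -> "HRVStateFCResults":
        """State-dependent FC analysis for one cardiac metric."""
        if metric not in HRV_METRICS:
            raise ValueError(f"metric must be one of {HRV_METRICS}")
        kept, excluded = self._prepare()

        per_subject = []
        for rec in kept:
            clean, mts, fd = rec["clean"], rec["metrics"], rec["fd"]
            course = mts.metric(metric)
            filled = _fill_nan(course)
            sm = state_fc.state_masks(filled, clean.censor, metric,
                                      self.quartile_fraction)
            fc_low = state_fc.state_fc_matrix(clean, sm.low)
            fc_high = state_fc.state_fc_matrix(clean, sm.high)
            per_subject.append({
                "subject": rec["sub"].subject, "group": rec["sub"].group,
                "sex": rec["sub"].sex, "age": rec["sub"].age,
                "mask": sm,
                "fc_low": fc_low, "fc_high": fc_high,
                "net_low": state_fc.network_fc(fc_low, self.partition),
                "net_high": state_fc.network_fc(fc_high, self.partition),
                "fd_low": state_fc.state_motion(fd, clean.censor, sm.low),
                "fd_high": state_fc.state_motion(fd, clean.censor, sm.high),
            })

        groups = np.array([d["group"] for d in per_subject])
        cov = {
            "sex": np.array([d["sex"] for d in per_subject], float),
            "age": np.array([d["age"] for d in per_subject], float),
            "mean_fd_low": np.array([d["fd_low"] for d in per_subject]),
            "mean_fd_high": np.array([d["fd_high"] for d in per_subject]),
        } if adjust else None
        net_low = np.stack([d["net_low"] for d in per_subject])
        net_high = np.stack([d["net_high"] for d in per_subject])
        anova = network_pair_anova(net_low, net_high, groups, self.partition,
                                   alpha=alpha, metric=metric,
                                   covariates=cov)
        return HRVStateFCResults(self, metric, per_subject, net_low, net_high,
                                 groups, anova, excluded)

    def fit_glm(self, metric: str = "hr") -> "GLMMapResults":
        """Cardiac-metric GLM maps: per-subject betas + group tests.

        The metric course is evaluated on the 1-s grid, HRF-convolved,
        sampled at volume times, censored and z-scored.
        """
        kept, excluded = self._prepare()
        betas, results = [], []
        meta = []
        for rec in kept:
            sub, clean = rec["sub"], rec["clean"]
            series_1s = cardiac.sliding_metrics(sub.rr, window=self.window)
            series_1s = series_1s.orthogonalize_hrv()
            course = series_1s.metric(metric)
            reg = glm.build_metric_regressor(course, self.tr, clean.n_volumes,
                                             clean.censor)
            res = glm.subject_glm(clean, reg, metric, sub.subject)
            results.append(res)
            betas.append(res.beta)
            meta.append({"sex": sub.sex, "age": sub.age,
                         "mean_fd": float(np.mean(rec["fd"])),
                         "group": sub.group})
        betas = np.array(betas)
        meta = pd.DataFrame(meta)
        covs = meta[["sex", "age", "mean_fd"]].to_numpy(float)
        t1, p1 = glm.group_one_sample(betas, covs)
        t2, p2 = glm.group_two_sample(betas, meta["group"].to_numpy(), covs)
        return GLMMapResults(metric, betas, results, t1, p1, t2, p2, excluded)


def _fill_nan(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if ok.all():
        return x
    if not ok.any():
        raise ValueError("metric course is all-missing")
    idx = np.arange(len(x), dtype=float)
    return np.interp(idx, idx[ok], x[ok])


class HRVStateFCResults:
    """Fitted state-dependent FC analysis for one cardiac metric."""

    def __init__(self, model, metric, per_subject, net_low, net_high,
                 groups, anova, excluded_subjects):
        self.model = model
        self.metric = metric
        self.per_subject = per_subject
        self.net_low = net_low
        self.net_high = net_high
        self.groups = groups
        self.anova = anova
        self.excluded_subjects = excluded_subjects

    @property
    def table(self) -> pd.DataFrame:
        return self.anova.table

    def significant_pairs(self, effect: str = "interaction") -> pd.DataFrame:
        return self.anova.significant(effect)

    def state_difference_by_group(self) -> pd.DataFrame:
        """Mean network-pair connectivity change (high - low) per group."""
        diff = self.net_high - self.net_low
        rows = []
        nets = self.model.partition.networks
        for g in np.unique(self.groups):
            mean_d = diff[self.groups == g].mean(axis=0)
            iu = np.triu_indices(len(nets))
            for i, j in zip(*iu):
                rows.append({"group": g, "network_a": nets[i],
                             "network_b": nets[j],
                             "delta_fc": mean_d[i, j]})
        return pd.DataFrame(rows)

    def posthoc(self, network_pair) -> pd.DataFrame:
        fc_low = np.stack([d["fc_low"] for d in self.per_subject])
        fc_high = np.stack([d["fc_high"] for d in self.per_subject])
        return posthoc_parcel_interactions(fc_low, fc_high, self.groups,
                                           self.model.partition, network_pair)

    def summary(self) -> str:
        t = self.table
        lines = [
            "HRV-state-dependent functional connectivity: mixed ANOVA",
            f"metric: {self.metric}   subjects: {len(self.per_subject)} "
            f"({(self.groups == 'control').sum()} control / "
            f"{(self.groups == 'patient').sum()} patient)   "
            f"excluded for motion: {len(self.excluded_subjects)}",
            f"network pairs: {len(t)}   FDR alpha: {self.anova.alpha}",
            "",
            t[["network_a", "network_b", "F_group", "p_group", "F_state",
               "p_state", "F_int", "p_int", "p_int_adj", "sig_int"]]
            .sort_values("F_int", ascending=False).head(10)
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            f"significant interactions (FDR): "
            f"{int(t.sig_int.sum())} of {len(t)} pairs",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<HRVStateFCResults metric={self.metric!r} "
                f"n={len(self.per_subject)}>")


@dataclass
class GLMMapResults:
    """Cardiac-metric GLM maps and group-level tests."""

    metric: str
    betas: np.ndarray
    subject_results: list
    t_one_sample: np.ndarray
    p_one_sample: np.ndarray
    t_two_sample: np.ndarray
    p_two_sample: np.ndarray
    excluded_subjects: list

    def summary(self) -> str:
        k = int(np.argmax(np.abs(self.t_one_sample)))
        return (
            f"cardiac GLM ({self.metric}): {self.betas.shape[0]} subjects x "
            f"{self.betas.shape[1]} parcels\n"
            f"strongest one-sample parcel: index {k}, "
            f"t = {self.t_one_sample[k]:.3f}, p = {self.p_one_sample[k]:.3g}"
        )
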