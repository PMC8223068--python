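"""Motion quantification, volume censoring, and parcel time-series cleanup.

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, with rotations
(radians) converted to arc length on a 50-mm sphere.  Subjects whose mean FD
exceeds 0.25 mm are excluded; individual volumes with FD > 0.2 mm are
censored, as are the first five volumes of every scan (steady-state
magnetization).

Temporal cleanup is a single joint regression on retained volumes of a
discrete-cosine high-pass basis (cutoff 0.008 Hz) together with the nuisance
set: ten white-matter principal components, six cardiac-pulsatility phase
regressors, and the gray-matter mean.  Censored volumes never enter any fit
or correlation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cardiac import RRSeries

__all__ = [
    "MotionParams",
    "ParcelTimeSeries",
    "framewise_displacement",
    "subject_passes_motion",
    "censor_mask",
    "dct_highpass_basis",
    "highpass",
    "wm_pca_regressors",
    "cardiac_pulsatility_regressors",
    "nuisance_regress",
    "extract_parcel_timeseries",
]

HEAD_RADIUS_MM = 50.0
MEAN_FD_LIMIT = 0.25
FD_CENSOR_LIMIT = 0.2
N_DUMMY_VOLUMES = 5
HIGHPASS_HZ = 0.008


@dataclass
class MotionParams:
    """Six rigid-body realignment parameters per volume.

    Columns: tx, ty, tz (mm), rx, ry, rz (radians).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def fd(self, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
        return framewise_displacement(self, head_radius)


@dataclass
class ParcelTimeSeries:
    """Volumes x parcels BOLD matrix with acquisition and censoring metadata."""

    data: np.ndarray
    tr: float
    parcel_ids: np.ndarray | None = None
    censor: np.ndarray | None = None  # True = retained
    filtered: bool = False
    denoised: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_volumes, n_parcels)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.parcel_ids is None:
            self.parcel_ids = np.arange(1, self.data.shape[1] + 1)
        else:
            self.parcel_ids = np.asarray(self.parcel_ids)
        if self.censor is None:
            self.censor = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.censor = np.asarray(self.censor, dtype=bool)
            if len(self.censor) != self.data.shape[0]:
                raise ValueError("censor mask length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition time of each volume (slice-timing ignored)."""
        return np.arange(self.n_volumes) * self.tr

    def retained(self) -> np.ndarray:
        return self.data[self.censor]


def framewise_displacement(motion: MotionParams | np.ndarray,
                           head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Per-volume framewise displacement (mm); the first volume gets 0.

    ``fd_t = sum |d translation| + head_radius * sum |d rotation|``.
    """
    params = motion.params if isinstance(motion, MotionParams) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6)")
    if params.shape[0] < 2:
        raise ValueError("need at least two volumes")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def subject_passes_motion(fd, limit: float = MEAN_FD_LIMIT) -> bool:
    """True when the scan's mean FD does not exceed the exclusion limit."""
    return bool(np.mean(np.asarray(fd, float)) <= limit)


def censor_mask(fd, threshold: float = FD_CENSOR_LIMIT,
                n_dummy: int = N_DUMMY_VOLUMES) -> np.ndarray:
    """Boolean retention mask: drops the first ``n_dummy`` volumes and any
    volume with FD above ``threshold``."""
    fd = np.asarray(fd, dtype=float)
    mask = fd <= threshold
    mask[:n_dummy] = False
    return mask


def dct_highpass_basis(n_volumes: int, tr: float,
                       cutoff: float = HIGHPASS_HZ) -> np.ndarray:
    """Discrete-cosine basis spanning frequencies below ``cutoff``.

    Order ``floor(2 * duration * cutoff)``; columns are unit-norm DCT-II
    cosines (the constant term is excluded -- the regression design always
    carries its own intercept).
    """
    if cutoff >= 0.5 / tr:
        raise ValueError("cutoff at or above Nyquist")
    duration = n_volumes * tr
    order = int(np.floor(2.0 * duration * cutoff))
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, order))
    for k in range(1, order + 1):
        basis[:, k - 1] = np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
    if order:
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of columns of y on the design (intercept added)."""
    X = np.column_stack([np.ones(len(design)), design]) if design.size else \
        np.ones((len(y), 1))
    # drop collinear columns via rank-revealing QR on the fly
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear design column(s)")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def highpass(ts: ParcelTimeSeries, cutoff: float = HIGHPASS_HZ) -> ParcelTimeSeries:
    """High-pass parcel series by regressing out the low-frequency DCT basis
    (mean removed) over retained volumes; censored rows are zero-filled."""
    basis = dct_highpass_basis(ts.n_volumes, ts.tr, cutoff)
    out = np.zeros_like(ts.data)
    keep = ts.censor
    out[keep] = _residualize(ts.data[keep], basis[keep])
    return ParcelTimeSeries(out, ts.tr, ts.parcel_ids, ts.censor, filtered=True,
                            denoised=ts.denoised)


def wm_pca_regressors(wm_voxel_ts: np.ndarray, k: int = 10) -> np.ndarray:
    """First ``k`` principal-component score series of a voxels-in-columns
    white-matter matrix.

    De-meaned SVD; scores are unit-normalized, variance-ordered, with the sign
    fixed so each component's largest-magnitude voxel loading is positive.
    """
    X = np.asarray(wm_voxel_ts, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"requested {k} components from rank-{rank} matrix")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    scores = u[:, :k] * flip[:k]
    return scores


def cardiac_pulsatility_regressors(beats: RRSeries, tr: float,
                                   n_volumes: int, n_orders: int = 3) -> np.ndarray:
    """Cardiac-phase sine/cosine pairs (orders 1..n) at volume times.

    The cardiac phase ramps linearly from 0 to 2*pi between successive
    R-waves; the six columns are sin/cos of orders 1-3 of that phase, a
    simplified pulsatility basis sampled at volume acquisition times (phase
    is held at the boundary value outside the beat record).
    """
    t = np.arange(n_volumes) * tr
    bt = beats.beat_times
    idx = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, len(bt) - 2)
    frac = (t - bt[idx]) / (bt[idx + 1] - bt[idx])
    frac = np.clip(frac, 0.0, 1.0)
    phase = 2.0 * np.pi * frac
    cols = []
    for order in range(1, n_orders + 1):
        cols.append(np.sin(order * phase))
        cols.append(np.cos(order * phase))
    return np.column_stack(cols)


def nuisance_regress(ts: ParcelTimeSeries, regressors: np.ndarray,
                     include_highpass: bool = True,
                     cutoff: float = HIGHPASS_HZ) -> ParcelTimeSeries:
    """Joint nuisance regression over retained volumes.

    ``regressors`` is (n_volumes, k) in full-scan volume indexing; the DCT
    high-pass basis is appended by default so filtering and denoising happen
    in one fit (sequential regression can reintroduce filtered frequencies).
    Residuals replace retained rows; censored rows are zero-filled and remain
    excluded from every later computation.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.n_volumes:
        regressors = regressors.T
    if regressors.shape[0] != ts.n_volumes:
        raise ValueError("regressors must align with full-scan volumes")
    design = regressors
    if include_highpass:
        design = np.column_stack([dct_highpass_basis(ts.n_volumes, ts.tr, cutoff),
                                  regressors])
    out = np.zeros_like(ts.data)
    keep = ts.censor
    out[keep] = _residualize(ts.data[keep], design[keep])
    return ParcelTimeSeries(out, ts.tr, ts.parcel_ids, ts.censor,
                            filtered=include_highpass, denoised=True)


def extract_parcel_timeseries(image4d, labels) -> ParcelTimeSeries:
    """Mean time series per labeled parcel from a 4-D array or NIfTI pair.

    ``labels`` is an integer volume of the same spatial shape; label 0 is
    background.  Accepts nibabel images or plain arrays; TR is read from the
    NIfTI header when available (else 1.0 and should be set by the caller).
    """
    tr = 1.0
    try:  # nibabel images expose get_fdata/header; plain arrays do not
        data = image4d.get_fdata()
        zooms = image4d.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr = float(zooms[3])
    except AttributeError:
        data = np.asarray(image4d, dtype=float)
    try:
        lab = np.asarray(labels.get_fdata()).astype(int)
    except AttributeError:
        lab = np.asarray(labels).astype(int)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    if lab.shape != data.shape[:3]:
        raise ValueError("label volume shape mismatch")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    flat = data.reshape(-1, data.shape[3])
    labf = lab.ravel()
    series = np.column_stack([flat[labf == i].mean(axis=0) for i in ids])
    return ParcelTimeSeries(series, tr, parcel_ids=ids)
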