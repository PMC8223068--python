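"""Low/high HRV states and state-conditioned functional connectivity.

A scan's low (high) HRV state is the quarter of its retained volumes at which
the chosen cardiac metric — resampled at volume acquisition times — takes its
smallest (largest) values.  Exact quartile counts, ``floor(n/4)`` per state,
are enforced by rank with ties broken by time index, so state sizes are
reproducible (353 retained volumes -> 88 volumes per state).

Functional connectivity is the Pearson correlation of parcel series over the
masked volumes; network-level connectivity averages raw correlations over all
parcel pairs spanning (or within) networks.  Seed-based state contrasts use
Fisher-z transformed correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preproc import ParcelTimeSeries

__all__ = [
    "StateMask",
    "NetworkPartition",
    "state_masks",
    "resample_metric_at_volumes",
    "state_fc_matrix",
    "fisher_z",
    "network_fc",
    "state_motion",
    "seed_state_difference",
    "NETWORK_SIZES",
]

#: published network sizes for the 246-parcel atlas (3 cortical unassigned)
NETWORK_SIZES = {
    "visual": 34,
    "somatomotor": 33,
    "dorsal attention": 30,
    "ventral attention": 22,
    "limbic": 26,
    "frontoparietal": 26,
    "default mode": 36,
    "amygdala": 4,
    "hippocampus": 4,
    "basal ganglia": 12,
    "thalamus": 16,
}
N_PARCELS = 246
N_UNASSIGNED = 3


@dataclass
class StateMask:
    """Disjoint low/high boolean masks in retained-volume indexing."""

    metric: str
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self) -> None:
        self.low = np.asarray(self.low, dtype=bool)
        self.high = np.asarray(self.high, dtype=bool)
        if self.low.shape != self.high.shape:
            raise ValueError("mask shape mismatch")
        if np.any(self.low & self.high):
            raise ValueError("low/high masks must be disjoint")


class NetworkPartition:
    """Parcel -> network assignment over the 246-parcel atlas.

    Construct from a table with columns ``parcel_id`` and ``network``
    (network empty/"unassigned" for the three excluded cortical parcels).
    """

    def __init__(self, table: pd.DataFrame, validate_counts: bool = True):
        table = table.copy()
        if not {"parcel_id", "network"} <= set(table.columns):
            raise ValueError("partition table needs parcel_id and network columns")
        table["network"] = table["network"].fillna("unassigned").replace("", "unassigned")
        self.table = table
        counts = table[table.network != "unassigned"].network.value_counts().to_dict()
        if validate_counts:
            if counts != NETWORK_SIZES:
                raise ValueError(
                    "partition violates the published network sizes: "
                    f"got {counts}"
                )
            if len(table) != N_PARCELS:
                raise ValueError(f"expected {N_PARCELS} parcels, got {len(table)}")
        self.networks = [n for n in NETWORK_SIZES if n in counts] or \
            sorted(counts)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def indicator(self, parcel_ids) -> np.ndarray:
        """(n_parcels, n_networks) 0/1 membership matrix aligned to parcel_ids."""
        net_of = dict(zip(self.table.parcel_id, self.table.network))
        ind = np.zeros((len(parcel_ids), self.n_networks))
        for i, pid in enumerate(parcel_ids):
            net = net_of.get(pid, "unassigned")
            if net != "unassigned":
                ind[i, self.networks.index(net)] = 1.0
        return ind

    def pair_labels(self):
        """Unordered network pairs (including within-network), row-major
        upper triangle order."""
        nets = self.networks
        return [(nets[i], nets[j]) for i in range(len(nets))
                for j in range(i, len(nets))]


def resample_metric_at_volumes(metric_1s: np.ndarray, tr: float,
                               n_volumes: int) -> np.ndarray:
    """Linear interpolation of a 1-s metric course onto volume times,
    NaN-filling from the nearest finite values first."""
    m = np.asarray(metric_1s, dtype=float)
    idx = np.arange(len(m), dtype=float)
    finite = np.isfinite(m)
    if finite.sum() < 2:
        raise ValueError("metric course has fewer than two finite values")
    filled = np.interp(idx, idx[finite], m[finite])
    return np.interp(np.arange(n_volumes) * tr, idx, filled)


def state_masks(metric_at_volumes: np.ndarray, censor: np.ndarray,
                metric: str = "", fraction: float = 0.25) -> StateMask:
    """Quartile state masks over retained volumes.

    ``metric_at_volumes`` is in full-scan indexing; masks are returned in
    retained-volume indexing (aligned with ``ParcelTimeSeries.retained()``).
    Each state holds exactly ``floor(n_retained * fraction)`` volumes, chosen
    by value rank with ties broken by time index (stable sort).  All-equal
    input still fills both masks deterministically, with a warning.
    """
    censor = np.asarray(censor, dtype=bool)
    vals = np.asarray(metric_at_volumes, dtype=float)[censor]
    n = len(vals)
    if n < 8:
        raise ValueError("fewer than 8 retained volumes; states undefined")
    k = int(np.floor(n * fraction))
    order = np.argsort(vals, kind="stable")
    low = np.zeros(n, dtype=bool)
    high = np.zeros(n, dtype=bool)
    low[order[:k]] = True
    high[order[n - k:]] = True
    if np.ptp(vals) == 0:
        warnings.warn("metric constant over retained volumes; "
                      "states are tie-break artifacts")
    return StateMask(metric, low, high)


def state_fc_matrix(ts: ParcelTimeSeries, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over the masked retained volumes."""
    data = ts.retained()[np.asarray(mask, dtype=bool)]
    if data.shape[0] < 3:
        raise ValueError("too few volumes in state for correlation")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with the diagonal/|r|=1 guarded to the largest finite value."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    return np.arctanh(r)


def network_fc(fc: np.ndarray, partition: NetworkPartition,
               parcel_ids=None) -> np.ndarray:
    """Network-pair connectivity: mean raw correlation over all parcel pairs
    of the two networks (within-network: unordered distinct pairs).

    Returns the symmetric (n_networks, n_networks) table.
    """
    fc = np.asarray(fc, dtype=float)
    if parcel_ids is None:
        parcel_ids = np.arange(1, fc.shape[0] + 1)
    B = partition.indicator(parcel_ids)
    sizes = B.sum(axis=0)
    S = B.T @ fc @ B  # sum of r over ordered cross pairs (incl. diagonal)
    nn = partition.n_networks
    out = np.empty((nn, nn))
    for i in range(nn):
        for j in range(nn):
            if i == j:
                npairs = sizes[i] * (sizes[i] - 1) / 2
                out[i, j] = (S[i, i] - sizes[i]) / (2 * npairs)
            else:
                out[i, j] = S[i, j] / (sizes[i] * sizes[j])
    return out


def state_motion(fd: np.ndarray, censor: np.ndarray, mask: np.ndarray) -> float:
    """Mean framewise displacement over the state's volumes only."""
    fd_ret = np.asarray(fd, dtype=float)[np.asarray(censor, dtype=bool)]
    return float(fd_ret[np.asarray(mask, dtype=bool)].mean())


def seed_state_difference(ts_list, seed_parcel_index: int, masks_list,
                          groups) -> pd.DataFrame:
    """Seed-based low-vs-high state contrast across subjects.

    For each subject, the per-parcel difference in Fisher-z seed correlations
    ``z(high) - z(low)``; returns a frame with per-group means and the
    two-sample t (group 1 minus group 0) per parcel.
    """
    from scipy import stats as _st

    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    dz = []
    for ts, sm in zip(ts_list, masks_list):
        r_low = state_fc_matrix(ts, sm.low)[seed_parcel_index]
        r_high = state_fc_matrix(ts, sm.high)[seed_parcel_index]
        dz.append(fisher_z(r_high) - fisher_z(r_low))
    dz = np.array(dz)
    dz[:, seed_parcel_index] = 0.0
    g0 = dz[groups == labels[0]]
    g1 = dz[groups == labels[1]]
    t, p = _st.ttest_ind(g1, g0, axis=0)
    return pd.DataFrame({
        "parcel_index": np.arange(dz.shape[1]),
        f"mean_dz_{labels[0]}": g0.mean(axis=0),
        f"mean_dz_{labels[1]}": g1.mean(axis=0),
        "t": t,
        "p": p,
    })
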