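"""Synthetic cardiac + fMRI datasets with planted, recoverable structure.

The generator emulates the statistical structure the analysis assumes for a
resting-state EEG-fMRI cohort: ~20-min scans at TR = 3 s, beat records whose
successive-difference spectrum carries distinct LF (0.04-0.15 Hz) and HF
(0.15-0.40 Hz) modulation with amplitude that varies within the scan, motion
traces with occasional spikes, and parcel BOLD built from shared network
latents.  One designated network pair carries a planted HRV-state-by-group
interaction: the latent correlation of that pair is ``r0 + s * dr / 2`` with
``s = +1`` in ground-truth high-LF-state volumes and ``-1`` in low-state
volumes, and the sign of ``dr`` flipped between groups (controls lose
connectivity in the high state, patients gain it).

RR intervals are generated directly as modulated intervals — a deliberate
stand-in for a full pulse-frequency-modulation cardiac model; it is simpler
and exercises every HRV formula downstream.  Ground-truth states come from
the generated LF-amplitude profile, not from estimated HRV, so state
estimation error is measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cardiac import RRSeries
from .glm import canonical_hrf
from .preproc import MotionParams
from .state_fc import NETWORK_SIZES, N_PARCELS, NetworkPartition

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedSubject",
    "default_partition",
    "block_amplitude_profile",
    "gen_rr_series",
    "gen_ecg_trace",
    "gen_motion",
    "gen_bold_dataset",
]


def default_partition() -> NetworkPartition:
    """Synthetic parcel->network partition with the published network sizes.

    Parcels 1..210 are cortical (seven networks in listed order followed by
    the three unassigned parcels), 211..246 subcortical (amygdala,
    hippocampus, basal ganglia, thalamus).  The assignment is synthetic —
    contiguous ID blocks, not the anatomical atlas mapping — but has the
    exact published counts, which is all the pipeline depends on.
    """
    rows = []
    pid = 1
    cortical = ["visual", "somatomotor", "dorsal attention", "ventral attention",
                "limbic", "frontoparietal", "default mode"]
    for net in cortical:
        for _ in range(NETWORK_SIZES[net]):
            rows.append((pid, f"parcel_{pid:03d}", net))
            pid += 1
    for _ in range(3):
        rows.append((pid, f"parcel_{pid:03d}", "unassigned"))
        pid += 1
    for net in ["amygdala", "hippocampus", "basal ganglia", "thalamus"]:
        for _ in range(NETWORK_SIZES[net]):
            rows.append((pid, f"parcel_{pid:03d}", net))
            pid += 1
    assert pid - 1 == N_PARCELS
    table = pd.DataFrame(rows, columns=["parcel_id", "parcel_name", "network"])
    return NetworkPartition(table)


def block_amplitude_profile(high: float, low: float, block_s: float = 150.0):
    """Square-wave amplitude profile alternating high/low blocks.

    Returns ``profile(t) -> amplitude`` starting in a high block.  The
    alternation gives each scan a balanced mix of high- and low-LF epochs so
    quartile states fall inside coherent blocks.
    """

    def profile(t):
        t = np.asarray(t, dtype=float)
        return np.where((t // block_s) % 2 == 0, high, low)

    return profile


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults mirror the emulated study: 16 controls and 28 patients, 20-min
    scans of 400 volumes at TR = 3 s, group baseline RR of ~1100 ms
    (controls) vs ~950 ms (patients), LF/HF modulation at 0.10 / 0.30 Hz,
    and a planted group-by-state connectivity interaction of |dr| = 0.4
    between the ventral attention and thalamus networks.
    """

    n_controls: int = 16
    n_patients: int = 28
    n_volumes: int = 400
    tr: float = 3.0
    baseline_rr: dict = field(default_factory=lambda: {"control": 1100.0,
                                                       "patient": 950.0})
    baseline_rr_sd: dict = field(default_factory=lambda: {"control": 200.0,
                                                          "patient": 100.0})
    lf_freq: float = 0.10
    hf_freq: float = 0.30
    lf_amp_high: float = 40.0   # ms, high-LF blocks
    lf_amp_low: float = 8.0     # ms, low-LF blocks
    hf_amp: float = 25.0        # ms, constant HF modulation
    lf_block_s: float = 150.0
    rr_noise_sd: float = 5.0    # ms white noise on intervals
    interaction_pair: tuple = ("ventral attention", "thalamus")
    r0: float = 0.3
    interaction_effect: float = 0.4   # |dr| across states; sign flips by group
    latent_loading: float = 1.0
    noise_sd: float = 0.65      # parcel noise, latent units
    motion_drift_sd: float = 0.02
    motion_spike_rate: float = 0.05
    motion_spike_mm: float = 0.35
    n_wm_voxels: int = 60
    hr_coupled_parcel: int | None = None
    hr_coupling_beta: float = 0.0
    global_signal_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_controls, self.n_patients, self.n_volumes) <= 0:
            raise ValueError("counts must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 < self.lf_freq < self.hf_freq):
            raise ValueError("need 0 < lf_freq < hf_freq")
        if abs(self.interaction_effect) >= 1:
            raise ValueError("|interaction_effect| must be < 1")
        for g, base in self.baseline_rr.items():
            if self.lf_amp_high + self.hf_amp >= base:
                raise ValueError(f"modulation amplitude >= baseline RR for {g}")
        for pair in (self.r0 - self.interaction_effect / 2,
                     self.r0 + self.interaction_effect / 2):
            if not -1 < pair < 1:
                raise ValueError("planted correlation outside (-1, 1)")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def lf_amp_profile(self):
        return block_amplitude_profile(self.lf_amp_high, self.lf_amp_low,
                                       self.lf_block_s)

    def to_json(self) -> str:
        d = asdict(self)
        d["interaction_pair"] = list(d["interaction_pair"])
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    interaction_pair: tuple
    dr_by_group: dict                 # group -> (r_high - r_low) of latents
    high_state_volumes: dict          # subject -> bool array over volumes
    lf_amp_at_volumes: dict           # subject -> amplitude profile samples
    hr_coupling: dict                 # subject -> (parcel, beta)
    seeds: dict


@dataclass
class SimulatedSubject:
    subject: str
    group: str
    sex: int
    age: float
    rr: RRSeries
    motion: MotionParams
    bold: np.ndarray                  # (n_volumes, 246)
    wm_voxels: np.ndarray             # (n_volumes, n_wm_voxels)


def _subject_rng(config: SimConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_index, stream])
    )


def gen_rr_series(config: SimConfig, subject_index: int = 0,
                  group: str = "control", baseline: float | None = None,
                  lf_amp_profile=None, hf_amp_profile=None,
                  noise_sd: float | None = None,
                  outlier_times=()) -> RRSeries:
    """Beat record with sinusoidal LF/HF modulation of the RR intervals.

    ``rr_i = baseline + a_LF(t_i) sin(2 pi f_LF t_i) + a_HF(t_i)
    sin(2 pi f_HF t_i) + noise``, with beats accumulated until the scan
    duration is covered.  ``outlier_times`` (s) plant isolated halved beats
    (one RR split into a short/long pair) for exercising the MAD rule.
    """
    rng = _subject_rng(config, subject_index, 0)
    if baseline is None:
        baseline = config.baseline_rr[group]
    if lf_amp_profile is None:
        lf_amp_profile = config.lf_amp_profile()
    if hf_amp_profile is None:
        hf_amp_profile = lambda t: np.full_like(np.asarray(t, float), config.hf_amp)
    if noise_sd is None:
        noise_sd = config.rr_noise_sd
    if float(np.max(lf_amp_profile(np.linspace(0, config.duration, 50)))) + \
            float(np.max(hf_amp_profile(np.linspace(0, config.duration, 50)))) \
            >= baseline:
        raise ValueError("modulation amplitude >= baseline would yield RR <= 0")

    t = 0.0
    beats = [0.0]
    margin = config.duration + 120.0  # run past scan end so edge windows fill
    while t < margin:
        rr_ms = (baseline
                 + float(lf_amp_profile(t)) * np.sin(2 * np.pi * config.lf_freq * t)
                 + float(hf_amp_profile(t)) * np.sin(2 * np.pi * config.hf_freq * t)
                 + (rng.standard_normal() * noise_sd if noise_sd else 0.0))
        t += rr_ms / 1000.0
        beats.append(t)
    beats = np.array(beats)
    for ot in outlier_times:
        i = int(np.searchsorted(beats, ot))
        if 0 < i < len(beats) - 1:
            # insert an ectopic-like early beat, splitting one interval
            beats = np.insert(beats, i, (beats[i - 1] + beats[i]) / 2)
    return RRSeries.from_beat_times(beats)


def gen_ecg_trace(rr: RRSeries, fs: float = 250.0,
                  qrs_width: float = 0.02, amplitude: float = 1.0,
                  noise_sd: float = 0.0, seed=None) -> np.ndarray:
    """Toy ECG: Gaussian QRS-like bumps at the beat times (R-peak fixture)."""
    rng = np.random.default_rng(seed)
    n = int(np.ceil(rr.beat_times[-1] * fs)) + 1
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    for bt in rr.beat_times:
        ecg += amplitude * np.exp(-0.5 * ((t - bt) / qrs_width) ** 2)
    if noise_sd:
        ecg += rng.standard_normal(n) * noise_sd
    return ecg


def gen_motion(config: SimConfig, subject_index: int = 0,
               drift_sd: float | None = None,
               spike_rate: float | None = None,
               spike_mm: float | None = None) -> MotionParams:
    """Six-parameter motion trace: smooth random-walk drift plus rare spikes.

    Spikes are one-volume translation jumps of ~``spike_mm`` (> 0.2 mm, so
    they trip the censoring rule by construction).
    """
    rng = _subject_rng(config, subject_index, 1)
    n = config.n_volumes
    drift_sd = config.motion_drift_sd if drift_sd is None else drift_sd
    spike_rate = config.motion_spike_rate if spike_rate is None else spike_rate
    spike_mm = config.motion_spike_mm if spike_mm is None else spike_mm
    steps = rng.standard_normal((n, 6)) * drift_sd
    steps[:, 3:] /= 50.0  # rotations contribute via the 50-mm arm
    params = np.cumsum(steps, axis=0)
    spikes = rng.random(n) < spike_rate
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        params[i, 0] += spike_mm * (1 + 0.5 * rng.random()) * rng.choice([-1, 1])
    return MotionParams(params)


def _correlated_pair(rng, n, r_t):
    """Two unit-variance series whose instantaneous correlation is r_t."""
    z1 = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z2 = r_t * z1 + np.sqrt(1.0 - r_t ** 2) * e
    return z1, z2


def gen_bold_dataset(config: SimConfig):
    """Full synthetic cohort: subjects, parcel BOLD, motion, RR, ground truth.

    Returns ``(subjects, subject_table, partition, truth)`` where ``subjects``
    is a list of :class:`SimulatedSubject` and ``subject_table`` a DataFrame
    with group/sex/age.  Parcel signal is ``loading * network latent + parcel
    noise``; the designated pair's latent correlation switches between
    ``r0 - dr/2`` and ``r0 + dr/2`` with the ground-truth LF state, with the
    state effect sign flipped between groups.
    """
    partition = default_partition()
    groups = ["control"] * config.n_controls + ["patient"] * config.n_patients
    lf_profile = config.lf_amp_profile()
    vol_times = np.arange(config.n_volumes) * config.tr
    lf_at_vol = lf_profile(vol_times)
    high_state = lf_at_vol > (config.lf_amp_high + config.lf_amp_low) / 2

    net_a, net_b = config.interaction_pair
    ia = partition.networks.index(net_a)
    ib = partition.networks.index(net_b)

    subjects = []
    rows = []
    truth = GroundTruth(
        interaction_pair=config.interaction_pair,
        dr_by_group={"control": -config.interaction_effect,
                     "patient": +config.interaction_effect},
        high_state_volumes={}, lf_amp_at_volumes={}, hr_coupling={},
        seeds={"root": config.seed},
    )
    for s_idx, group in enumerate(groups):
        rng = _subject_rng(config, s_idx, 2)
        name = f"sub-{s_idx + 1:03d}"
        # subject baseline RR drawn around the group level (the +-sd spread
        # is across subjects, not within-scan), kept clear of the modulation
        baseline = float(np.clip(
            config.baseline_rr[group]
            + rng.standard_normal() * config.baseline_rr_sd[group],
            700.0, 1600.0))
        rr = gen_rr_series(config, s_idx, group, baseline=baseline)
        motion = gen_motion(config, s_idx)

        sign = -1.0 if group == "control" else 1.0
        r_t = np.where(high_state,
                       config.r0 + sign * config.interaction_effect / 2,
                       config.r0 - sign * config.interaction_effect / 2)
        n = config.n_volumes
        nn = partition.n_networks
        latents = rng.standard_normal((n, nn))
        la, lb = _correlated_pair(rng, n, r_t)
        latents[:, ia] = la
        latents[:, ib] = lb

        B = partition.indicator(np.arange(1, N_PARCELS + 1))
        bold = (config.latent_loading * latents @ B.T
                + rng.standard_normal((n, N_PARCELS)) * config.noise_sd)
        # unassigned parcels carry pure noise already (zero indicator rows)

        if config.global_signal_sd:
            bold += rng.standard_normal((n, 1)) * config.global_signal_sd
        if config.hr_coupled_parcel is not None:
            from .cardiac import instantaneous_hr
            hr_1s = instantaneous_hr(rr, np.arange(int(config.duration)))
            conv = np.convolve(hr_1s - hr_1s.mean(), canonical_hrf(1.0))[:len(hr_1s)]
            at_vol = np.interp(vol_times, np.arange(len(conv), dtype=float), conv)
            j = int(config.hr_coupled_parcel) - 1
            bold[:, j] += config.hr_coupling_beta * at_vol
            truth.hr_coupling[name] = (config.hr_coupled_parcel,
                                       config.hr_coupling_beta)

        wm = rng.standard_normal((n, config.n_wm_voxels))
        sex = int(rng.random() < 0.5)
        age = float(rng.uniform(20, 45))
        subjects.append(SimulatedSubject(name, group, sex, age, rr, motion,
                                         bold, wm))
        rows.append({"subject": name, "group": group, "sex": sex, "age": age})
        truth.high_state_volumes[name] = high_state.copy()
        truth.lf_amp_at_volumes[name] = lf_at_vol.copy()
        truth.seeds[name] = [config.seed, s_idx]

    return subjects, pd.DataFrame(rows), partition, truth
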