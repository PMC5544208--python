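"""Synthetic rapid event-related BOLD generator with ground truth.

Emulates the statistical structure the decoding method assumes: two
stimulus classes presented for 2 s each with 1-10 s jittered fixation at
TR = 2 s, class-specific sparse voxel patterns, hemodynamic responses
that overlap across neighbouring trials, low-frequency drift confounds,
and AR(1) serially correlated Gaussian noise. Every random quantity is
drawn from a single seeded generator, so a configuration reproduces the
identical dataset bit-for-bit.

SNR is defined as the standard deviation of the noiseless signal in
pattern-carrying voxels divided by the marginal noise standard
deviation, averaged over those voxels (the literature rarely pins this
down, so the convention is stated here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .design import (HRFModel, TrialTable, DEFAULT_MICROTIME_DT,
                     hrf_kernel, place_event)

_TAIL_S = 24.0  # rest after the last stimulus so its response is observed


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults mirror the experimental protocol the method targets:
    40 trials per class, 2 s stimuli, 1-10 s jitter, TR 2 s. Pattern
    geometry, amplitude variability, drift and AR(1) noise are the
    package's stated desk-scale conventions.
    """

    n_voxels: int = 96
    n_trials_per_class: int = 40
    stim_duration_s: float = 2.0
    jitter_range_s: tuple[float, float] = (1.0, 10.0)
    TR_s: float = 2.0
    pattern_sparsity: float = 0.25
    pattern_overlap: float = 0.25
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.25
    snr: float = 1.0
    ar1_rho: float = 0.2
    drift_amplitude: float = 1.0
    identical_patterns: bool = False
    class_names: tuple[str, str] = ("A", "B")
    microtime_dt: float = DEFAULT_MICROTIME_DT
    hrf: HRFModel = field(default_factory=HRFModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1 or self.n_trials_per_class < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.pattern_sparsity <= 1.0:
            raise ValueError("pattern_sparsity must lie in [0, 1]")
        if not 0.0 <= self.pattern_overlap <= 1.0:
            raise ValueError("pattern_overlap must lie in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        lo, hi = self.jitter_range_s
        if lo < 0 or hi < lo:
            raise ValueError("invalid jitter range")


@dataclass
class BoldDataset:
    """M x N voxel time-series matrix inside a feature mask."""

    data: np.ndarray
    TR: float
    voxel_coords: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Everything needed to verify recovery: true patterns, per-trial
    amplitudes, labels, and the seed of the noise realization."""

    w_A: np.ndarray
    w_B: np.ndarray
    amplitudes: np.ndarray
    labels: np.ndarray
    support_A: np.ndarray
    support_B: np.ndarray
    noiseless: np.ndarray
    seed: int

    @property
    def discriminative(self) -> np.ndarray:
        """True discriminative voxel weights, w_A - w_B."""
        return self.w_A - self.w_B


def simulate_events(cfg: SimConfig,
                    rng: np.random.Generator | None = None) -> TrialTable:
    """Randomized interleaving of the two classes with jittered gaps.

    Inter-onset gap = stimulus duration + Uniform(jitter range); onsets
    land on the microtime grid.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    a, b = cfg.class_names
    labels = np.array([a] * cfg.n_trials_per_class
                      + [b] * cfg.n_trials_per_class, dtype=object)
    labels = labels[rng.permutation(len(labels))]
    lo, hi = cfg.jitter_range_s
    gaps = cfg.stim_duration_s + rng.uniform(lo, hi, size=len(labels))
    onsets = np.cumsum(gaps)
    onsets = np.round(onsets / cfg.microtime_dt) * cfg.microtime_dt
    return TrialTable(onsets=onsets,
                      durations=np.full(len(labels), cfg.stim_duration_s),
                      labels=labels,
                      target_flags=np.zeros(len(labels), dtype=bool))


def _sparse_patterns(cfg: SimConfig, rng: np.random.Generator):
    n_active = max(1, int(round(cfg.pattern_sparsity * cfg.n_voxels)))
    n_shared = int(round(cfg.pattern_overlap * n_active))
    need = 2 * n_active - n_shared
    if need > cfg.n_voxels:
        raise ValueError("pattern supports do not fit in the voxel count")
    perm = rng.permutation(cfg.n_voxels)
    shared = perm[:n_shared]
    only_a = perm[n_shared:n_active]
    only_b = perm[n_active:need]
    sup_a = np.sort(np.concatenate([shared, only_a])).astype(int)
    sup_b = np.sort(np.concatenate([shared, only_b])).astype(int)
    w_A = np.zeros(cfg.n_voxels)
    w_B = np.zeros(cfg.n_voxels)
    w_A[sup_a] = rng.normal(0.0, 1.0, size=len(sup_a))
    if cfg.identical_patterns:
        w_B, sup_b = w_A.copy(), sup_a.copy()
    else:
        w_B[sup_b] = rng.normal(0.0, 1.0, size=len(sup_b))
    return w_A, w_B, sup_a, sup_b


def _drift(M: int, TR: float, n_vox: int, amp: float,
           rng: np.random.Generator, cutoff_s: float = 128.0) -> np.ndarray:
    K = int(np.floor(2.0 * M * TR / cutoff_s))
    if K == 0 or amp == 0:
        return np.zeros((M, n_vox))
    m = np.arange(M)
    basis = np.column_stack([np.cos(np.pi * k * (2 * m + 1) / (2 * M))
                             for k in range(1, K + 1)])
    coefs = rng.normal(0.0, amp, size=(K, n_vox))
    return basis @ coefs


def _ar1_noise(M: int, n_vox: int, rho: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    e = rng.normal(0.0, 1.0, size=(M, n_vox))
    if rho > 0:
        x = lfilter([1.0], [1.0, -rho], e, axis=0)
        # stationary marginal sd of the filtered series is 1/sqrt(1-rho^2)
        x *= np.sqrt(1.0 - rho ** 2)
    else:
        x = e
    return sd * x


def simulate_bold(trials: TrialTable, cfg: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[BoldDataset, GroundTruth]:
    """Generate the voxel time-series matrix for an event sequence.

    Y = sum_class conv(sticks_class * amplitudes) (x) pattern_class
        + drift + AR(1) noise scaled to the requested SNR.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    TR, dt = cfg.TR_s, cfg.microtime_dt
    last = trials.onsets[-1] + trials.durations[-1]
    M = int(np.ceil((last + _TAIL_S) / TR))
    if M * TR < last:
        raise ValueError("scan count too small to contain all events")
    n_fine = int(round(M * TR / dt))
    kernel = hrf_kernel(cfg.hrf, dt)
    scan_idx = np.round(np.arange(M) * TR / dt).astype(int)

    w_A, w_B, sup_a, sup_b = _sparse_patterns(cfg, rng)
    amplitudes = rng.normal(cfg.amplitude_mean, cfg.amplitude_sd,
                            size=len(trials))

    a, b = cfg.class_names
    signal = np.zeros((M, cfg.n_voxels))
    for cls, w in ((a, w_A), (b, w_B)):
        neural = np.zeros(n_fine)
        for i in np.flatnonzero(trials.labels == cls):
            place_event(neural, trials.onsets[i], trials.durations[i], dt,
                        amplitudes[i])
        conv = (np.convolve(neural, kernel)[:n_fine] * dt)[scan_idx]
        signal += np.outer(conv, w)

    active = np.union1d(sup_a, sup_b)
    sig_sd = float(np.mean(signal[:, active].std(axis=0))) if len(active) else 0.0
    noise_sd = sig_sd / cfg.snr if sig_sd > 0 else 0.0

    Y = (signal
         + _drift(M, TR, cfg.n_voxels, cfg.drift_amplitude, rng)
         + _ar1_noise(M, cfg.n_voxels, cfg.ar1_rho, noise_sd, rng))

    truth = GroundTruth(w_A=w_A, w_B=w_B, amplitudes=amplitudes,
                        labels=trials.labels.copy(),
                        support_A=sup_a, support_B=sup_b,
                        noiseless=signal, seed=cfg.seed)
    return BoldDataset(data=Y, TR=TR), truth


def simulate_dataset(cfg: SimConfig) -> tuple[TrialTable, BoldDataset, GroundTruth]:
    """Events plus BOLD in one call from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    trials = simulate_events(cfg, rng)
    bold, truth = simulate_bold(trials, cfg, rng)
    return trials, bold, truth
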