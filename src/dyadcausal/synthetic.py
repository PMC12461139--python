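"""Synthetic dyad generator with known ground-truth direction of influence.

Emulates HbO-like recordings of a two-person imitation experiment: the
Model watches instruction videos (20 s task blocks separated by 60 s rest)
and moves; the Imitator copies the Model with a short lag.  Each region
channel is a sum of

* a task component: the event boxcar ("neural drive") convolved with a
  difference-of-gammas hemodynamic response; the Imitator's drive is the
  Model's drive delayed by ``coupling_lag`` samples (plus an optional
  condition-specific reaction-time delay) and scaled by ``coupling_gain`` —
  coupling acts on the pre-hemodynamic drive, and both sides are convolved
  with the same response kernel;
* an AR(1) background (coefficient 0.9) band-limited to the analysis band;
* a shared ~0.1 Hz Mayer-wave confounder with the *same phase* in both
  participants and in the short-distance channels (the designed spurious-
  causality stressor the causal measure must reject);
* independent white measurement noise.

Short-distance channels (SDC) carry only confounder + noise — no task
drive and no coupling — mirroring their role as a no-causality reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .io import DyadRecording, EventTable
from .preprocess import bandpass_filter

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "canonical_hrf",
    "simulate_dyad",
    "make_dataset",
    "truth_frame",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and signal parameters of the simulated experiment.

    Defaults follow the experimental protocol the generator emulates:
    10.17 Hz sampling, ten 20-s task trials per condition each preceded by
    60 s of rest, a Model->Imitator lag of 2 samples (~200 ms), a shared
    0.1 Hz confounder, and 3 region + 3 short-distance channels per
    participant.
    """

    fs: float = 10.17
    n_trials_per_condition: int = 10
    conditions: tuple[str, ...] = ("hand", "foot")
    task_duration: float = 20.0
    baseline_duration: float = 60.0
    coupling_gain: float = 1.0
    coupling_lag: int = 2                       # samples (~200 ms)
    confounder_amplitude: float = 0.3
    confounder_freq: float = 0.1                # Hz (Mayer waves)
    noise_sd: float = 0.5
    drive_noise_sd: float = 0.5
    background_sd: float = 0.3
    ar_coeff: float = 0.9
    hrf_peak_delay: float = 6.0                 # s
    # Behavioral reaction delay of the Imitator relative to the Model, in
    # seconds; foot responses lag more than hand responses.
    imitator_onset_delay: float | dict = field(
        default_factory=lambda: {"hand": 1.0, "foot": 2.0})
    task_amplitude: float = 1.0
    n_channels_region: int = 3
    n_sdc: int = 3
    region: str = "M1"
    tail_padding: float = 40.0                  # s after the last trial
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.task_duration, self.baseline_duration, self.tail_padding) <= 0:
            raise ValueError("durations must be positive")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1 sample")
        if self.fs <= 2 * self.confounder_freq:
            raise ValueError("fs must exceed twice the confounder frequency")
        if self.n_trials_per_condition < 1 or self.n_channels_region < 1:
            raise ValueError("need at least one trial and one region channel")

    def onset_delay(self, condition: str) -> float:
        if isinstance(self.imitator_onset_delay, dict):
            return float(self.imitator_onset_delay.get(condition, 0.0))
        return float(self.imitator_onset_delay)

    def total_lag(self, condition: str) -> int:
        """Total Model->Imitator delay in samples for one condition."""
        return self.coupling_lag + int(round(self.onset_delay(condition) * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """Simulator label for one epoch-able interval."""

    true_direction: str        # "M_to_I" or "none"
    lag: int                   # samples (0 when no link)
    condition: str
    trial_index: int
    dyad_id: str = "dyad"


def canonical_hrf(t, peak_delay: float = 6.0) -> np.ndarray:
    """Difference-of-gammas hemodynamic response, unit peak, zero at t=0.

    The positive lobe is a gamma density peaking at ``peak_delay`` seconds;
    a later, 1/6-amplitude gamma lobe produces the post-stimulus undershoot.
    Negative times return 0 by convention.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    shape1 = peak_delay + 1.0          # rate-1 gamma peaks at shape - 1
    shape2 = peak_delay + 11.0
    h = stats.gamma.pdf(t, shape1) - stats.gamma.pdf(t, shape2) / 6.0
    h[t < 0] = 0.0
    peak = stats.gamma.pdf(peak_delay, shape1) - stats.gamma.pdf(peak_delay, shape2) / 6.0
    h = h / peak
    return float(h[0]) if scalar else h


def _condition_sequence(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Pseudo-randomized order: each shuffle round shows every condition once."""
    order: list[str] = []
    for _ in range(cfg.n_trials_per_condition):
        block = list(cfg.conditions)
        rng.shuffle(block)
        order.extend(block)
    return order


def _ar1_background(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    raw = sps.lfilter([1.0], [1.0, -cfg.ar_coeff], rng.standard_normal(n))
    band = bandpass_filter(raw, cfg.fs)
    sd = band.std()
    return band * (cfg.background_sd / sd) if sd > 0 else band


def simulate_dyad(cfg: SimulationConfig, seed=None, dyad_id: str = "dyad01"
                  ) -> tuple[DyadRecording, EventTable, list[GroundTruth]]:
    """Simulate one dyad: recording, events table, and per-epoch ground truth.

    The events table contains one ``baseline`` event per trial (its 204-
    sample window end-aligned with the upcoming video onset, well clear of
    the previous task) followed by the task event itself.  Ground-truth
    labels align with the events row order.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.fs
    epoch_len, pre_onset = 204, 10

    order = _condition_sequence(cfg, rng)
    n_trials = len(order)
    rest_samples = int(round(cfg.baseline_duration * fs))
    task_samples = int(round(cfg.task_duration * fs))
    L = n_trials * (rest_samples + task_samples) + int(round(cfg.tail_padding * fs))

    # event bookkeeping (exact sample arithmetic, reported in seconds)
    events_rows = []
    truth: list[GroundTruth] = []
    drive_m = np.zeros(L)
    drive_i = np.zeros(L)
    cursor = 0
    coupled = cfg.coupling_gain > 0
    for k, condition in enumerate(order):
        video_start = cursor + rest_samples
        # Model neural drive: task boxcar plus motor-performance variability
        # (white modulation, task-gated).  The stochastic part is what makes
        # the direction information-theoretically recoverable: a purely
        # deterministic response would be predictable from the Imitator's
        # own past alone.
        drive_m[video_start : video_start + task_samples] = (
            1.0 + cfg.drive_noise_sd * rng.standard_normal(task_samples))
        lag = cfg.total_lag(condition)
        i_start = video_start + lag
        i_stop = min(i_start + task_samples, L)
        # Imitator copies the Model's *realized* drive, delayed and scaled
        drive_i[i_start:i_stop] = (
            cfg.coupling_gain * drive_m[video_start : video_start + (i_stop - i_start)])

        base_start = video_start - epoch_len          # end-aligned rest window
        events_rows.append({
            "onset": (base_start + pre_onset) / fs,
            "duration": epoch_len / fs,
            "condition": "baseline",
            "trial_index": k,
        })
        truth.append(GroundTruth("none", 0, "baseline", k, dyad_id))
        events_rows.append({
            "onset": video_start / fs,
            "duration": cfg.task_duration,
            "condition": condition,
            "trial_index": k,
        })
        truth.append(GroundTruth("M_to_I" if coupled else "none",
                                 lag if coupled else 0, condition, k, dyad_id))
        cursor = video_start + task_samples

    # hemodynamic task components; the scale is set so the *mean* (noise-free
    # boxcar) response peaks at task_amplitude
    kernel_t = np.arange(0.0, 40.0, 1.0 / fs)
    kernel = canonical_hrf(kernel_t, cfg.hrf_peak_delay)
    boxcar_peak = np.max(np.convolve(np.ones(task_samples), kernel))
    if boxcar_peak > 0:
        scale = cfg.task_amplitude / boxcar_peak
        task_m = sps.fftconvolve(drive_m, kernel)[:L] * scale
        task_i = sps.fftconvolve(drive_i, kernel)[:L] * scale
    else:
        task_m = np.zeros(L)
        task_i = np.zeros(L)

    t = np.arange(L) / fs
    conf_phase = rng.uniform(0.0, 2.0 * np.pi)        # shared by everyone
    confounder = np.sin(2.0 * np.pi * cfg.confounder_freq * t + conf_phase)

    def make_channel(task: np.ndarray | None) -> np.ndarray:
        gain = rng.uniform(0.8, 1.2)
        conf_gain = rng.uniform(0.8, 1.2)
        x = cfg.confounder_amplitude * conf_gain * confounder \
            + cfg.noise_sd * rng.standard_normal(L)
        if task is not None:
            x = x + gain * task + _ar1_background(L, cfg, rng)
        return x

    labels: list[str] = []
    columns: list[np.ndarray] = []
    role_map: dict[str, str] = {}
    region_map: dict[str, str] = {}
    for prefix, role, task in (("M", "Model", task_m), ("I", "Imitator", task_i)):
        for c in range(cfg.n_channels_region):
            ch = f"{prefix}_{cfg.region}_{c + 1}"
            labels.append(ch)
            columns.append(make_channel(task))
            role_map[ch] = role
            region_map[ch] = cfg.region
        for c in range(cfg.n_sdc):
            ch = f"{prefix}_SDC_{c + 1}"
            labels.append(ch)
            columns.append(make_channel(None))
            role_map[ch] = role
            region_map[ch] = "SDC"

    rec = DyadRecording(samples=np.column_stack(columns), fs=fs,
                        channel_labels=labels, role_map=role_map,
                        region_map=region_map, chromophore="HbO",
                        dyad_id=dyad_id)
    events = EventTable(pd.DataFrame(events_rows))
    return rec, events, truth


def make_dataset(n_dyads: int, cfg: SimulationConfig | None = None, seed: int = 0
                 ) -> list[tuple[DyadRecording, EventTable, list[GroundTruth]]]:
    """Independent dyads from per-dyad seeds spawned off one master seed."""
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    cfg = cfg or SimulationConfig()
    streams = np.random.SeedSequence(seed).spawn(n_dyads)
    out = []
    for k, stream in enumerate(streams):
        dyad_id = f"dyad{k + 1:02d}"
        out.append(simulate_dyad(cfg, seed=np.random.default_rng(stream),
                                 dyad_id=dyad_id))
    return out


def truth_frame(truth: list[GroundTruth]) -> pd.DataFrame:
    """Ground-truth labels as a flat table (writable next to the events CSV)."""
    return pd.DataFrame([{
        "dyad_id": g.dyad_id,
        "trial_index": g.trial_index,
        "condition": g.condition,
        "true_direction": g.true_direction,
        "lag": g.lag,
    } for g in truth])
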