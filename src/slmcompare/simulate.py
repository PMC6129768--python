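"""Ground-truth-known synthetic EEG with pre-movement slow potentials.

The generator produces the statistical structure the analysis pipeline
assumes: each trial is a stretch of resting activity (random background
sources with 1/f-shaped time courses plus white sensor noise) followed by a
movement-related cortical potential — a slow negative-going ramp at chosen
cortical source vertices beginning a fixed lead time (default 2 s) before
the movement onset marker.  Sensor data are the lead-field projection of all
source activity plus Gaussian sensor noise; every random draw comes from one
recorded seed, so recordings are bit-reproducible.  Matching motion-tracking
kinematics (stationary, then a fast ~20 cm reach) are generated so that
threshold-based onset detection can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward import LeadField
from .pipeline import Recording

__all__ = [
    "SimulationConfig",
    "SyntheticRecording",
    "mrcp_waveform",
    "simulate_trials",
    "simulate_kinematics",
    "save_recording",
    "load_recording",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator.

    active_vertices : ground-truth source vertices carrying the MRCP.
    moments : (len(active_vertices), 3) dipole moment directions (nA·m per
        unit waveform amplitude); normalized internally.
    mrcp_peak : peak source amplitude in nA·m reached at movement onset.
    mrcp_onset_lead : seconds before onset at which the ramp starts.
    background_count / background_amplitude : number of random nuisance
        sources per trial and their RMS amplitude (nA·m).
    sensor_noise_sd : white sensor noise standard deviation in µV.
    trials_per_run, runs : trial structure (three runs, as in a three-fold
        by-run evaluation).
    rate : sampling rate in Hz (the pipeline's 20 Hz analysis rate by
        default; use 5000 to exercise the decimation chain).
    """

    active_vertices: tuple[int, ...] = (0,)
    moments: np.ndarray | None = None
    mrcp_peak: float = 60.0
    mrcp_onset_lead: float = 2.0
    background_count: int = 3
    background_amplitude: float = 10.0
    sensor_noise_sd: float = 1.0
    trials_per_run: int = 40
    runs: int = 3
    rate: float = 20.0
    rest_duration: float = 3.2
    post_duration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_run < 1:
            raise ValueError("trials_per_run must be >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.mrcp_onset_lead <= 0:
            raise ValueError("mrcp_onset_lead must be positive")


@dataclass
class SyntheticRecording:
    """One run's Recording plus everything needed to reconstruct it."""

    recording: Recording
    active_vertices: np.ndarray
    source_timecourses: np.ndarray  # (3*N_active, n_times) nA·m
    background_vertices: list[np.ndarray]
    seed: int


def mrcp_waveform(
    t: np.ndarray | float,
    peak: float,
    lead: float = 2.0,
    execution_window: float = 0.3,
) -> np.ndarray | float:
    """Slow pre-movement negativity: 0 before ``-lead``, a monotone
    half-cosine ramp to ``-peak`` at t = 0, held through a brief execution
    window, then 0."""
    if lead <= 0:
        raise ValueError("lead must be positive")
    t = np.asarray(t, dtype=float)
    ramp = -peak * 0.5 * (1.0 - np.cos(np.pi * (t + lead) / lead))
    out = np.where((t >= -lead) & (t <= 0.0), ramp, 0.0)
    out = np.where((t > 0.0) & (t <= execution_window), -peak, out)
    return out if out.ndim else float(out)


def _one_over_f(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Unit-RMS noise with ~1/f amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * np.exp(2j * np.pi * rng.random(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    rms = x.std()
    return x / (rms if rms > 0 else 1.0)


def simulate_trials(config: SimulationConfig, lead_field: LeadField) -> list[SyntheticRecording]:
    """Generate one SyntheticRecording per run.

    Per trial: ``rest_duration`` seconds of background + sensor noise only,
    then the MRCP ramp at the configured vertices peaking at the onset
    marker, plus ``post_duration`` seconds after onset.  Sensor data are
    L s + n with Gaussian sensor noise of the configured standard deviation.
    """
    n_s = lead_field.n_sources
    active = np.asarray(config.active_vertices, dtype=int)
    if np.any(active < 0) or np.any(active >= n_s):
        raise ValueError(f"active vertex ids out of range [0, {n_s})")
    if config.moments is None:
        moments = np.tile([0.0, 0.0, 1.0], (len(active), 1))
    else:
        moments = np.atleast_2d(np.asarray(config.moments, dtype=float))
    moments = moments / np.linalg.norm(moments, axis=1, keepdims=True)
    rate = config.rate
    trial_len = int(round((config.rest_duration + config.post_duration) * rate))
    onset_in_trial = int(round(config.rest_duration * rate))
    t_rel = (np.arange(trial_len) - onset_in_trial) / rate
    wave = mrcp_waveform(t_rel, config.mrcp_peak, config.mrcp_onset_lead)
    rng = np.random.default_rng(config.seed)
    out: list[SyntheticRecording] = []
    for run in range(config.runs):
        n_t = trial_len * config.trials_per_run
        s = np.zeros((3 * n_s, n_t))
        bg_ids: list[np.ndarray] = []
        onsets = []
        for trial in range(config.trials_per_run):
            a = trial * trial_len
            onsets.append((a + onset_in_trial) / rate)
            for vid, mom in zip(active, moments):
                s[3 * vid : 3 * vid + 3, a : a + trial_len] += mom[:, None] * wave[None, :]
            ids = rng.choice(n_s, size=config.background_count, replace=False)
            bg_ids.append(ids)
            for vid in ids:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                tc = _one_over_f(rng, trial_len, rate) * config.background_amplitude
                s[3 * vid : 3 * vid + 3, a : a + trial_len] += direction[:, None] * tc[None, :]
        noise = rng.normal(scale=config.sensor_noise_sd, size=(lead_field.n_electrodes, n_t)) \
            if config.sensor_noise_sd > 0 else 0.0
        data = lead_field.matrix @ s + noise
        rec = Recording(data, rate, np.array(onsets), run_id=f"run{run + 1}")
        active_rows = np.concatenate([np.arange(3 * v, 3 * v + 3) for v in active])
        out.append(
            SyntheticRecording(rec, active.copy(), s[active_rows], bg_ids, config.seed)
        )
    return out


def simulate_kinematics(
    onset: float,
    duration: float | None = None,
    rate: float = 500.0,
    reach_mm: float = 200.0,
    precision: float = 0.075,
    peak_speed: float = 1.0,
    ramp_ms: float = 10.0,
) -> np.ndarray:
    """Motion-tracking trajectory: stationary, then a fast straight reach.

    Speed is zero before ``onset`` and follows a trapezoidal profile after
    it (10 ms linear ramp to ``peak_speed`` mm/ms, plateau, 10 ms ramp
    down), sized so total displacement equals ``reach_mm``.  The interval-
    averaged speed exceeds ``precision`` within one sample of the onset, so
    threshold-based detection recovers the onset to one-sample accuracy.
    Returns (n_times, 3) positions in mm.
    """
    ramp_s = ramp_ms / 1000.0
    v_peak = peak_speed * 1000.0  # mm/s
    plateau_s = (reach_mm - v_peak * ramp_s) / v_peak
    if plateau_s < 0:
        raise ValueError("reach too short for the requested peak speed")
    move_s = 2 * ramp_s + plateau_s
    if duration is None:
        duration = onset + move_s + 0.2
    t = np.arange(int(round(duration * rate))) / rate
    tau = t - onset
    v = np.zeros_like(t)
    rising = (tau >= 0) & (tau < ramp_s)
    flat = (tau >= ramp_s) & (tau < ramp_s + plateau_s)
    falling = (tau >= ramp_s + plateau_s) & (tau < move_s)
    v[rising] = v_peak * tau[rising] / ramp_s
    v[flat] = v_peak
    v[falling] = v_peak * (move_s - tau[falling]) / ramp_s
    x = np.cumsum(v) / rate
    traj = np.zeros((len(t), 3))
    traj[:, 0] = x  # rightward reach
    return traj


# ---------------------------------------------------------------------------
# container I/O: .npy samples + JSON header, ground truth JSON


def save_recording(rec: Recording, prefix: str | Path) -> None:
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), rec.samples)
    header = {
        "rate": rec.rate,
        "onsets": rec.onsets.tolist(),
        "run_id": rec.run_id,
        "n_channels": rec.n_channels,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    samples = np.load(prefix.with_suffix(".npy"))
    header = json.loads(prefix.with_suffix(".json").read_text())
    return Recording(samples, header["rate"], np.asarray(header["onsets"]), header["run_id"])
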