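"""Synthetic recording/performance envelope pairs for a learning study.

Emulates the design in which each of P performers plays along with the
same fixed stimulus recording J times in a row.  The performer's output
on trial j blends two information sources:

* a *reactive* term — a lagged kernel over the recording's recent past,
  standing in for moment-to-moment auditory tracking of the sound; and
* an *internal-model* term — the recording's envelope itself, read out
  through a smooth random delay field, standing in for a learned
  representation of the rendition.

Over trials the reactive weight w_react(j) decays and the internal-model
weight w_int(j) = 1 - w_react(j) grows, while the alignment-delay scale
tau(j) shrinks: directed information flow from recording to performance
therefore falls across trials while zero-lag similarity rises, the
qualitative learning signature the analysis pipeline is built to detect.

Tunable magnitudes (coupling schedules, kernel length, noise scale) are
chosen to produce envelope-scale Granger-causality magnitudes and
correlations in a realistic range; they encode a qualitative pattern,
not any particular dataset's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .envelope import Envelope, write_envelope_csv

__all__ = [
    "Score",
    "SimConfig",
    "SyntheticStudy",
    "make_score",
    "render_recording_envelope",
    "simulate_performance_trial",
    "simulate_study",
    "render_score_audio",
]


@dataclass(frozen=True)
class Score:
    """A stylised folk-piece score: note events plus expressive curves.

    onsets/durations/amplitudes describe the nominal note events; the
    tempo-warp and dynamics curves (sampled on a coarse control grid)
    encode the expressive rendition — tempo shifts, caesuras, swells —
    that makes the recording's envelope non-trivial to predict.
    """

    onsets: np.ndarray        # s, sorted
    durations: np.ndarray     # s, > 0
    amplitudes: np.ndarray    # >= 0
    duration: float           # total piece length T, s
    warp_knots: np.ndarray    # smooth time-warp offsets at control points, s
    dynamics_knots: np.ndarray  # multiplicative dynamics curve at control points

    def __post_init__(self) -> None:
        if self.onsets.size == 0:
            raise ValueError("score has no note events")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be sorted")
        if np.any(self.durations <= 0) or np.any(self.amplitudes < 0):
            raise ValueError("durations must be > 0 and amplitudes >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters (defaults mirror the 8 x 8 design).

    w_react(j) falls linearly from ``w_react_start`` to ``w_react_end``
    across trials; w_int(j) = 1 - w_react(j); the delay scale tau(j)
    falls linearly from ``tau_start`` to ``tau_end`` (seconds).  The
    coupling kernel spans ``kernel_lags`` envelope points (0.75 s at the
    default 6), placing the true lag structure inside the 6-9 range that
    AIC order selection typically recovers for this kind of data.
    """

    participants: int = 8
    trials: int = 8
    duration: float = 90.0
    interval: float = 0.125
    w_react_start: float = 0.6
    w_react_end: float = 0.15
    tau_start: float = 0.25
    tau_end: float = 0.05
    kernel_lags: int = 6
    noise_scale: float = 0.05
    participant_sd: float = 0.15  # log-scale spread of per-participant factors
    clip_mode: str = "clip"       # "clip" (hard at 0) or "softplus"
    seed: int = 0

    def w_react(self, j: int) -> float:
        """Reactive-coupling weight on trial j (1-based), nonincreasing."""
        self._check_trial(j)
        if self.trials == 1:
            return self.w_react_start
        frac = (j - 1) / (self.trials - 1)
        return self.w_react_start + frac * (self.w_react_end - self.w_react_start)

    def w_int(self, j: int) -> float:
        """Internal-model weight on trial j, nondecreasing."""
        return 1.0 - self.w_react(j)

    def tau(self, j: int) -> float:
        """Alignment-delay scale (s) on trial j, nonincreasing."""
        self._check_trial(j)
        if self.trials == 1:
            return self.tau_start
        frac = (j - 1) / (self.trials - 1)
        return self.tau_start + frac * (self.tau_end - self.tau_start)

    def _check_trial(self, j: int) -> None:
        if not 1 <= j <= self.trials:
            raise ValueError(f"trial index {j} outside 1..{self.trials}")


@dataclass(frozen=True)
class SyntheticStudy:
    """One simulated piece: a fixed recording and P x J performances."""

    recording: Envelope
    performances: dict  # (participant, trial) -> Envelope
    config: SimConfig

    def pairs(self):
        """Yield (participant, trial, recording, performance) tuples."""
        for (p, j), perf in sorted(self.performances.items()):
            yield p, j, self.recording, perf


def make_score(duration: float = 90.0, seed: int = 0, tempo_bpm: float = 100.0) -> Score:
    """Draw a random stylised score: notes with varied rhythm, a smooth
    tempo warp, and a slow dynamics curve."""
    rng = np.random.default_rng(seed)
    beat = 60.0 / tempo_bpm
    onsets, durations, amplitudes = [], [], []
    t = 0.0
    while t < duration - beat:
        ioi = beat * rng.choice([0.5, 0.5, 1.0, 1.0, 1.0, 2.0])
        # occasional caesura / fermata-like stretch
        if rng.random() < 0.04:
            ioi *= rng.uniform(1.8, 3.0)
        onsets.append(t)
        durations.append(ioi * rng.uniform(0.75, 1.0))
        amplitudes.append(rng.uniform(0.4, 1.0))
        t += ioi
    n_knots = max(4, int(duration / 10.0))
    warp = np.cumsum(rng.normal(0.0, 0.15, size=n_knots))
    warp -= warp.mean()
    dynamics = 1.0 + 0.35 * np.sin(
        2.0 * np.pi * rng.uniform(0.5, 1.5) * np.linspace(0, 1, n_knots)
        + rng.uniform(0, 2 * np.pi)
    )
    return Score(
        onsets=np.asarray(onsets),
        durations=np.asarray(durations),
        amplitudes=np.asarray(amplitudes),
        duration=float(duration),
        warp_knots=warp,
        dynamics_knots=np.clip(dynamics, 0.2, None),
    )


def _score_envelope_fn(score: Score):
    """Continuous envelope function of time for a score (attack/decay
    note shapes, time-warped and dynamics-scaled)."""
    knot_times = np.linspace(0.0, score.duration, score.warp_knots.size)

    def fn(t: np.ndarray) -> np.ndarray:
        warped = t + np.interp(t, knot_times, score.warp_knots)
        dyn = np.interp(t, knot_times, score.dynamics_knots)
        out = np.zeros_like(t, dtype=float)
        attack = 0.06
        for onset, dur, amp in zip(score.onsets, score.durations, score.amplitudes):
            rel = warped - onset
            active = (rel >= 0) & (rel < dur + 0.2)
            if not np.any(active):
                continue
            r = rel[active]
            shape = np.where(
                r < attack, r / attack, np.exp(-(r - attack) / max(dur * 0.6, 0.05))
            )
            out[active] += amp * shape
        return out * dyn

    return fn


def render_recording_envelope(score: Score, seed: int = 0, interval: float = 0.125) -> Envelope:
    """Render a score to a nonnegative envelope on the analysis grid.

    A small amount of smooth multiplicative texture (bow noise, room)
    is added deterministically from the seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(score.duration / interval))
    t = np.arange(n) * interval
    values = _score_envelope_fn(score)(t)
    texture = gaussian_filter1d(rng.normal(0.0, 1.0, size=n), sigma=2.0)
    values = values * (1.0 + 0.1 * texture)
    return Envelope(values=np.clip(values, 0.0, None), interval=interval)


def _smooth_noise(rng: np.random.Generator, n: int, sigma_points: float) -> np.ndarray:
    """Unit-variance smooth Gaussian noise (Gaussian-kernel filtered)."""
    z = gaussian_filter1d(rng.normal(0.0, 1.0, size=n), sigma=sigma_points)
    sd = z.std()
    return z / sd if sd > 0 else z


def _coupling_kernel(k: int) -> np.ndarray:
    """Decaying positive kernel over lags 1..k, normalised to sum 1."""
    w = np.exp(-0.4 * np.arange(k))
    return w / w.sum()


def simulate_performance_trial(
    template: Envelope, j: int, cfg: SimConfig, seed: int
) -> Envelope:
    """Simulate one performer's envelope on trial j.

    P_t = w_int(j) * template(t - d_t) + w_react(j) * sum_k c_k R_{t-k}
          + noise, floored at zero; d_t is a smooth nonnegative delay
    field with scale tau(j) (the performer trails the recording).
    """
    rng = np.random.default_rng(seed)
    rec = template.values
    n = rec.size
    interval = template.interval
    t = np.arange(n) * interval

    delay = cfg.tau(j) * np.clip(1.0 + 0.5 * _smooth_noise(rng, n, sigma_points=16.0), 0.0, None)
    internal = np.interp(t - delay, t, rec)

    kernel = _coupling_kernel(cfg.kernel_lags)
    reactive = np.zeros(n)
    for k, c in enumerate(kernel, start=1):
        reactive[k:] += c * rec[:-k]

    noise = cfg.noise_scale * rec.std() * rng.normal(0.0, 1.0, size=n)
    raw = cfg.w_int(j) * internal + cfg.w_react(j) * reactive + noise
    if cfg.clip_mode == "softplus":
        sharp = 50.0
        values = np.log1p(np.exp(sharp * raw)) / sharp
    else:
        values = np.clip(raw, 0.0, None)
    return Envelope(values=values, interval=interval)


def simulate_study(cfg: SimConfig | None = None) -> SyntheticStudy:
    """Simulate a full piece: one fixed recording, P x J performances.

    Per-participant heterogeneity enters as seeded log-normal factors on
    the reactive weight, the delay scale, and the noise scale.
    """
    cfg = cfg or SimConfig()
    root = np.random.default_rng(cfg.seed)
    score = make_score(duration=cfg.duration, seed=int(root.integers(2**31)))
    recording = render_recording_envelope(
        score, seed=int(root.integers(2**31)), interval=cfg.interval
    )
    performances: dict = {}
    for p in range(1, cfg.participants + 1):
        factors = np.exp(root.normal(0.0, cfg.participant_sd, size=3))
        pcfg = replace(
            cfg,
            w_react_start=min(cfg.w_react_start * factors[0], 0.95),
            w_react_end=min(cfg.w_react_end * factors[0], 0.95),
            tau_start=cfg.tau_start * factors[1],
            tau_end=cfg.tau_end * factors[1],
            noise_scale=cfg.noise_scale * factors[2],
        )
        for j in range(1, cfg.trials + 1):
            trial_seed = int(root.integers(2**31))
            performances[(p, j)] = simulate_performance_trial(
                recording, j, pcfg, seed=trial_seed
            )
    return SyntheticStudy(recording=recording, performances=performances, config=cfg)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write a simulated study as envelope CSVs plus a manifest dict.

    The recording and each participant's concatenated performance track
    are written in the same CSV format the analysis pipeline reads; the
    returned manifest (serialisable to YAML) lists per-trial boundaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    rec_path = out_dir / "recording.csv"
    n_trial = len(study.recording)
    trial_s = n_trial * cfg.interval
    # the stimulus track repeats the fixed recording once per trial
    rec_track = Envelope(
        values=np.tile(study.recording.values, cfg.trials), interval=cfg.interval
    )
    write_envelope_csv(rec_track, rec_path)
    boundaries = [
        {"start_s": round(j * trial_s, 6), "end_s": round((j + 1) * trial_s, 6)}
        for j in range(cfg.trials)
    ]
    participants = []
    for p in range(1, cfg.participants + 1):
        perf_values = np.concatenate(
            [study.performances[(p, j)].values for j in range(1, cfg.trials + 1)]
        )
        perf_path = out_dir / f"performance_P{p:02d}.csv"
        write_envelope_csv(Envelope(values=perf_values, interval=cfg.interval), perf_path)
        participants.append(
            {
                "id": f"P{p:02d}",
                "recording": rec_path.name,
                "performance": perf_path.name,
                "trials": boundaries,
            }
        )
    return {
        "pieces": [{"id": "synthetic_piece", "participants": participants}],
        "options": {"seed": cfg.seed},
    }


def render_score_audio(
    score: Score, seed: int = 0, rate: int = 44100, max_duration: float | None = None
) -> np.ndarray:
    """Synthesize a score as mono audio samples in [-1, 1].

    Notes are rendered as sine tones (plus a weak second harmonic) under
    the same envelope function used for direct envelope rendering; used
    to integration-test the waveform-to-envelope pipeline.
    """
    rng = np.random.default_rng(seed)
    duration = min(score.duration, max_duration) if max_duration else score.duration
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    env = _score_envelope_fn(score)(t)
    # per-note pitches from a diatonic-ish set around A4
    freqs = rng.choice([220.0, 247.0, 262.0, 294.0, 330.0, 392.0, 440.0], size=score.onsets.size)
    phase = np.zeros(n)
    freq_of_t = np.full(n, freqs[0])
    for onset, f in zip(score.onsets, freqs):
        freq_of_t[t >= onset] = f
    phase = 2.0 * np.pi * np.cumsum(freq_of_t) / rate
    wave = env * (np.sin(phase) + 0.3 * np.sin(2.0 * phase))
    peak = np.abs(wave).max()
    if peak > 0:
        wave = 0.9 * wave / peak
    return wave
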