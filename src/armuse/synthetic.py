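"""Regime-switching synthetic wrist-IMU recordings with known ground truth.

The generator emulates the structure of a semi-structured activity session:
a subject alternates between **rest** (seated, arm still), **gait** (walking
with the arm swinging freely — nonfunctional movement) and **functional**
activity (reaching/manipulation pulses typical of household tasks).  State
dwell times are drawn from a log-normal with a configurable mean (20 s by
default, long relative to the 2000-sample / 10 s change-detector probe), and
each state imposes a distinct gravity baseline on the accelerometer —
posture is what a mean-difference detector actually senses — plus
state-specific dynamics:

* rest — low-variance white noise around the arm-down gravity vector;
* gait — ~1 Hz arm-swing sinusoid with a weaker second harmonic,
  gyroscope-dominant, plus moderate noise;
* functional — superposed bell-shaped (Gaussian-profile) velocity pulses
  with randomised amplitude, width and sign, plus broadband noise, giving
  the highest variance and entropy.

Per-subject idiosyncrasies (multiplicative channel gains, individual gait
cadence and amplitude) drive a realistic intra- vs inter-subject
generalisation gap.  Three simulated annotators code video frames (30 Hz) by
reading off the true state, then jitter every run boundary by ±2 frames and
flip 5% of frames to a random other code — the error scale that keeps the
merged Unknown fraction comfortably under a few percent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annotation import merge_annotators
from .io import AnnotatorSet, ImuSeries, SubjectDataset, align_annotations

STATES = ("rest", "gait", "functional")
FAABOS_BY_STATE = {"rest": 0, "gait": 1, "functional": 3}

# per-state channel models: gravity baseline (accel) in device units,
# noise sd per channel group (accel, gyro)
_STATE_BASELINE = {
    "rest": np.array([0.3, -0.2, 9.7, 0.0, 0.0, 0.0]),
    "gait": np.array([0.8, 1.4, 9.4, 0.0, 0.05, 0.0]),
    "functional": np.array([2.2, 3.1, 8.6, 0.05, 0.0, 0.05]),
}
_STATE_NOISE = {
    "rest": np.array([0.05] * 3 + [0.02] * 3),
    "gait": np.array([0.30] * 3 + [0.15] * 3),
    "functional": np.array([0.55] * 3 + [0.30] * 3),
}

_DEFAULT_TRANSITION = np.array([
    # rest   gait  functional
    [0.0, 0.5, 0.5],   # from rest
    [0.3, 0.0, 0.7],   # from gait
    [0.5, 0.5, 0.0],   # from functional
])


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one synthetic recording session."""

    sampling_rate_hz: float = 200.0
    duration_s: float = 600.0
    mean_dwell_s: float = 20.0
    dwell_cv: float = 0.35            # log-normal coefficient of variation
    min_dwell_s: float = 12.0         # keeps dwells above the 10 s probe
    transition: np.ndarray = dataclasses.field(
        default_factory=lambda: _DEFAULT_TRANSITION.copy())
    subject_gain_sd: float = 0.15     # sd of log per-subject channel gains
    frame_rate_hz: float = 30.0
    n_annotators: int = 3
    annotator_error_rate: float = 0.05
    annotator_boundary_jitter_frames: int = 2
    gesture_rate_hz: float = 0.0      # optional FAABOS-2 gesturing during rest

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (3, 3) or not np.allclose(
                self.transition.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if self.mean_dwell_s <= 0 or self.duration_s <= 0:
            raise ValueError("durations must be positive")


@dataclasses.dataclass
class SyntheticSubject:
    """A generated subject: signals, merged annotations, and the hidden truth."""

    dataset: SubjectDataset
    annotators: AnnotatorSet
    true_states: np.ndarray          # per-sample state index into STATES
    true_codes: np.ndarray           # per-sample behavioural code
    transitions: np.ndarray          # sample indices where the state changes

    @property
    def series(self) -> ImuSeries:
        return self.dataset.series

    @property
    def true_fu_percent(self) -> float:
        return float(100.0 * np.mean(
            self.true_states == STATES.index("functional")))


def _sample_dwell(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    cv = max(cfg.dwell_cv, 1e-6)
    sigma = np.sqrt(np.log(1 + cv ** 2))
    mu = np.log(cfg.mean_dwell_s) - sigma ** 2 / 2
    return max(cfg.min_dwell_s, float(rng.lognormal(mu, sigma)))


def _state_sequence(rng: np.random.Generator, cfg: GeneratorConfig,
                    n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Semi-Markov state path: explicit dwells + embedded transition matrix."""
    sr = cfg.sampling_rate_hz
    states = np.empty(n_samples, dtype=int)
    transitions = []
    state = int(rng.integers(len(STATES)))
    pos = 0
    while pos < n_samples:
        dwell = int(round(_sample_dwell(rng, cfg) * sr))
        end = min(n_samples, pos + max(1, dwell))
        states[pos:end] = state
        pos = end
        if pos < n_samples:
            transitions.append(pos)
            state = int(rng.choice(len(STATES), p=cfg.transition[state]))
    return states, np.asarray(transitions, dtype=int)


def _gait_waveform(rng: np.random.Generator, n: int, sr: float,
                   freq: float, amp: float) -> np.ndarray:
    """Arm-swing oscillation: fundamental + second harmonic, random phase."""
    t = np.arange(n) / sr
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.zeros((n, 6))
    fund = np.sin(2 * np.pi * freq * t + phase)
    harm = np.sin(2 * np.pi * 2 * freq * t + 2 * phase)
    wave[:, 4] = amp * (1.5 * fund + 0.35 * harm)          # gy dominates swing
    wave[:, 3] = amp * 0.5 * np.sin(2 * np.pi * freq * t + phase + 0.8)
    wave[:, 0] = amp * 0.8 * fund
    wave[:, 2] = amp * 0.3 * harm
    return wave


def _functional_pulses(rng: np.random.Generator, n: int, sr: float,
                       amp: float, rate_hz: float = 0.8) -> np.ndarray:
    """Superposed smooth bell-shaped movement pulses on all channels."""
    wave = np.zeros((n, 6))
    t = np.arange(n) / sr
    n_pulses = rng.poisson(rate_hz * n / sr)
    for _ in range(n_pulses):
        centre = rng.uniform(0, n / sr)
        width = rng.uniform(0.15, 0.5)
        bell = np.exp(-0.5 * ((t - centre) / width) ** 2)
        chans = rng.choice(6, size=rng.integers(2, 5), replace=False)
        for c in chans:
            a = amp * rng.uniform(0.5, 2.5) * rng.choice([-1.0, 1.0])
            wave[:, c] += a * bell
    return wave


def generate_signals(rng: np.random.Generator, cfg: GeneratorConfig,
                     states: np.ndarray, transitions: np.ndarray,
                     gains: np.ndarray, gait_freq: float,
                     amp_scale: float) -> np.ndarray:
    """Render the 6-channel signal for a given hidden state path."""
    n = len(states)
    sr = cfg.sampling_rate_hz
    data = np.zeros((n, 6))
    edges = np.concatenate([[0], transitions, [n]])
    for s, e in zip(edges[:-1], edges[1:]):
        name = STATES[states[s]]
        seg = np.tile(_STATE_BASELINE[name], (e - s, 1)).astype(float)
        seg += rng.normal(0, 1, (e - s, 6)) * _STATE_NOISE[name]
        if name == "gait":
            seg += _gait_waveform(rng, e - s, sr, gait_freq, amp_scale)
        elif name == "functional":
            seg += _functional_pulses(rng, e - s, sr, amp_scale)
        data[s:e] = seg
    return data * gains


def simulate_annotators(subject_codes: np.ndarray, cfg: GeneratorConfig,
                        rng: np.random.Generator) -> AnnotatorSet:
    """Simulate noisy frame-level annotators for a true per-sample code track.

    Each annotator sees the true code of every video frame, then (a) every
    boundary between code runs is independently jittered by up to
    ±``annotator_boundary_jitter_frames`` frames and (b) each frame is
    flipped to a uniformly random *other* code with probability
    ``annotator_error_rate``.
    """
    sr, fr = cfg.sampling_rate_hz, cfg.frame_rate_hz
    n_frames = int(len(subject_codes) * fr / sr)
    frame_samples = np.minimum((np.arange(n_frames) / fr * sr).astype(int),
                               len(subject_codes) - 1)
    truth = subject_codes[frame_samples]
    edges = np.flatnonzero(np.diff(truth)) + 1
    codes = np.array([-1, 0, 1, 2, 3])
    tracks = []
    j = cfg.annotator_boundary_jitter_frames
    for _ in range(cfg.n_annotators):
        if j > 0 and edges.size:
            jit = edges + rng.integers(-j, j + 1, size=edges.size)
            jit = np.clip(np.maximum.accumulate(jit), 1, n_frames - 1)
        else:
            jit = edges
        track = np.empty(n_frames, dtype=int)
        bounds = np.concatenate([[0], jit, [n_frames]])
        run_codes = truth[np.concatenate([[0], edges])]
        for (s, e), c in zip(zip(bounds[:-1], bounds[1:]), run_codes):
            track[s:e] = c
        flip = rng.random(n_frames) < cfg.annotator_error_rate
        for i in np.flatnonzero(flip):
            others = codes[codes != track[i]]
            track[i] = rng.choice(others)
        tracks.append(track)
    return AnnotatorSet(fr, np.vstack(tracks))


def generate_subject(cfg: GeneratorConfig, seed, subject_id: str = "S01",
                     group: str = "control") -> SyntheticSubject:
    """Generate one subject end to end: signals, annotators, merged dataset.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  The same
    seed reproduces the subject bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.sampling_rate_hz))
    states, transitions = _state_sequence(rng, cfg, n)
    gains = np.exp(rng.normal(0, cfg.subject_gain_sd, 6))
    gait_freq = float(rng.normal(0.9, 0.08))
    amp_scale = float(np.exp(rng.normal(0, 0.10)))
    data = generate_signals(rng, cfg, states, transitions, gains,
                            gait_freq, amp_scale)
    true_codes = np.array([FAABOS_BY_STATE[STATES[s]] for s in states])
    if cfg.gesture_rate_hz > 0:   # optional FAABOS-2 gesturing within rest
        rest = np.flatnonzero(true_codes == 0)
        n_gest = rng.poisson(cfg.gesture_rate_hz * len(rest) / cfg.sampling_rate_hz)
        for _ in range(n_gest):
            if rest.size:
                c = rng.choice(rest)
                w = int(rng.uniform(0.5, 1.5) * cfg.sampling_rate_hz)
                true_codes[c:c + w][true_codes[c:c + w] == 0] = 2
    series = ImuSeries(subject_id, data, cfg.sampling_rate_hz,
                       "affected" if group == "amputee" else "nondominant")
    ann = simulate_annotators(true_codes, cfg, rng)
    per_sample = align_annotations(ann, series, offset_s=0.0)
    merged = merge_annotators(per_sample)
    dataset = SubjectDataset(series, merged, group)
    return SyntheticSubject(dataset, ann, states, true_codes, transitions)


def generate_cohort(cfg: GeneratorConfig, n_subjects: int, seed,
                    group: str = "control") -> list[SyntheticSubject]:
    """Generate independent subjects with distinct per-subject idiosyncrasies."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        generate_subject(cfg, child, subject_id=f"S{i + 1:02d}", group=group)
        for i, child in enumerate(children)
    ]
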