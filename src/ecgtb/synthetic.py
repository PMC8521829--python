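"""Synthetic 10-s ECG segments for the four study rhythm classes.

Beat morphology is a sum of Gaussian bumps, one per ECG wave (P, Q, R, S, T),
the standard device of dynamical ECG simulators: smooth, differentiable, and
fully parameterized by (amplitude, offset from the R peak, width).  Rhythm is
generated at the level of beat onset times:

* ``Norm`` — i.i.d. Normal(mean_rr, rr_sd) RR intervals, truncated below at
  0.4 s.
* ``AF``   — i.i.d. Uniform(0.35, 1.1) s RR intervals, P waves suppressed,
  plus a fibrillatory oscillation (three random-phase sinusoids with
  frequencies drawn in the fibrillatory band, 0.05 mV each).
* ``PVC``  — with probability ``ectopic_rate`` a sinus beat is replaced by a
  wide ventricular ectopic (QRS widths tripled, R amplitude x1.3, inverted T,
  no P) coupled at ``coupling_fraction x mean_rr`` after the previous beat,
  followed by a compensatory pause that restores the sinus grid.
* ``APB``  — with probability ``ectopic_rate`` a premature narrow beat is
  inserted ``coupling_fraction x mean_rr`` after a sinus beat, followed by a
  non-compensatory pause (the rhythm resets from the ectopic).

Noise (baseline wander, powerline, white) is added last.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import CLASS_LABELS, EcgSegment

__all__ = [
    "Wave",
    "BeatTemplate",
    "RhythmSpec",
    "NoiseSpec",
    "DEFAULT_TEMPLATE",
    "DEFAULT_RHYTHMS",
    "DEFAULT_NOISE",
    "TABLE1_COUNTS",
    "generate_segment",
    "generate_dataset",
    "lognormal_feature_dataset",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump of a beat template."""

    wave_id: str  # P, Q, R, S or T
    amplitude: float  # mV
    center_offset: float  # s, relative to the R peak
    width: float  # s, Gaussian sigma


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians morphology of a single heartbeat."""

    waves: tuple[Wave, ...]

    def __post_init__(self) -> None:
        if any(w.width <= 0 for w in self.waves):
            raise ValueError("wave widths must be strictly positive")
        if sum(1 for w in self.waves if w.wave_id == "R") != 1:
            raise ValueError("template must contain exactly one R wave")


#: Default morphology, amplitudes in mV, times in seconds.
DEFAULT_TEMPLATE = BeatTemplate(
    waves=(
        Wave("P", 0.15, -0.20, 0.025),
        Wave("Q", -0.10, -0.030, 0.010),
        Wave("R", 1.20, 0.0, 0.012),
        Wave("S", -0.25, 0.030, 0.010),
        Wave("T", 0.35, 0.25, 0.060),
    )
)


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-level description of one study class."""

    class_label: str
    mean_rr: float = 0.8  # s
    rr_sd: float = 0.05  # s (normal-rhythm classes)
    rr_distribution: str = "normal"  # "normal" or "uniform" (AF)
    ectopic_rate: float = 0.0  # per-beat probability (PVC/APB)
    coupling_fraction: float = 0.6  # premature-beat position / mean_rr
    fibrillatory_band: tuple[float, float] = (4.0, 9.0)  # Hz (AF)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be non-negative")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ValueError("ectopic_rate must lie in [0, 1]")
        if not 0.0 < self.coupling_fraction < 1.0:
            raise ValueError("coupling_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline wander + powerline + white noise."""

    baseline_wander: tuple[float, float] = (0.3, 0.10)  # (Hz, mV)
    powerline: tuple[float, float] = (60.0, 0.05)  # (Hz, mV)
    white_sd: float = 0.02  # mV

    def __post_init__(self) -> None:
        if self.baseline_wander[1] < 0 or self.powerline[1] < 0 or self.white_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.baseline_wander[0] >= 0.5:
            raise ValueError("baseline wander frequency must be below 0.5 Hz")


#: Study-condition rhythm parameters for each class.
DEFAULT_RHYTHMS: dict[str, RhythmSpec] = {
    "Norm": RhythmSpec("Norm", mean_rr=0.8, rr_sd=0.05),
    "AF": RhythmSpec("AF", rr_distribution="uniform"),
    "PVC": RhythmSpec("PVC", mean_rr=0.8, rr_sd=0.05, ectopic_rate=0.25),
    "APB": RhythmSpec("APB", mean_rr=0.8, rr_sd=0.05, ectopic_rate=0.20),
}

DEFAULT_NOISE = NoiseSpec()

#: Class structure of the study's segment inventory (Norm/AF/PVC/APB).
TABLE1_COUNTS: dict[str, int] = {"Norm": 283, "AF": 135, "PVC": 133, "APB": 66}

# AF RR interval bounds (s); CV of Uniform(0.35, 1.1) is ~0.30.
_AF_RR_LOW, _AF_RR_HIGH = 0.35, 1.1
_RR_FLOOR = 0.4  # s, truncation of normal-rhythm RR draws
_FIB_AMPLITUDE = 0.05  # mV per fibrillatory sinusoid
_N_FIB_SINUSOIDS = 3


def _beat_schedule(
    rhythm: RhythmSpec, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Beat onset times and kinds ('normal' | 'pvc' | 'apb').

    The random-draw pattern for the normal-rhythm classes is identical
    regardless of ectopic_rate, so a PVC/APB spec with zero ectopy produces
    exactly the Norm schedule under the same seed.
    """
    times: list[float] = []
    kinds: list[str] = []
    t = 0.4  # first beat shortly after segment start
    times.append(t)
    kinds.append("normal")
    label = rhythm.class_label
    while t <= duration:
        if rhythm.rr_distribution == "uniform":
            t += rng.uniform(_AF_RR_LOW, _AF_RR_HIGH)
            times.append(t)
            kinds.append("normal")
            continue
        rr = max(_RR_FLOOR, rng.normal(rhythm.mean_rr, rhythm.rr_sd))
        u = rng.random()
        if label == "PVC" and u < rhythm.ectopic_rate:
            # ectopic replaces the next sinus beat; compensatory pause
            times.append(t + rhythm.coupling_fraction * rhythm.mean_rr)
            kinds.append("pvc")
            t = t + 2.0 * rhythm.mean_rr
            times.append(t)
            kinds.append("normal")
        elif label == "APB" and u < rhythm.ectopic_rate:
            # premature beat inserted; non-compensatory pause (grid resets)
            t_apb = t + rhythm.coupling_fraction * rhythm.mean_rr
            times.append(t_apb)
            kinds.append("apb")
            t = t_apb + rhythm.mean_rr
            times.append(t)
            kinds.append("normal")
        else:
            t += rr
            times.append(t)
            kinds.append("normal")
    return np.asarray(times), kinds


def _render_beat(
    t_grid: np.ndarray,
    beat_time: float,
    kind: str,
    template: BeatTemplate,
    suppress_p: bool,
) -> np.ndarray:
    out = np.zeros_like(t_grid)
    for w in template.waves:
        amp, center, width = w.amplitude, w.center_offset, w.width
        if kind == "pvc":
            if w.wave_id == "P":
                continue  # ventricular ectopics carry no P wave
            if w.wave_id in ("Q", "R", "S"):
                width *= 3.0
                if w.wave_id == "R":
                    amp *= 1.3
            elif w.wave_id == "T":
                amp = -amp
        elif suppress_p and w.wave_id == "P":
            continue
        out += amp * np.exp(-((t_grid - beat_time - center) ** 2) / (2.0 * width**2))
    return out


def generate_segment(
    rhythm: RhythmSpec,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    noise: NoiseSpec = DEFAULT_NOISE,
    fs: float = 360.0,
    duration: float = 10.0,
    seed: int = 0,
) -> EcgSegment:
    """Generate one labeled synthetic ECG segment.

    Returns an :class:`EcgSegment` whose ``meta`` carries the generated beat
    times, the per-beat kinds, and the ectopic count, so rhythm statistics can
    be asserted without peak detection.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if duration < 2.0 * rhythm.mean_rr:
        raise ValueError("duration must cover at least two mean RR intervals")
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    t_grid = np.arange(n) / fs

    beat_times, beat_kinds = _beat_schedule(rhythm, duration, rng)
    is_af = rhythm.class_label == "AF"
    signal = np.zeros(n)
    for bt, kind in zip(beat_times, beat_kinds):
        if -0.5 <= bt <= duration + 0.5:
            signal += _render_beat(t_grid, bt, kind, template, suppress_p=is_af)

    if is_af:
        lo, hi = rhythm.fibrillatory_band
        freqs = rng.uniform(lo, hi, _N_FIB_SINUSOIDS)
        phases = rng.uniform(0.0, 2.0 * np.pi, _N_FIB_SINUSOIDS)
        for f, ph in zip(freqs, phases):
            signal += _FIB_AMPLITUDE * np.sin(2.0 * np.pi * f * t_grid + ph)

    bw_f, bw_a = noise.baseline_wander
    pl_f, pl_a = noise.powerline
    if pl_a > 0 and not 30.0 < pl_f < fs / 2.0:
        raise ValueError("powerline frequency must lie in (30, fs/2)")
    signal += bw_a * np.sin(2.0 * np.pi * bw_f * t_grid + rng.uniform(0, 2 * np.pi))
    signal += pl_a * np.sin(2.0 * np.pi * pl_f * t_grid + rng.uniform(0, 2 * np.pi))
    if noise.white_sd > 0:
        signal += rng.normal(0.0, noise.white_sd, n)

    return EcgSegment(
        samples=signal,
        fs=fs,
        label=rhythm.class_label,
        source="synthetic",
        record_id=f"syn-{rhythm.class_label}-{seed}",
        start_sample=0,
        filtered=False,
        meta={
            "beat_times": beat_times,
            "beat_kinds": beat_kinds,
            "n_ectopic": sum(k != "normal" for k in beat_kinds),
            "seed": seed,
        },
    )


def segment_seed(master_seed: int, label: str, index: int) -> int:
    """Counter-based per-segment seed: hash of (master seed, class, index)."""
    class_code = CLASS_LABELS.index(label)
    ss = np.random.SeedSequence([int(master_seed), class_code, int(index)])
    return int(ss.generate_state(1)[0])


def generate_dataset(
    class_counts: dict[str, int],
    fs: float = 360.0,
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
    rhythms: dict[str, RhythmSpec] | None = None,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    duration: float = 10.0,
) -> list[EcgSegment]:
    """Generate a labeled dataset with exactly the requested per-class counts.

    Per-segment seeds are derived deterministically from (seed, class, index),
    so the output is independent of generation order.
    """
    rhythms = dict(DEFAULT_RHYTHMS if rhythms is None else rhythms)
    segments: list[EcgSegment] = []
    for label in CLASS_LABELS:
        count = int(class_counts.get(label, 0))
        if count < 0:
            raise ValueError("class counts must be non-negative")
        for index in range(count):
            seg = generate_segment(
                rhythms[label],
                template=template,
                noise=noise,
                fs=fs,
                duration=duration,
                seed=segment_seed(seed, label, index),
            )
            seg.record_id = f"syn-{label}-{index:04d}"
            segments.append(seg)
    return segments


@dataclass(frozen=True)
class LogNormalFeatureSpec:
    """Class-conditional log-normal model of a scalar feature (e.g. skewness).

    The positive (abnormal) class forms a dense cluster at small values
    (median exp(-3.0) ~ 0.05) while the negative (Norm) class is diffuse with
    a separated, larger log-mean.  The reciprocal's strong curvature at small
    arguments expands the dense cluster region relative to the diffuse class
    above it — the geometry under which an unstandardized distance-based
    classifier could profit from the transform.  (In practice an exact
    nearest-neighbour rule in one dimension is almost invariant under smooth
    monotone maps, so the measurable effect is small; see the methods note.)
    """

    log_mean_neg: float = -1.0  # Norm: diffuse, median exp(-1.0) ~ 0.37
    log_sd_neg: float = 1.0
    log_mean_pos: float = -3.0  # abnormal: dense cluster, median ~ 0.05
    log_sd_pos: float = 0.4
    n_neg: int = 283
    n_pos: int = 135


def lognormal_feature_dataset(
    seed: int, spec: LogNormalFeatureSpec = LogNormalFeatureSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (values, labels) for the designed directional-reproduction study.

    labels are 0 (negative / Norm-like) and 1 (positive / abnormal).
    """
    rng = np.random.default_rng(seed)
    neg = rng.lognormal(spec.log_mean_neg, spec.log_sd_neg, spec.n_neg)
    pos = rng.lognormal(spec.log_mean_pos, spec.log_sd_pos, spec.n_pos)
    values = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(spec.n_neg, int), np.ones(spec.n_pos, int)])
    return values, labels
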