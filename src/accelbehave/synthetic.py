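"""Seeded synthetic tri-axial accelerometer traces for quadruped behaviours.

The generator emulates collar-mounted 40 Hz accelerometer recordings of a
quadruped ethogram (rest, walk, trot, run, collar shake, feed, groom).  Each
behaviour is a :class:`BehaviourRegime`: a static gravity vector set by the
animal's posture plus a dynamic component — a fundamental stride sinusoid and
one harmonic, amplitude-modulated per second, with optional per-second
frequency resampling for aperiodic behaviours (grooming, feeding) — plus white
sensor noise.  Units are g throughout (1 g = 9.81 m/s^2), so a resting tag
reads a unit static vector.

Axis convention: ``ax`` = sway (lateral), ``ay`` = heave (vertical),
``az`` = surge (sagittal).  A level posture therefore has static (0, 1, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BEHAVIOURS: tuple[str, ...] = ("rest", "walk", "trot", "run", "shake", "feed", "groom")

#: relative share of the dynamic amplitude on (sway, heave, surge)
_AXIS_MIX = (0.35, 1.0, 0.6)
_AXIS_PHASE = (2.2, 0.0, 1.3)
_HARMONIC_FRACTION = 0.4


@dataclass(frozen=True)
class BehaviourRegime:
    """Signal model for one behaviour.

    Parameters
    ----------
    stride_freq_hz
        Dominant oscillation frequency; 0 for aperiodic/stationary signals.
    dyn_amplitude_g
        Peak dynamic acceleration of the heave axis; sway and surge receive
        fixed fractions of it.
    posture_pitch_deg, posture_roll_deg
        Mean static orientation of the tag.
    amplitude_cv
        Coefficient of variation of the per-second amplitude modulation;
        high values (groom, feed) make the signal visibly aperiodic.
    noise_sd_g
        White sensor-noise standard deviation, per axis.
    freq_cv
        Per-second CV of the stride frequency (0 = strictly periodic).
    roll_drift_deg
        Amplitude of a slow sinusoidal roll wander (posture drift while
        grooming).
    bout_amp_cv
        CV of a per-bout amplitude multiplier: different bouts of the same
        behaviour differ in vigour, which makes neighbouring gaits overlap.
    """

    name: str
    stride_freq_hz: float
    dyn_amplitude_g: float
    posture_pitch_deg: float = 0.0
    posture_roll_deg: float = 0.0
    amplitude_cv: float = 0.2
    noise_sd_g: float = 0.02
    freq_cv: float = 0.0
    roll_drift_deg: float = 0.0
    bout_amp_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.stride_freq_hz < 0:
            raise ValueError("stride_freq_hz must be >= 0")
        if self.dyn_amplitude_g < 0:
            raise ValueError("dyn_amplitude_g must be >= 0")
        if self.noise_sd_g <= 0:
            raise ValueError("noise_sd_g must be > 0")


#: The gait trio (walk/trot/run) shares a bout-level amplitude spread wide
#: enough that neighbouring gaits genuinely overlap; groom is level-postured
#: with a wandering roll and an amplitude inside walk's range, identifiable
#: mainly by its aperiodicity; feed is marked by a head-down pitch.
DEFAULT_REGIMES: dict[str, BehaviourRegime] = {
    "rest": BehaviourRegime("rest", 0.0, 0.02, amplitude_cv=0.1, noise_sd_g=0.01,
                            bout_amp_cv=0.1),
    "walk": BehaviourRegime("walk", 1.8, 0.28, amplitude_cv=0.45,
                            noise_sd_g=0.03, bout_amp_cv=0.4),
    "trot": BehaviourRegime("trot", 2.6, 0.42, amplitude_cv=0.45,
                            noise_sd_g=0.03, bout_amp_cv=0.4),
    "run": BehaviourRegime("run", 3.5, 0.65, amplitude_cv=0.45, noise_sd_g=0.03,
                           bout_amp_cv=0.4),
    "shake": BehaviourRegime("shake", 10.0, 0.8, amplitude_cv=0.3, noise_sd_g=0.03,
                             bout_amp_cv=0.35),
    "feed": BehaviourRegime("feed", 1.0, 0.12, posture_pitch_deg=-40.0,
                            amplitude_cv=0.6, freq_cv=0.5, bout_amp_cv=0.3),
    "groom": BehaviourRegime("groom", 1.3, 0.24, posture_pitch_deg=0.0,
                             posture_roll_deg=15.0, amplitude_cv=0.8, freq_cv=0.6,
                             roll_drift_deg=25.0, bout_amp_cv=0.3),
}

#: default total calibration seconds per behaviour, pooled over individuals —
#: rest dominant, durations deliberately inconsistent (the confusable trot is
#: scarce next to walk and run), groom and shake under the 60 s cap
DEFAULT_CALIBRATION_S: dict[str, float] = {
    "rest": 420.0, "walk": 240.0, "trot": 60.0, "run": 150.0,
    "shake": 30.0, "feed": 80.0, "groom": 40.0,
}

#: free-ranging activity budget: 22.1 h/day rest, then walk 55.4, groom 39.5,
#: run 6.6, trot 5.0, shake 3.5 and feed 2.7 min/day, normalised to 1
_MIN_PER_DAY = {"rest": 1326.0, "walk": 55.4, "groom": 39.5, "run": 6.6,
                "trot": 5.0, "shake": 3.5, "feed": 2.7}
DEFAULT_BUDGET: dict[str, float] = {
    b: m / sum(_MIN_PER_DAY.values()) for b, m in _MIN_PER_DAY.items()
}

DEFAULT_MEAN_BOUT_S: dict[str, float] = {
    "rest": 600.0, "walk": 30.0, "groom": 60.0, "run": 10.0,
    "trot": 8.0, "shake": 4.0, "feed": 45.0,
}

MIN_BOUT_S = 2.0


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration, in g."""

    sample_rate_hz: float
    t: np.ndarray
    ax: np.ndarray  # sway
    ay: np.ndarray  # heave
    az: np.ndarray  # surge

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        n = len(self.t)
        if any(len(a) != n for a in (self.ax, self.ay, self.az)):
            raise ValueError("axis arrays must share the time base")
        for a in (self.t, self.ax, self.ay, self.az):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite values in trace")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sample_rate_hz,
                                                  rtol=0, atol=1e-9):
                raise ValueError("t must be uniformly spaced at 1/sample_rate_hz")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "ax_g": self.ax,
                             "ay_g": self.ay, "az_g": self.az})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, sample_rate_hz: float = 40.0) -> "AccelTrace":
        df = pd.read_csv(path)
        return cls(sample_rate_hz, df["time_s"].to_numpy(),
                   df["ax_g"].to_numpy(), df["ay_g"].to_numpy(),
                   df["az_g"].to_numpy())


@dataclass(frozen=True)
class LabelledSegment:
    """A behaviour bout: one label over a half-open time interval."""

    individual_id: str
    behaviour: str
    start_s: float
    end_s: float
    source: str = "truth"  # truth | rule_tree | rf_model

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def segments_to_frame(segments: list[LabelledSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual_id, s.behaviour, s.start_s, s.end_s, s.source) for s in segments],
        columns=["individual_id", "behaviour", "start_s", "end_s", "source"])


def segments_to_csv(segments: list[LabelledSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, index=False, float_format="%.6f")


def segments_from_csv(path) -> list[LabelledSegment]:
    df = pd.read_csv(path)
    return [LabelledSegment(r.individual_id, r.behaviour, r.start_s, r.end_s, r.source)
            for r in df.itertuples()]


@dataclass
class DeploymentConfig:
    """Free-ranging deployment: length, stationary budget, bout-length means."""

    duration_days: float = 2.74
    budget: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BUDGET))
    mean_bout_s: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEAN_BOUT_S))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        total = sum(self.budget.values())
        if total <= 0:
            raise ValueError("budget must have positive total mass")
        for b, p in self.budget.items():
            if p < 0:
                raise ValueError(f"negative budget fraction for {b!r}")
            if p == 0 and b in self.mean_bout_s:
                raise ValueError(
                    f"behaviour {b!r} has zero budget but a requested bout mean")
        self.budget = {b: p / total for b, p in self.budget.items() if p > 0}
        for b in self.budget:
            m = self.mean_bout_s.get(b, None)
            if m is None:
                raise ValueError(f"no mean bout duration for {b!r}")
            if m < MIN_BOUT_S:
                raise ValueError(f"mean_bout_s[{b!r}] must be >= {MIN_BOUT_S}")


# ---------------------------------------------------------------------------
# single-bout signal synthesis


def _static_vector(pitch_deg: np.ndarray | float, roll_deg: np.ndarray | float):
    """Unit gravity vector for a given attitude (sway, heave, surge)."""
    p = np.deg2rad(pitch_deg)
    r = np.deg2rad(roll_deg)
    return np.sin(r) * np.cos(p), np.cos(r) * np.cos(p), np.sin(p)


def _per_second_multipliers(rng: np.random.Generator, n_seconds: int, cv: float):
    """Log-normal multipliers with mean 1 and the requested CV."""
    if cv <= 0:
        return np.ones(n_seconds)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n_seconds)


def generate_bout(regime: BehaviourRegime, duration_s: float,
                  sample_rate_hz: float = 40.0, seed: int | np.random.Generator = 0,
                  start_s: float = 0.0) -> AccelTrace:
    """Synthesise one behaviour bout.

    The trace is gravity rotated by the regime's posture, plus a dynamic
    component (fundamental at ``stride_freq_hz`` + one harmonic at twice the
    frequency, amplitude-modulated per second with CV ``amplitude_cv``), plus
    white noise.  Deterministic for a fixed seed.
    """
    if duration_s < MIN_BOUT_S:
        raise ValueError(f"bout duration must be >= {MIN_BOUT_S} s")
    if regime.stride_freq_hz >= sample_rate_hz / 2.0:
        raise ValueError("stride_freq_hz must be below the Nyquist frequency")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = round(duration_s * sample_rate_hz)
    t = start_s + np.arange(n) / sample_rate_hz
    sec = np.minimum((np.arange(n) / sample_rate_hz).astype(int), max(0, n - 1))
    n_seconds = int(sec.max()) + 1 if n else 0

    bout_amp = float(_per_second_multipliers(rng, 1, regime.bout_amp_cv)[0])
    amp_per_s = _per_second_multipliers(rng, n_seconds, regime.amplitude_cv)
    amp = regime.dyn_amplitude_g * bout_amp * amp_per_s[sec]

    # posture (with optional slow roll wander)
    if regime.roll_drift_deg > 0:
        period = rng.uniform(4.0, 10.0)
        phase = rng.uniform(0, 2 * np.pi)
        roll = regime.posture_roll_deg + regime.roll_drift_deg * np.sin(
            2 * np.pi * (t - start_s) / period + phase)
    else:
        roll = regime.posture_roll_deg
    stx, sty, stz = _static_vector(regime.posture_pitch_deg, roll)
    static = np.empty((n, 3))
    static[:, 0], static[:, 1], static[:, 2] = stx, sty, stz

    if regime.stride_freq_hz > 0:
        freq_per_s = regime.stride_freq_hz * _per_second_multipliers(
            rng, n_seconds, regime.freq_cv)
        freq_per_s = np.clip(freq_per_s, 0.05, 0.95 * sample_rate_hz / 2.0)
        inst_freq = freq_per_s[sec]
        phase0 = rng.uniform(0, 2 * np.pi)
        phi = phase0 + 2 * np.pi * np.cumsum(inst_freq) / sample_rate_hz
        dyn = np.empty((n, 3))
        for k, (mix, ax_phase) in enumerate(zip(_AXIS_MIX, _AXIS_PHASE)):
            dyn[:, k] = mix * amp * (np.sin(phi + ax_phase)
                                     + _HARMONIC_FRACTION * np.sin(2 * phi + ax_phase))
    else:
        # stationary/aperiodic: small amplitude-scaled jitter instead of a gait
        dyn = amp[:, None] * np.array(_AXIS_MIX) * rng.standard_normal((n, 3))

    noise = regime.noise_sd_g * rng.standard_normal((n, 3))
    acc = static + dyn + noise
    return AccelTrace(sample_rate_hz, t, acc[:, 0], acc[:, 1], acc[:, 2])


# ---------------------------------------------------------------------------
# calibration set


def _split_into_bouts(total_samples: int, sample_rate_hz: float,
                      rng: np.random.Generator) -> list[int]:
    """Split a sample budget into bout sample-counts, each >= 2 s.

    Bout lengths are uniform on 4-13 s so the default calibration set holds
    on the order of 110 discrete bouts — the bout count of a realistic
    calibration campaign, at desk scale.
    """
    min_n = round(MIN_BOUT_S * sample_rate_hz)
    out: list[int] = []
    remaining = total_samples
    while remaining > 0:
        n = min(remaining, round(rng.uniform(4.0, 13.0) * sample_rate_hz))
        if remaining - n < min_n:  # avoid a trailing sliver shorter than 2 s
            n = remaining
        out.append(n)
        remaining -= n
    return out


def generate_calibration_set(
    n_individuals: int = 9,
    per_behaviour_s: dict[str, float] | None = None,
    seed: int = 0,
    sample_rate_hz: float = 40.0,
    regimes: dict[str, BehaviourRegime] | None = None,
) -> tuple[list[AccelTrace], list[LabelledSegment]]:
    """Generate labelled calibration bouts for ``n_individuals`` animals.

    ``per_behaviour_s`` gives the total labelled seconds of each behaviour
    pooled over individuals; it is divided evenly (to the sample) across
    individuals and split into bouts of a few seconds to tens of seconds.
    Every individual expresses every behaviour provided its share is >= 2 s.
    Individuals differ by a small log-normal amplitude multiplier.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if per_behaviour_s is None:
        per_behaviour_s = DEFAULT_CALIBRATION_S
    per_behaviour_s = dict(per_behaviour_s)
    if not per_behaviour_s:
        raise ValueError("at least one behaviour must be requested")
    regimes = regimes or DEFAULT_REGIMES
    for b, dur in per_behaviour_s.items():
        if b not in regimes:
            raise ValueError(f"no regime for behaviour {b!r}")
        if dur < MIN_BOUT_S:
            raise ValueError(f"per_behaviour_s[{b!r}] must be >= {MIN_BOUT_S}")

    root = np.random.default_rng(seed)
    indiv_rngs = root.spawn(n_individuals)
    indiv_amp = _per_second_multipliers(root, n_individuals, 0.1)

    min_n = round(MIN_BOUT_S * sample_rate_hz)
    # per-behaviour sample budgets per individual (even split, remainder first)
    shares: dict[str, np.ndarray] = {}
    for b, dur in per_behaviour_s.items():
        total_n = round(dur * sample_rate_hz)
        base, extra = divmod(total_n, n_individuals)
        share = np.full(n_individuals, base, dtype=int)
        share[:extra] += 1
        if base < min_n:  # too little for everyone: give 2 s bouts to as many as fit
            k = total_n // min_n
            share[:] = 0
            share[:k] = min_n
            share[0] += total_n - k * min_n
        shares[b] = share

    traces: list[AccelTrace] = []
    segments: list[LabelledSegment] = []
    for i in range(n_individuals):
        rng = indiv_rngs[i]
        iid = f"cat{i + 1:02d}"
        bouts: list[tuple[str, int]] = []
        for b in per_behaviour_s:
            for bn in _split_into_bouts(int(shares[b][i]), sample_rate_hz, rng):
                bouts.append((b, bn))
        rng.shuffle(bouts)

        parts, cursor = [], 0
        for b, bn in bouts:
            regime = regimes[b]
            regime_i = replace(regime, dyn_amplitude_g=regime.dyn_amplitude_g
                               * float(indiv_amp[i]))
            start = cursor / sample_rate_hz
            parts.append(generate_bout(regime_i, bn / sample_rate_hz,
                                       sample_rate_hz, rng, start_s=start))
            segments.append(LabelledSegment(iid, b, start,
                                            (cursor + bn) / sample_rate_hz))
            cursor += bn
        traces.append(AccelTrace(
            sample_rate_hz,
            np.concatenate([p.t for p in parts]),
            np.concatenate([p.ax for p in parts]),
            np.concatenate([p.ay for p in parts]),
            np.concatenate([p.az for p in parts])))
    return traces, segments


# ---------------------------------------------------------------------------
# free-ranging deployments


def build_transition_kernel(budget: dict[str, float],
                            mean_bout_s: dict[str, float],
                            tol: float = 1e-13, max_iter: int = 100_000,
                            ) -> tuple[list[str], np.ndarray]:
    """Embedded behaviour-to-behaviour transition kernel (no self loops).

    The semi-Markov bout process occupies behaviour ``b`` a fraction
    ``budget[b]`` of time when the embedded chain's stationary distribution is
    proportional to ``budget[b] / mean_bout_s[b]``.  A zero-diagonal kernel
    with that stationary law exists iff no single weight exceeds 1/2; it is
    built by Sinkhorn-balancing the outer-product flow matrix with its
    diagonal removed.
    """
    names = list(budget)
    if len(names) == 1:
        return names, np.array([[1.0]])
    w = np.array([budget[b] / mean_bout_s[b] for b in names])
    nu = w / w.sum()
    if nu.max() > 0.5 + 1e-12:
        raise ValueError(
            "no self-loop-free kernel exists: one behaviour's entry weight "
            "(budget/mean_bout) exceeds half the total; shorten its mean bout")
    F = np.outer(nu, nu)
    np.fill_diagonal(F, 0.0)
    for _ in range(max_iter):
        F *= (nu / F.sum(axis=1))[:, None]
        F *= nu / F.sum(axis=0)
        if (np.abs(F.sum(axis=1) - nu).max() < tol
                and np.abs(F.sum(axis=0) - nu).max() < tol):
            break
    else:
        raise ValueError("kernel balancing did not converge")
    P = F / F.sum(axis=1, keepdims=True)
    return names, P


def simulate_behaviour_sequence(cfg: DeploymentConfig,
                                rng: np.random.Generator | None = None,
                                ) -> list[tuple[str, float]]:
    """Draw a bout sequence (behaviour, duration_s) covering the deployment.

    Bout durations are ``2 + Exp(mean - 2)`` seconds (exponential truncated at
    the 2 s minimum, keeping the stated mean exact); the final bout is cut at
    the deployment end.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    names, P = build_transition_kernel(cfg.budget, cfg.mean_bout_s)
    total_s = cfg.duration_days * 86_400.0
    probs = np.array([cfg.budget[b] for b in names])
    state = int(rng.choice(len(names), p=probs))
    out: list[tuple[str, float]] = []
    elapsed = 0.0
    while elapsed < total_s:
        m = cfg.mean_bout_s[names[state]]
        dur = MIN_BOUT_S + (rng.exponential(m - MIN_BOUT_S) if m > MIN_BOUT_S else 0.0)
        dur = min(dur, total_s - elapsed)
        if out and out[-1][0] == names[state]:  # only possible with one behaviour
            out[-1] = (names[state], out[-1][1] + dur)
        else:
            out.append((names[state], dur))
        elapsed += dur
        if len(names) > 1:
            state = int(rng.choice(len(names), p=P[state]))
    return out


def generate_deployment(cfg: DeploymentConfig, sample_rate_hz: float = 40.0,
                        regimes: dict[str, BehaviourRegime] | None = None,
                        individual_id: str = "cat01",
                        ) -> tuple[AccelTrace, list[LabelledSegment]]:
    """Simulate a free-ranging deployment: bout sequence plus its trace."""
    regimes = regimes or DEFAULT_REGIMES
    for b in cfg.budget:
        if b not in regimes:
            raise ValueError(f"no regime for behaviour {b!r}")
    rng = np.random.default_rng(cfg.seed)
    bouts = simulate_behaviour_sequence(cfg, rng)

    # snap bout boundaries to the sample grid so segments tile the trace
    segments: list[LabelledSegment] = []
    parts: list[AccelTrace] = []
    cursor = 0
    total_n = round(cfg.duration_days * 86_400.0 * sample_rate_hz)
    for b, dur in bouts:
        bn = min(round(dur * sample_rate_hz), total_n - cursor)
        if bn <= 0:
            continue
        start = cursor / sample_rate_hz
        # very short snapped bouts still get a signal; generate_bout requires
        # >= 2 s, so pad the synthesis and cut
        synth_n = max(bn, round(MIN_BOUT_S * sample_rate_hz))
        part = generate_bout(regimes[b], synth_n / sample_rate_hz, sample_rate_hz,
                             rng, start_s=start)
        if synth_n != bn:
            part = AccelTrace(sample_rate_hz, part.t[:bn], part.ax[:bn],
                              part.ay[:bn], part.az[:bn])
        parts.append(part)
        segments.append(LabelledSegment(individual_id, b, start,
                                        (cursor + bn) / sample_rate_hz))
        cursor += bn
    trace = AccelTrace(
        sample_rate_hz,
        np.concatenate([p.t for p in parts]),
        np.concatenate([p.ax for p in parts]),
        np.concatenate([p.ay for p in parts]),
        np.concatenate([p.az for p in parts]))
    return trace, segments


def labels_per_sample(segments: list[LabelledSegment], t: np.ndarray) -> np.ndarray:
    """Behaviour label of each sample time (segments assumed to tile t)."""
    out = np.empty(len(t), dtype=object)
    for s in segments:
        mask = (t >= s.start_s - 1e-9) & (t < s.end_s - 1e-9)
        out[mask] = s.behaviour
    return out
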