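"""Per-sample movement variables derived from raw tri-axial acceleration.

The *base* set holds 13 variables: raw acceleration (``accX/Y/Z``), its
static (gravitational) and dynamic (inertial) decomposition (``stX/Y/Z``,
``dyX/Y/Z``), vectorial dynamic body acceleration ``VeDBA``, its 2-s running
mean ``VeDBAs``, and the attitude angles ``Pitch`` and ``Roll``.  The
*extended* set adds 8 running 2-s standard errors: of the raw axes, the
dynamic axes, VeDBA and VeDBAs — 21 variables in total.

All running windows are centred and truncated at the edges (they shrink near
the boundaries rather than lag behind the signal).  X is sway, Y heave, Z
surge; a level tag has static (0, 1, 0) so Pitch = Roll = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import AccelTrace, LabelledSegment

log = logging.getLogger(__name__)

BASE_VARIABLES: tuple[str, ...] = (
    "accX", "accY", "accZ", "stX", "stY", "stZ", "dyX", "dyY", "dyZ",
    "VeDBA", "VeDBAs", "Pitch", "Roll")
EXTENDED_EXTRA_VARIABLES: tuple[str, ...] = (
    "seAccX", "seAccY", "seAccZ", "seDyX", "seDyY", "seDyZ", "seVeDBA", "seVeDBAs")
EXTENDED_VARIABLES: tuple[str, ...] = BASE_VARIABLES + EXTENDED_EXTRA_VARIABLES

_META_COLUMNS = ("time_s", "individual_id", "bout_id", "behaviour")


@dataclass
class FeatureFrame:
    """A labelled (or unlabelled) table of derived variables.

    ``data`` holds one row per sample: ``time_s``, the variable columns for
    the frame's ``variant``, and optionally ``individual_id``, ``bout_id``
    and ``behaviour``.
    """

    data: pd.DataFrame
    frequency_hz: float
    variant: str  # "base" | "extended"

    def __post_init__(self) -> None:
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"feature frame missing columns: {missing}")

    @property
    def variables(self) -> tuple[str, ...]:
        if self.variant == "base":
            return BASE_VARIABLES
        if self.variant == "extended":
            return EXTENDED_VARIABLES
        raise ValueError(f"unknown variant {self.variant!r}")

    def restrict(self, variant: str) -> "FeatureFrame":
        """View of this frame with the column set of ``variant`` (base <= extended)."""
        if variant == self.variant:
            return self
        if variant != "base" or self.variant != "extended":
            raise ValueError(f"cannot restrict {self.variant!r} to {variant!r}")
        keep = [c for c in self.data.columns
                if c in _META_COLUMNS or c in BASE_VARIABLES]
        return FeatureFrame(self.data[keep].copy(), self.frequency_hz, "base")

    def to_csv(self, path) -> None:
        cols = [c for c in _META_COLUMNS if c in self.data.columns and c != "behaviour"]
        cols += list(self.variables)
        if "behaviour" in self.data.columns:
            cols.append("behaviour")
        self.data[cols].to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# windowed primitives (centred, edge-truncated)


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    left = window // 2
    right = window - 1 - left
    i = np.arange(n)
    return np.clip(i - left, 0, n), np.clip(i + right + 1, 0, n)


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean over ``window`` samples, truncated at the edges."""
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    lo, hi = _window_bounds(n, window)
    S = np.concatenate(([0.0], np.cumsum(x)))
    return (S[hi] - S[lo]) / (hi - lo)


def running_se(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running standard error sd/sqrt(m) with sample sd (ddof 1).

    ``m`` is the (edge-truncated) window count.  Windows with fewer than two
    samples have no defined sample sd and return 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3 samples for a running SE")
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    lo, hi = _window_bounds(n, window)
    m = (hi - lo).astype(float)
    S = np.concatenate(([0.0], np.cumsum(x)))
    S2 = np.concatenate(([0.0], np.cumsum(x * x)))
    sums = S[hi] - S[lo]
    sumsq = S2[hi] - S2[lo]
    out = np.zeros(n)
    ok = m >= 2
    var = np.maximum(sumsq[ok] - sums[ok] ** 2 / m[ok], 0.0) / (m[ok] - 1.0)
    out[ok] = np.sqrt(var / m[ok])
    if not ok.all():
        log.debug("running_se: %d window(s) had < 2 samples; returned 0", (~ok).sum())
    return out


def smooth(x: np.ndarray, window_s: float = 2.0, sample_rate_hz: float = 40.0
           ) -> np.ndarray:
    """Centred running mean over ``window_s`` seconds (>= 2 samples)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    window = round(window_s * sample_rate_hz)
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    return running_mean(x, window)


# ---------------------------------------------------------------------------
# named operations


def split_static_dynamic(trace: AccelTrace, window_s: float = 2.0
                         ) -> tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...]]:
    """Decompose raw acceleration into static (running mean) and dynamic parts."""
    window = round(window_s * trace.sample_rate_hz)
    if window < 2:
        raise ValueError("static window must span at least 2 samples")
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    static = tuple(running_mean(a, window) for a in (trace.ax, trace.ay, trace.az))
    dynamic = tuple(a - s for a, s in zip((trace.ax, trace.ay, trace.az), static))
    return static, dynamic


def vedba(dyx: np.ndarray, dyy: np.ndarray, dyz: np.ndarray) -> np.ndarray:
    """Vectorial dynamic body acceleration: the norm of the dynamic vector."""
    if not (len(dyx) == len(dyy) == len(dyz)):
        raise ValueError("dynamic axis series must have equal length")
    return np.sqrt(np.asarray(dyx) ** 2 + np.asarray(dyy) ** 2 + np.asarray(dyz) ** 2)


def pitch_roll(stx: np.ndarray, sty: np.ndarray, stz: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Attitude angles, in degrees, from the static vector.

    Pitch is the elevation of the surge axis (atan2(stZ, hypot(stX, stY)),
    in [-90, 90]); roll rotates sway against heave (atan2(stX, stY), in
    (-180, 180]).  A zero static vector has no attitude: flagged NaN.
    """
    stx, sty, stz = (np.asarray(a, dtype=float) for a in (stx, sty, stz))
    mag = np.sqrt(stx ** 2 + sty ** 2 + stz ** 2)
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(stz, np.hypot(stx, sty)))
        roll = np.degrees(np.arctan2(stx, sty))
    zero = mag == 0
    if zero.any():
        log.warning("pitch_roll: %d sample(s) with zero static vector", zero.sum())
        pitch[zero] = np.nan
        roll[zero] = np.nan
    return pitch, roll


def build_features(trace: AccelTrace, variant: str = "base",
                   static_window_s: float = 2.0, smooth_window_s: float = 2.0,
                   se_window_s: float = 2.0) -> FeatureFrame:
    """Compute the 13 base (or 21 extended) variables for every sample."""
    if variant not in ("base", "extended"):
        raise ValueError(f"unknown variant {variant!r}")
    (stx, sty, stz), (dyx, dyy, dyz) = split_static_dynamic(trace, static_window_s)
    v = vedba(dyx, dyy, dyz)
    vs = smooth(v, smooth_window_s, trace.sample_rate_hz)
    pitch, roll = pitch_roll(stx, sty, stz)
    cols = {
        "time_s": trace.t,
        "accX": trace.ax, "accY": trace.ay, "accZ": trace.az,
        "stX": stx, "stY": sty, "stZ": stz,
        "dyX": dyx, "dyY": dyy, "dyZ": dyz,
        "VeDBA": v, "VeDBAs": vs, "Pitch": pitch, "Roll": roll,
    }
    if variant == "extended":
        w = round(se_window_s * trace.sample_rate_hz)
        for name, series in (("seAccX", trace.ax), ("seAccY", trace.ay),
                             ("seAccZ", trace.az), ("seDyX", dyx), ("seDyY", dyy),
                             ("seDyZ", dyz), ("seVeDBA", v), ("seVeDBAs", vs)):
            cols[name] = running_se(series, w)
    return FeatureFrame(pd.DataFrame(cols), trace.sample_rate_hz, variant)


def build_bout_features(traces: list[AccelTrace],
                        segments: list[LabelledSegment],
                        variant: str = "extended",
                        individual_ids: list[str] | None = None,
                        **window_kwargs) -> FeatureFrame:
    """Labelled features for a calibration set, computed bout by bout.

    Each bout is featurised in isolation (running windows never straddle a
    behaviour boundary, matching how calibration samples are grouped per
    behaviour before derived variables are computed).
    """
    if individual_ids is None:
        individual_ids = [f"cat{i + 1:02d}" for i in range(len(traces))]
    by_id = dict(zip(individual_ids, traces))
    frames = []
    rate = traces[0].sample_rate_hz
    for bout_id, seg in enumerate(segments):
        tr = by_id[seg.individual_id]
        i0 = round(seg.start_s * rate)
        i1 = round(seg.end_s * rate)
        sub = AccelTrace(rate, tr.t[i0:i1], tr.ax[i0:i1], tr.ay[i0:i1], tr.az[i0:i1])
        ff = build_features(sub, variant, **window_kwargs)
        df = ff.data
        df.insert(1, "individual_id", seg.individual_id)
        df.insert(2, "bout_id", bout_id)
        df["behaviour"] = seg.behaviour
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return FeatureFrame(data, rate, variant)


def to_1hz(frame: FeatureFrame) -> FeatureFrame:
    """Mean of every variable over non-overlapping whole seconds.

    Blocks are aligned to each bout's first sample when a ``bout_id`` column
    is present (calibration data), else to t = 0.  A trailing partial second
    is dropped.  Labels attach by majority within the second; ties break to
    the earliest label in the block.
    """
    rate = round(frame.frequency_hz)
    if rate <= 1:
        raise ValueError("frame must be above 1 Hz to aggregate")
    df = frame.data
    if len(df) < rate:
        raise ValueError("need at least one full second of data")

    def _blocks(g: pd.DataFrame) -> pd.DataFrame:
        n = (len(g) // rate) * rate
        if n < len(g):
            log.debug("to_1hz: dropping %d trailing sample(s)", len(g) - n)
        g = g.iloc[:n]
        block = np.arange(n) // rate
        agg = {c: "mean" for c in g.columns
               if c not in ("individual_id", "bout_id", "behaviour")}
        out = g.groupby(block).agg(agg)
        for c in ("individual_id", "bout_id"):
            if c in g.columns:
                out[c] = g[c].iloc[0]
        if "behaviour" in g.columns:
            def majority(labels: pd.Series) -> str:
                counts: dict[str, int] = {}
                for lab in labels:  # first-seen order breaks ties
                    counts[lab] = counts.get(lab, 0) + 1
                return max(counts, key=counts.get)
            out["behaviour"] = [majority(g["behaviour"].iloc[b * rate:(b + 1) * rate])
                                for b in range(len(out))]
        return out

    if "bout_id" in df.columns:
        parts = [_blocks(g) for _, g in df.groupby("bout_id", sort=True)
                 if len(g) >= rate]
        if not parts:
            raise ValueError("no bout holds a full second of data")
        data = pd.concat(parts, ignore_index=True)
    else:
        data = _blocks(df).reset_index(drop=True)
    return FeatureFrame(data, 1.0, frame.variant)
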