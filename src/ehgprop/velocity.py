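"""Short-time cross-correlation estimation of conduction velocity and direction.

A correlation window of length ``w_C`` (default 5 s) slides over the
record in steps of ``d_CI`` (default 0.5 s).  Inside each window the two
signals of a pair are min-max normalized to [0, 1] and cross-correlated,

    C_{x,y}(m) = sum_n x(n) * y(n - m),

and the lag maximizing C within +/- ``d_SS`` (default 1 s) is the
similarity shift.  The shift of the horizontal pair (S1, S3) is the
vertical shift s_V; the shift of the vertical pair (S2, S4) is the
horizontal shift s_H.  A positive s_V means the wave travelled upwards,
a positive s_H that it travelled to the right.  Transitional times are
t_V = -s_V / fs and t_H = -s_H / fs; the conduction-velocity amplitude
is CV = d / sqrt(t_V^2 + t_H^2) with d the electrode spacing, and the
incidence angle phi = atan2(t_H, t_V) measured from the vertical axis.
Estimates with both transitional times zero (no propagation) or with
CV above a physiological ceiling (default 30 cm/s, outliers) are set to
CV = 0 with phi undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import correlate

from ehgprop.preprocess import BandSpec, OrientedSignalSet


@dataclass(frozen=True)
class XCorrParams:
    """Short-time cross-correlation parameters.

    w_c : correlation window length (s); must exceed twice the shift range.
    d_ci : consecutive correlation-interval length (s).
    d_ss : maximum searched shift (s).
    d_cm : inter-electrode spacing (cm).
    cv_max : outlier ceiling on the velocity amplitude (cm/s).
    """

    w_c: float = 5.0
    d_ci: float = 0.5
    d_ss: float = 1.0
    d_cm: float = 7.0
    cv_max: float = 30.0

    def __post_init__(self) -> None:
        if self.w_c <= 2 * self.d_ss:
            raise ValueError(f"w_c ({self.w_c}) must exceed 2 * d_ss ({2 * self.d_ss})")
        if self.d_ci <= 0 or self.d_cm <= 0 or self.cv_max <= 0 or self.d_ss <= 0:
            raise ValueError("d_ci, d_ss, d_cm and cv_max must all be > 0")

    def window_samples(self, fs: float) -> int:
        return int(round(self.w_c * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.d_ci * fs))

    def shift_samples(self, fs: float) -> int:
        return int(round(self.d_ss * fs))


@dataclass(frozen=True)
class VelocityEstimate:
    """Velocity-vector estimate at one correlation interval.

    ``cv`` is 0 exactly when no propagation was detected (or the
    estimate was an outlier), in which case ``phi``, ``direction`` and
    ``sector`` are undefined (None).
    """

    k: int
    center_sample: int
    s_v: int | None
    s_h: int | None
    t_v: float
    t_h: float
    cv: float
    phi: float | None
    direction: str | None
    sector: str | None


@dataclass
class VelocityTrack:
    """Ordered velocity estimates for one record and band."""

    record_id: str
    band: BandSpec
    params: XCorrParams
    fs: float
    estimates: list[VelocityEstimate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.estimates)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "k": e.k,
                "center_s": e.center_sample / self.fs,
                "s_V": e.s_v,
                "s_H": e.s_h,
                "t_V": e.t_v,
                "t_H": e.t_h,
                "CV_cm_s": e.cv,
                "phi_deg": e.phi,
                "direction": e.direction,
                "sector": e.sector,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "k", "center_s", "s_V", "s_H", "t_V", "t_H",
                "CV_cm_s", "phi_deg", "direction", "sector",
            ],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def in_interval(self, interval) -> list[VelocityEstimate]:
        """Estimates whose center sample lies in [start, end)."""
        return [
            e
            for e in self.estimates
            if interval.start_sample <= e.center_sample < interval.end_sample
        ]


def window_normalize(x: np.ndarray) -> np.ndarray | None:
    """Min-max normalize a correlation window to [0, 1].

    Returns ``None`` for a degenerate (constant) window, which callers
    treat as no measurable propagation.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty window")
    lo = x.min()
    rng = x.max() - lo
    if rng == 0:
        return None
    return (x - lo) / rng


def similarity_shift(
    x: np.ndarray | None, y: np.ndarray | None, d_ss_samples: int
) -> int | None:
    """Lag of the cross-correlation maximum within +/- ``d_ss_samples``.

    Implements C(m) = sum_n x(n) y(n - m) over the samples of ``x``:
    a ``y`` that is a delayed copy of ``x`` by k samples yields shift
    -k.  ``y`` may be longer than ``x`` by an even margin, in which
    case it is treated as centred on ``x`` and the extra samples supply
    the shifted products (the infinite-support sum of the correlation
    definition); samples beyond either window contribute zero.  Keeping
    every searched lag at full overlap matters because the windows are
    min-max normalized without mean removal: with zero padding alone,
    the positive offset adds a triangular term peaked at zero lag that
    can alias the maximum toward zero by whole carrier periods.

    Ties are broken toward the smallest |m|, then toward negative m,
    biasing ambiguous windows toward "no propagation" rather than
    spurious fast waves.  Returns ``None`` if either window is
    degenerate.
    """
    if x is None or y is None:
        return None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (len(y) - len(x)) % 2:
        raise ValueError("y must be longer than x by an even margin")
    off = (len(y) - len(x)) // 2
    # R(k) = sum_n x(n) y(n + k); C(m) = R(off - m)
    r = correlate(y, x, mode="full")  # index i <-> k = i - (len(x) - 1)
    lags = off - (np.arange(len(r)) - (len(x) - 1))
    in_range = np.abs(lags) <= d_ss_samples
    c, lags = r[in_range], lags[in_range]
    order = np.lexsort((lags, np.abs(lags)))  # |m| ascending, then m ascending
    best_m = None
    best_c = -np.inf
    for i in order:
        if c[i] > best_c:
            best_c = c[i]
            best_m = int(lags[i])
    return best_m


def shifts_to_velocity(
    s_v: int | None,
    s_h: int | None,
    fs: float,
    d: float,
    cv_max: float,
) -> tuple[float, float, float, float | None]:
    """Convert similarity shifts to (t_V, t_H, CV, phi).

    A degenerate pair (shift ``None``) contributes zero transitional
    time.  Both times zero means no propagation; CV above ``cv_max``
    is an outlier; either way CV = 0 and phi is undefined.  phi is in
    degrees in [-180, 180), measured from the vertical axis with the
    quadrant resolved by the signs of (t_V, t_H).
    """
    if fs <= 0 or d <= 0 or cv_max <= 0:
        raise ValueError("fs, d and cv_max must be > 0")
    t_v = -(s_v or 0) / fs
    t_h = -(s_h or 0) / fs
    if t_v == 0 and t_h == 0:
        return t_v, t_h, 0.0, None
    cv = d / math.hypot(t_v, t_h)
    if cv > cv_max:
        return t_v, t_h, 0.0, None
    phi = math.degrees(math.atan2(t_h, t_v))
    if phi >= 180.0:
        phi -= 360.0
    return t_v, t_h, cv, phi


def assign_sector(phi: float | None) -> tuple[str | None, str | None]:
    """Map an incidence angle to (direction, sector).

    -45 <= phi < 45 -> (vertical, south); 45 <= phi < 135 ->
    (horizontal, east); phi >= 135 or phi < -135 -> (vertical, north);
    -135 <= phi < -45 -> (horizontal, west).  Undefined phi maps to
    (None, None).
    """
    if phi is None:
        return None, None
    if not -180.0 <= phi < 180.0:
        raise ValueError(f"phi {phi} outside [-180, 180)")
    if -45.0 <= phi < 45.0:
        return "vertical", "south"
    if 45.0 <= phi < 135.0:
        return "horizontal", "east"
    if phi >= 135.0 or phi < -135.0:
        return "vertical", "north"
    return "horizontal", "west"


def track_record(
    signals: OrientedSignalSet,
    params: XCorrParams | None = None,
    record_id: str = "",
) -> VelocityTrack:
    """Estimate a velocity vector at every correlation interval of a record.

    Correlation-interval centers tile the record every ``d_CI`` starting
    at ``w_C / 2``; windows that would overrun either record edge are
    omitted.  Within each window the (S1, S3) and (S2, S4) pairs are
    normalized and correlated independently.
    """
    params = params or XCorrParams()
    fs = signals.fs
    win = params.window_samples(fs)
    step = params.step_samples(fs)
    dss = params.shift_samples(fs)
    n = signals.n_samples
    if n < win:
        raise ValueError(f"record ({n} samples) shorter than correlation window ({win})")
    half = win // 2
    track = VelocityTrack(
        record_id=record_id, band=signals.band, params=params, fs=fs
    )
    s1, s2, s3, s4 = signals.S1, signals.S2, signals.S3, signals.S4

    def extended(sig: np.ndarray, lo: int, hi: int) -> np.ndarray | None:
        """Normalized window widened by d_SS per side; zero-fill past edges."""
        elo, ehi = lo - dss, hi + dss
        core = window_normalize(sig[max(elo, 0) : min(ehi, n)])
        if core is None:
            return None
        return np.pad(core, (max(0, -elo), max(0, ehi - n)))

    k = 0
    for center in range(half, n - (win - half) + 1, step):
        lo, hi = center - half, center - half + win
        s_v = similarity_shift(
            window_normalize(s1[lo:hi]), extended(s3, lo, hi), dss
        )
        s_h = similarity_shift(
            window_normalize(s2[lo:hi]), extended(s4, lo, hi), dss
        )
        t_v, t_h, cv, phi = shifts_to_velocity(
            s_v, s_h, fs, params.d_cm, params.cv_max
        )
        direction, sector = assign_sector(phi)
        track.estimates.append(
            VelocityEstimate(
                k=k, center_sample=center, s_v=s_v, s_h=s_h,
                t_v=t_v, t_h=t_h, cv=cv, phi=phi,
                direction=direction, sector=sector,
            )
        )
        k += 1
    return track
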