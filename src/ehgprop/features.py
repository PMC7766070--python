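"""Per-interval propagation features and sample entropy.

For every annotated interval (dummy or contraction) and analysis band,
the velocity track is aggregated into:

* the percentages of correlation intervals with a nonzero velocity
  vector in the vertical and horizontal directions,
  P_V = 100 N_V / N and P_H = 100 N_H / N, and their ratio RP_VH
  (N counts *all* correlation intervals in the annotated interval,
  including CV = 0 ones);
* the mean conduction velocities by direction, Vbar_V and Vbar_H
  (excluding CV = 0 estimates), and their ratio RV_VH;
* the same percentage/mean statistics per sector (south, north,
  east, west);
* sample entropies SE_S2 and SE_S3 of the band-filtered S2 and S3
  segments cropped to the interval (m = 3, r = 0.15 x SD).

Undefined quantities (zero denominators) are flagged as NaN, never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ehgprop.io import AnnotatedInterval, EHGRecord
from ehgprop.preprocess import BANDS, BandSpec, preprocess_record
from ehgprop.velocity import VelocityTrack, XCorrParams, track_record


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: template length m and matching margin r.

    By default r is relative (a fraction of the analyzed segment's
    standard deviation, the convention of the SampEn literature);
    ``relative=False`` treats r as an absolute amplitude margin.
    """

    m: int = 3
    r: float = 0.15
    relative: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")


def sample_entropy(x: np.ndarray, params: SampEnParams | None = None) -> float:
    """Sample entropy SampEn(m, r) = -ln(A / B) of a 1-D series.

    B counts pairs of templates of length m and A pairs of length m + 1
    within Chebyshev distance r (self-matches excluded, both counts over
    template starts 0 .. N-m-1).  Returns NaN when no template pair
    matches at either length (degenerate entropy).
    """
    params = params or SampEnParams()
    x = np.asarray(x, dtype=float)
    m = params.m
    if len(x) <= m + 1:
        raise ValueError(f"series length {len(x)} too short for m={m}")
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("sample entropy of a constant series is undefined")
    r = params.r * sd if params.relative else params.r

    n_t = len(x) - m  # template count; both lengths compared over starts < n_t
    # Chebyshev distances accumulated coordinate-by-coordinate keeps the
    # memory at O(n_t^2) floats, fine for interval-length segments.
    d_m = np.zeros((n_t, n_t))
    for j in range(m):
        np.maximum(d_m, np.abs(x[j : j + n_t, None] - x[None, j : j + n_t]), out=d_m)
    d_m1 = np.maximum(d_m, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]))
    iu = np.triu_indices(n_t, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


@dataclass
class PropagationFeatures:
    """Feature vector of one (record, interval, band) cell; NaN = undefined."""

    record_id: str
    group: str
    interval: AnnotatedInterval
    band: BandSpec
    N: int
    N_V: int
    N_H: int
    P_V: float
    P_H: float
    RP_VH: float
    Vbar_V: float
    Vbar_H: float
    RV_VH: float
    P_S: float
    P_N: float
    P_E: float
    P_W: float
    Vbar_S: float
    Vbar_N: float
    Vbar_E: float
    Vbar_W: float
    SE_S2: float = math.nan
    SE_S3: float = math.nan

    def as_row(self) -> dict:
        return {
            "record_id": self.record_id,
            "group": self.group,
            "interval_kind": self.interval.kind,
            "start_sample": self.interval.start_sample,
            "end_sample": self.interval.end_sample,
            "band": self.band.name,
            "N": self.N,
            "P_V": self.P_V,
            "P_H": self.P_H,
            "RP_VH": self.RP_VH,
            "Vbar_V": self.Vbar_V,
            "Vbar_H": self.Vbar_H,
            "RV_VH": self.RV_VH,
            "P_S": self.P_S,
            "P_N": self.P_N,
            "P_E": self.P_E,
            "P_W": self.P_W,
            "Vbar_S": self.Vbar_S,
            "Vbar_N": self.Vbar_N,
            "Vbar_E": self.Vbar_E,
            "Vbar_W": self.Vbar_W,
            "SE_S2": self.SE_S2,
            "SE_S3": self.SE_S3,
        }


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else math.nan


def interval_features(
    track: VelocityTrack,
    interval: AnnotatedInterval,
    record_id: str = "",
    group: str = "synthetic",
) -> PropagationFeatures:
    """Aggregate the velocity estimates of one annotated interval.

    An estimate belongs to the interval iff its center sample lies in
    [start, end).  Percentages are relative to all N estimates in the
    interval; velocity means exclude CV = 0 estimates.
    """
    members = track.in_interval(interval)
    n = len(members)
    if n == 0:
        raise ValueError(
            f"interval [{interval.start_sample}, {interval.end_sample}) contains "
            "no correlation-interval centers"
        )
    by_dir = {"vertical": [], "horizontal": []}
    by_sector = {"south": [], "north": [], "east": [], "west": []}
    for e in members:
        if e.cv != 0:
            by_dir[e.direction].append(e.cv)
            by_sector[e.sector].append(e.cv)
    n_v, n_h = len(by_dir["vertical"]), len(by_dir["horizontal"])
    p_v, p_h = 100.0 * n_v / n, 100.0 * n_h / n
    sector_p = {s: 100.0 * len(v) / n for s, v in by_sector.items()}
    return PropagationFeatures(
        record_id=record_id or track.record_id,
        group=group,
        interval=interval,
        band=track.band,
        N=n,
        N_V=n_v,
        N_H=n_h,
        P_V=p_v,
        P_H=p_h,
        RP_VH=(p_v / p_h) if p_h > 0 else math.nan,
        Vbar_V=_mean_or_nan(by_dir["vertical"]),
        Vbar_H=_mean_or_nan(by_dir["horizontal"]),
        RV_VH=(
            _mean_or_nan(by_dir["vertical"]) / _mean_or_nan(by_dir["horizontal"])
            if n_v > 0 and n_h > 0
            else math.nan
        ),
        P_S=sector_p["south"],
        P_N=sector_p["north"],
        P_E=sector_p["east"],
        P_W=sector_p["west"],
        Vbar_S=_mean_or_nan(by_sector["south"]),
        Vbar_N=_mean_or_nan(by_sector["north"]),
        Vbar_E=_mean_or_nan(by_sector["east"]),
        Vbar_W=_mean_or_nan(by_sector["west"]),
    )


def interval_mean_cv(track: VelocityTrack, interval: AnnotatedInterval | None = None) -> float:
    """Mean conduction-velocity amplitude over nonzero estimates.

    With ``interval=None`` the whole record is used.  This is the
    per-record / per-interval average CV statistic.
    """
    members = track.estimates if interval is None else track.in_interval(interval)
    nonzero = [e.cv for e in members if e.cv != 0]
    return _mean_or_nan(nonzero)


FEATURE_COLUMNS = [
    "record_id", "group", "interval_kind", "start_sample", "end_sample", "band",
    "N", "P_V", "P_H", "RP_VH", "Vbar_V", "Vbar_H", "RV_VH",
    "P_S", "P_N", "P_E", "P_W", "Vbar_S", "Vbar_N", "Vbar_E", "Vbar_W",
    "SE_S2", "SE_S3", "error",
]


def feature_table(
    records: list[tuple[EHGRecord, list[AnnotatedInterval]]],
    bands: list[BandSpec | str] | None = None,
    xcorr: XCorrParams | None = None,
    sampen: SampEnParams | None = None,
) -> pd.DataFrame:
    """One feature row per (record, annotated interval, band).

    Sample entropies are computed on the band-filtered S2/S3 segments
    cropped to each interval.  Per-interval failures surface as flagged
    rows (``error`` column set), never as silent drops.
    """
    bands = [BANDS[b] if isinstance(b, str) else b for b in (bands or ["B0p", "Bb", "B1", "B2", "B3"])]
    xcorr = xcorr or XCorrParams()
    sampen = sampen or SampEnParams()
    rows = []
    for record, intervals in records:
        for band in bands:
            oriented = preprocess_record(record, band)
            track = track_record(oriented, xcorr, record_id=record.record_id)
            for iv in intervals:
                try:
                    feats = interval_features(
                        track, iv, record_id=record.record_id, group=record.group
                    )
                    seg2 = oriented.S2[iv.start_sample : iv.end_sample]
                    seg3 = oriented.S3[iv.start_sample : iv.end_sample]
                    feats.SE_S2 = sample_entropy(seg2, sampen)
                    feats.SE_S3 = sample_entropy(seg3, sampen)
                    row = feats.as_row()
                    row["error"] = ""
                except ValueError as exc:
                    row = {
                        "record_id": record.record_id,
                        "group": record.group,
                        "interval_kind": iv.kind,
                        "start_sample": iv.start_sample,
                        "end_sample": iv.end_sample,
                        "band": band.name,
                        "error": str(exc),
                    }
                rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
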