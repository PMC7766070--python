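"""Fourth-signal derivation, signal orientation, and band-pass filtering.

The public dataset provides three bipolar signals measured on a square
electrode grid: S1 = E2 - E1 (top pair), S2 = E2 - E3 (left pair) and
S3 = E4 - E3 (bottom pair).  The fourth bipolar signal, between the two
right-hand electrodes, follows from the electrode potentials:

    S4 = E4 - E1 = S1 - S2 + S3.

For the cross-correlations of the horizontal pair (S1, S3) and the
vertical pair (S2, S4) to peak at the true travel lag, the members of
each pair must be equally oriented, so S3 and S4 are multiplied by -1.
All filtering uses a fourth-order Butterworth band-pass applied
forward-backward (zero phase).  The processing order is fixed: wide-band
filter (0.08-5.0 Hz) -> derive S4 -> per-band filter -> orient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band edges ({self.f_low}, {self.f_high})")

    def validate_for_fs(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_high} Hz >= Nyquist ({fs / 2} Hz)"
            )


#: Canonical analysis bands.  B0p covers the contraction mechanism below
#: 1 Hz; B1-B3 cover the maternal-heart-rate influence above 1 Hz; Bb is
#: the broad contraction band; ``wide`` is the acquisition-wide band used
#: before deriving S4.
BANDS: dict[str, BandSpec] = {
    "B0p": BandSpec("B0p", 0.3, 1.0),
    "Bb": BandSpec("Bb", 0.3, 4.0),
    "B1": BandSpec("B1", 1.0, 2.2),
    "B2": BandSpec("B2", 2.2, 3.5),
    "B3": BandSpec("B3", 3.5, 5.0),
    "wide": BandSpec("wide", 0.08, 5.0),
}


def bandpass(x: np.ndarray, fs: float, band: BandSpec | str) -> np.ndarray:
    """Zero-phase fourth-order Butterworth band-pass.

    The filter is a single fourth-order band-pass design (two poles per
    edge) applied forward-backward with odd-reflection padding, giving
    zero phase shift and a doubled magnitude roll-off.
    """
    if isinstance(band, str):
        band = BANDS[band]
    band.validate_for_fs(fs)
    x = np.asarray(x, dtype=float)
    b, a = butter(2, [band.f_low, band.f_high], btype="bandpass", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"signal length {len(x)} too short for filter warm-up")
    return filtfilt(b, a, x, padtype="odd")


def derive_s4(s1: np.ndarray, s2: np.ndarray, s3: np.ndarray) -> np.ndarray:
    """Derive the right-pair bipolar signal S4 = S1 - S2 + S3."""
    s1, s2, s3 = (np.asarray(s, dtype=float) for s in (s1, s2, s3))
    if not len(s1) == len(s2) == len(s3):
        raise ValueError(f"length mismatch: {len(s1)}, {len(s2)}, {len(s3)}")
    return s1 - s2 + s3


@dataclass
class OrientedSignalSet:
    """The four band-filtered bipolar signals with S3 and S4 sign-flipped.

    Orientation is applied exactly once at construction; the flag guards
    against a second application.
    """

    S1: np.ndarray
    S2: np.ndarray
    S3: np.ndarray
    S4: np.ndarray
    band: BandSpec
    fs: float
    oriented: bool = True

    def __post_init__(self) -> None:
        n = len(self.S1)
        if not all(len(s) == n for s in (self.S2, self.S3, self.S4)):
            raise ValueError("oriented signal set has unequal channel lengths")

    @property
    def n_samples(self) -> int:
        return len(self.S1)


def orient(
    s1: np.ndarray,
    s2: np.ndarray,
    s3: np.ndarray,
    s4: np.ndarray,
    band: BandSpec,
    fs: float,
) -> OrientedSignalSet:
    """Equally orient both signal pairs: S3 <- -S3, S4 <- -S4.

    Accepts plain arrays only; passing an already-oriented set (or its
    members via an :class:`OrientedSignalSet`) is a state error.
    """
    for s in (s1, s2, s3, s4):
        if isinstance(s, OrientedSignalSet):
            raise RuntimeError("signals are already oriented")
    return OrientedSignalSet(
        S1=np.asarray(s1, dtype=float),
        S2=np.asarray(s2, dtype=float),
        S3=-np.asarray(s3, dtype=float),
        S4=-np.asarray(s4, dtype=float),
        band=band,
        fs=fs,
    )


def preprocess_record(record, band: BandSpec | str) -> OrientedSignalSet:
    """Full preprocessing chain for one record and one analysis band.

    Wide-band filters S1-S3 (0.08-5.0 Hz), derives S4, band-filters all
    four signals for the requested band, and orients the pairs.
    """
    if isinstance(band, str):
        band = BANDS[band]
    fs = record.fs
    wide = BANDS["wide"]
    s1 = bandpass(record.channel("S1"), fs, wide)
    s2 = bandpass(record.channel("S2"), fs, wide)
    s3 = bandpass(record.channel("S3"), fs, wide)
    s4 = derive_s4(s1, s2, s3)
    s1, s2, s3, s4 = (bandpass(s, fs, band) for s in (s1, s2, s3, s4))
    return orient(s1, s2, s3, s4, band, fs)
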