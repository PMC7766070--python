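"""Synthetic EHG-like records with known planar-wave ground truth.

Four electrodes sit at the corners of an axis-aligned square of side
``d`` (7 cm by default): E2 top-left, E1 top-right, E3 bottom-left and
E4 bottom-right.  A planar wave with conduction velocity ``cv_true``
and incidence angle ``phi_true`` (degrees from the vertical axis;
0 = southward/down, 90 = eastward/right) reaches electrode i with delay

    tau_i = (p_i . u) / cv_true,      u = (sin phi, cos phi),

where p_i is the electrode position in (rightward, downward)
coordinates.  Bipolar channels are derived exactly from the electrode
potentials (S1 = E2-E1, S2 = E2-E3, S3 = E4-E3, S4 = E4-E1), so every
algebraic identity of the estimator holds by construction.

A pure-delay plane wave travelling exactly along an array axis makes
one bipolar pair identically zero (both of its electrodes lie on the
same wavefront), which no lag estimator can use.  Real tissue is not
homogeneous, so the generator imposes a small static amplitude gradient
across the array (default 10% per array span on both axes); this keeps
all directions measurable while leaving correlation-lag locations
essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ehgprop.io import (
    AnnotatedInterval,
    EHGRecord,
    write_annotations,
    write_record,
    write_sidecar,
)

#: electrode positions in units of d, coordinates (rightward, downward)
ELECTRODE_POSITIONS = {
    "E2": (0.0, 0.0),
    "E1": (1.0, 0.0),
    "E3": (0.0, 1.0),
    "E4": (1.0, 1.0),
}


@dataclass(frozen=True)
class WaveSpec:
    """One planar wave: velocity amplitude, direction, timing and shape."""

    cv_true: float
    phi_true: float
    onset_s: float
    waveform: str = "gaussian_burst"
    carrier_hz: float = 1.5
    burst_sd_s: float = 0.5
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.cv_true <= 0:
            raise ValueError(f"cv_true must be > 0, got {self.cv_true}")
        if not -180.0 <= self.phi_true < 180.0:
            raise ValueError(f"phi_true {self.phi_true} outside [-180, 180)")
        if self.waveform not in ("gaussian_burst", "sinus_burst"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Waveform value at times ``t`` (seconds relative to record start)."""
        dt = t - self.onset_s
        carrier = np.sin(2 * np.pi * self.carrier_hz * dt)
        if self.waveform == "gaussian_burst":
            envelope = np.exp(-(dt**2) / (2 * self.burst_sd_s**2))
        else:  # rectangular window of +/- 3 sd
            envelope = (np.abs(dt) <= 3 * self.burst_sd_s).astype(float)
        return self.amplitude * envelope * carrier

    def true_transitional_times(self, d_cm: float) -> tuple[float, float]:
        """(t_V, t_H) in seconds for electrode spacing ``d_cm``."""
        phi = np.deg2rad(self.phi_true)
        return d_cm * np.cos(phi) / self.cv_true, d_cm * np.sin(phi) / self.cv_true

    @property
    def true_sector(self) -> str:
        from ehgprop.velocity import assign_sector

        return assign_sector(self.phi_true)[1]


@dataclass
class SynthRecord:
    """A synthetic record plus its ground truth and annotations."""

    record: EHGRecord
    waves: list[WaveSpec]
    noise_sd: float
    rng_seed: int
    intervals: list[AnnotatedInterval] = field(default_factory=list)
    d_cm: float = 7.0
    amp_gradient: float = 0.1

    def write(self, directory: str | Path) -> Path:
        """Write WFDB record + annotation marks + ground-truth sidecar."""
        directory = Path(directory)
        base = directory / self.record.record_id
        hea = write_record(self.record, base)
        write_annotations(self.intervals, base.with_suffix(".ann"))
        write_sidecar(
            base.with_suffix(".truth.json"),
            {
                "record_id": self.record.record_id,
                "d_cm": self.d_cm,
                "noise_sd": self.noise_sd,
                "rng_seed": self.rng_seed,
                "amp_gradient": self.amp_gradient,
                "waves": [
                    {
                        "CV_true": w.cv_true,
                        "phi_true": w.phi_true,
                        "onset_s": w.onset_s,
                        "waveform": w.waveform,
                        "carrier_hz": w.carrier_hz,
                        "burst_sd_s": w.burst_sd_s,
                        "amplitude": w.amplitude,
                    }
                    for w in self.waves
                ],
            },
        )
        return hea


def simulate_record(
    waves: list[WaveSpec],
    fs: float = 20.0,
    duration_s: float = 120.0,
    d_cm: float = 7.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    amp_gradient: float = 0.1,
    min_separation_s: float = 5.0,
    record_id: str = "synth",
) -> SynthRecord:
    """Simulate electrode potentials for a train of planar waves.

    Each electrode potential is the sum of delayed copies of every
    wave's waveform (scaled by the electrode's static amplitude factor)
    plus white Gaussian noise of standard deviation ``noise_sd``.
    Bipolar channels S1-S3 and a measured S4 are derived exactly; the
    unipolar potentials E1-E4 are retained as channels for oracle
    checks.  Contraction annotations cover each wave's burst; dummy
    annotations cover the quiet gaps.

    Waves must be separated by more than ``min_separation_s`` plus their
    burst support; overlapping waves raise ``ValueError``.
    """
    waves = sorted(waves, key=lambda w: w.onset_s)
    for a, b in zip(waves, waves[1:]):
        support = 3 * (a.burst_sd_s + b.burst_sd_s)
        if b.onset_s - a.onset_s <= min_separation_s + support:
            raise ValueError(
                f"waves at {a.onset_s}s and {b.onset_s}s overlap "
                f"(need separation > {min_separation_s + support}s)"
            )
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    potentials = {}
    for name, (u_pos, v_pos) in ELECTRODE_POSITIONS.items():
        # static amplitude factor: linear gradient across both axes
        a_i = 1.0 + amp_gradient * (u_pos + v_pos - 1.0)
        e = np.zeros(n)
        for w in waves:
            phi = np.deg2rad(w.phi_true)
            tau = d_cm * (u_pos * np.sin(phi) + v_pos * np.cos(phi)) / w.cv_true
            e += a_i * w.sample(t - tau)
        if noise_sd > 0:
            e += rng.normal(0.0, noise_sd, size=n)
        potentials[name] = e

    signals = {
        "S1": potentials["E2"] - potentials["E1"],
        "S2": potentials["E2"] - potentials["E3"],
        "S3": potentials["E4"] - potentials["E3"],
        "S4_measured": potentials["E4"] - potentials["E1"],
        **potentials,
    }
    record = EHGRecord(record_id=record_id, fs=fs, signals=signals, group="synthetic")

    intervals = _annotate_spans(waves, d_cm, fs, n)
    return SynthRecord(
        record=record,
        waves=waves,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
        intervals=intervals,
        d_cm=d_cm,
        amp_gradient=amp_gradient,
    )


def _annotate_spans(
    waves: list[WaveSpec], d_cm: float, fs: float, n: int
) -> list[AnnotatedInterval]:
    """Contraction intervals over wave bursts, dummy intervals over gaps."""
    intervals = []
    spans = []
    for w in waves:
        tau_max = np.sqrt(2) * d_cm / w.cv_true
        lo = max(0, int((w.onset_s - 3 * w.burst_sd_s) * fs))
        hi = min(n, int(np.ceil((w.onset_s + 3 * w.burst_sd_s + tau_max) * fs)))
        if hi > lo:
            intervals.append(AnnotatedInterval("contraction", lo, hi))
            spans.append((lo, hi))
    # dummy intervals in the gaps, inset by one second to avoid burst tails
    inset = int(fs)
    edges = [0] + [s for span in spans for s in span] + [n]
    for lo, hi in zip(edges[::2], edges[1::2]):
        lo, hi = lo + inset, hi - inset
        if hi - lo >= int(10 * fs):
            intervals.append(AnnotatedInterval("dummy", lo, hi))
    return sorted(intervals, key=lambda iv: iv.start_sample)


#: Per-class feature distributions emulating the direction of effects
#: observed for dummy intervals above 1 Hz: preterm records show a lower
#: vertical and higher horizontal percentage of velocity vectors and a
#: lower sample entropy of the vertical signal.  Values (mean_preterm,
#: mean_term, sd) on each feature's natural scale.
DEFAULT_EFFECT_SPEC: dict[str, tuple[float, float, float]] = {
    "P_V": (32.7, 40.8, 10.0),
    "P_H": (45.2, 38.5, 11.0),
    "RP_VH": (0.86, 1.15, 0.48),
    "Vbar_V": (9.5, 9.2, 1.0),
    "Vbar_H": (9.0, 8.9, 0.8),
    "RV_VH": (1.07, 1.04, 0.13),
    "SE_S2": (0.70, 1.00, 0.25),
    "SE_S3": (1.00, 1.05, 0.30),
}


def simulate_feature_cohort(
    n_per_class: tuple[int, int] = (47, 53),
    effect_spec: dict[str, tuple[float, float, float]] | None = None,
    rng_seed: int = 0,
    null: bool = False,
):
    """Sample a labelled feature cohort from per-class Gaussian features.

    ``n_per_class`` is (n_preterm, n_term).  ``effect_spec`` maps each
    feature name to (mean_preterm, mean_term, sd); features are sampled
    independently.  ``null=True`` collapses both class means to their
    average (zero effect).  Returns (DataFrame X with a ``group``
    column, label array y with preterm = 1).
    """
    import pandas as pd

    effect_spec = effect_spec or DEFAULT_EFFECT_SPEC
    for name, (_, _, sd) in effect_spec.items():
        if sd <= 0:
            raise ValueError(f"feature {name!r} has non-positive variance")
    rng = np.random.default_rng(rng_seed)
    n_pre, n_term = n_per_class
    data = {}
    for name, (mu_pre, mu_term, sd) in effect_spec.items():
        if null:
            mu_pre = mu_term = 0.5 * (mu_pre + mu_term)
        data[name] = np.concatenate(
            [
                rng.normal(mu_pre, sd, size=n_pre),
                rng.normal(mu_term, sd, size=n_term),
            ]
        )
    x = pd.DataFrame(data)
    x["group"] = ["preterm"] * n_pre + ["term"] * n_term
    y = np.concatenate([np.ones(n_pre), np.zeros(n_term)])
    return x, y
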