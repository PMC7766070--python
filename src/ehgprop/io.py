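"""Record model and WFDB-format I/O for multichannel EHG records.

An EHG record holds at least the three bipolar abdominal signals S1, S2
and S3 sampled at a common rate (20 Hz for the public term/preterm
dataset this package targets), plus optional extra channels (a measured
S4, a tocogram, or unipolar electrode potentials on synthetic records).
Signals are read from and written to standard WFDB header/signal pairs
(.hea + .dat, format 16).  Interval annotations (dummy / contraction
spans) use a textual annotation dialect of paired begin/end marks whose
symbol-to-kind mapping is configurable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GROUPS = ("preterm", "term", "nonpregnant", "synthetic")

#: record-name prefix -> group, for the public term/preterm dataset
GROUP_PREFIXES = {
    "tpehgt_p": "preterm",
    "tpehgt_t": "term",
    "tpehgt_n": "nonpregnant",
}

#: default mapping of begin-mark auxiliary strings to interval kinds
DEFAULT_SYMBOL_MAP = {
    "C": "contraction",
    "c": "contraction",
    "D": "dummy",
    "d": "dummy",
}

MAX_CHANNEL_NAME = 40  # WFDB signal-description field limit we enforce


class FormatError(ValueError):
    """Raised for missing or corrupt WFDB headers/annotation streams."""


@dataclass
class EHGRecord:
    """Multichannel EHG signal container.

    Parameters
    ----------
    record_id : str
        Record name (used as the WFDB record name on write).
    fs : float
        Sampling frequency in Hz; strictly positive.
    signals : dict
        Ordered map of channel name to 1-D float sample array.  All
        channels must have the same length.
    group : str
        One of ``preterm``, ``term``, ``nonpregnant``, ``synthetic``.
    """

    record_id: str
    fs: float
    signals: dict[str, np.ndarray]
    group: str = "synthetic"
    gestation_weeks_at_recording: float | None = None
    gestation_weeks_at_delivery: float | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.signals:
            raise ValueError("record has no channels")
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        if lengths.pop() == 0:
            raise ValueError("record duration must be > 0")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.signals[name]


@dataclass(frozen=True)
class AnnotatedInterval:
    """Half-open [start_sample, end_sample) span of kind dummy or contraction."""

    kind: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.kind not in ("dummy", "contraction"):
            raise ValueError(f"kind must be dummy|contraction, got {self.kind!r}")
        if self.start_sample < 0 or self.end_sample <= self.start_sample:
            raise ValueError(
                f"invalid interval [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


def infer_group(record_id: str) -> str:
    for prefix, group in GROUP_PREFIXES.items():
        if record_id.startswith(prefix):
            return group
    return "synthetic"


# ---------------------------------------------------------------------------
# WFDB header/signal files (format 16, little-endian int16)
# ---------------------------------------------------------------------------

_SIGLINE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\S*\s+"
    r"(?P<gain>[\d.eE+-]+)(\((?P<baseline>-?\d+)\))?(/(?P<units>\S+))?"
    r"(?:\s+(?P<adcres>\d+)\s+(?P<adczero>-?\d+)\s+(?P<initval>-?\d+)"
    r"\s+(?P<cksum>-?\d+)\s+(?P<bsize>\d+))?"
    r"(?:\s+(?P<desc>.*\S))?\s*$"
)


def read_record(
    path: str | Path,
    dialect: str = "wfdb",
    group: str | None = None,
    min_channels: int = 3,
) -> EHGRecord:
    """Read a WFDB record (``.hea`` + companion ``.dat``) into an :class:`EHGRecord`.

    ``path`` may point at the header file or at the record base name.
    The group is inferred from the record-name prefix unless ``group``
    overrides it.
    """
    if dialect != "wfdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing WFDB header: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty WFDB header: {hea}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"corrupt WFDB header line: {lines[0]!r}")
    record_id = head[0]
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise FormatError(f"header declares {n_sig} signals, found {len(sig_lines)}")

    names, gains, baselines, files = [], [], [], []
    for i, ln in enumerate(sig_lines):
        m = _SIGLINE.match(ln)
        if m is None:
            raise FormatError(f"unparseable signal line: {ln!r}")
        if int(m.group("fmt")) != 16:
            raise FormatError(f"only WFDB format 16 is supported, got {m.group('fmt')}")
        files.append(m.group("file"))
        gains.append(float(m.group("gain")) or 200.0)
        baselines.append(int(m.group("baseline") or 0))
        names.append(m.group("desc") or f"sig{i}")
    if len(set(files)) != 1:
        raise FormatError("multi-file records are not supported")

    dat = hea.parent / files[0]
    if not dat.exists():
        raise FormatError(f"missing WFDB signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if len(raw) != n_sig * n_samples:
        raise FormatError(
            f"signal file length {len(raw)} != {n_sig} signals x {n_samples} samples"
        )
    raw = raw.reshape(n_samples, n_sig)
    signals = {
        name: (raw[:, i].astype(float) - baselines[i]) / gains[i]
        for i, name in enumerate(names)
    }
    if len(signals) < min_channels:
        raise FormatError(
            f"expected >= {min_channels} channels, record has {len(signals)}"
        )
    return EHGRecord(
        record_id=record_id,
        fs=fs,
        signals=signals,
        group=group or infer_group(record_id),
    )


def write_record(record: EHGRecord, path: str | Path, gain: float | None = None) -> Path:
    """Write ``record`` as a WFDB header/signal pair; returns the header path.

    Signals are quantized to int16 with a per-channel gain chosen so the
    full amplitude range fits; ``read_record`` inverts the quantized
    samples bit-exactly.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    base.parent.mkdir(parents=True, exist_ok=True)
    names = list(record.signals)
    for name in names:
        if len(name) > MAX_CHANNEL_NAME:
            raise ValueError(
                f"channel name {name!r} exceeds {MAX_CHANNEL_NAME} characters"
            )
    gains = []
    digital = np.empty((record.n_samples, len(names)), dtype="<i2")
    for i, name in enumerate(names):
        x = record.signals[name]
        peak = float(np.max(np.abs(x))) if len(x) else 0.0
        g = gain if gain is not None else (200.0 if peak == 0 else min(1000.0, 32000.0 / peak))
        gains.append(g)
        q = np.round(x * g)
        if np.any(np.abs(q) > 32767):
            raise ValueError(f"channel {name!r} overflows int16 at gain {g}")
        digital[:, i] = q.astype("<i2")

    dat_name = base.name + ".dat"
    header = [f"{record.record_id} {len(names)} {record.fs:g} {record.n_samples}"]
    for i, name in enumerate(names):
        header.append(f"{dat_name} 16 {gains[i]:g}(0)/uV 16 0 0 0 0 {name}")
    header.append(f"# group: {record.group}")
    (base.parent / (base.name + ".hea")).write_text("\n".join(header) + "\n")
    digital.tofile(base.parent / dat_name)
    return base.parent / (base.name + ".hea")


# ---------------------------------------------------------------------------
# Interval annotations: textual paired begin/end marks
# ---------------------------------------------------------------------------


def read_annotations(
    path: str | Path,
    record: EHGRecord,
    symbol_map: dict[str, str] | None = None,
) -> list[AnnotatedInterval]:
    """Read paired begin/end interval marks into :class:`AnnotatedInterval` spans.

    The stream is one mark per line, ``sample<TAB>symbol<TAB>aux``: the
    begin symbol ``(`` opens an interval whose kind is given by mapping
    ``aux`` through ``symbol_map`` (default: C/c -> contraction,
    D/d -> dummy); the end symbol ``)`` closes the most recent open
    interval of the same kind.  Unpaired marks raise
    :class:`FormatError` listing the offending samples.
    """
    symbol_map = symbol_map or DEFAULT_SYMBOL_MAP
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing annotation file: {path}")
    open_marks: dict[str, list[int]] = {}
    intervals: list[AnnotatedInterval] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: unparseable mark {line!r}")
        sample, symbol, aux = int(parts[0]), parts[1], parts[2]
        if aux not in symbol_map:
            raise FormatError(f"{path}:{lineno}: unknown annotation aux {aux!r}")
        kind = symbol_map[aux]
        if symbol == "(":
            open_marks.setdefault(kind, []).append(sample)
        elif symbol == ")":
            if not open_marks.get(kind):
                raise FormatError(
                    f"{path}:{lineno}: end mark at sample {sample} without begin ({kind})"
                )
            start = open_marks[kind].pop(0)
            if sample > record.n_samples:
                raise FormatError(
                    f"{path}:{lineno}: interval end {sample} beyond record "
                    f"length {record.n_samples}"
                )
            intervals.append(AnnotatedInterval(kind, start, sample))
        else:
            raise FormatError(f"{path}:{lineno}: unknown mark symbol {symbol!r}")
    dangling = [(k, s) for k, marks in open_marks.items() for s in marks]
    if dangling:
        raise FormatError(f"unpaired begin marks (kind, sample): {dangling}")
    return sorted(intervals, key=lambda iv: iv.start_sample)


def write_annotations(
    intervals: list[AnnotatedInterval],
    path: str | Path,
    symbol_map: dict[str, str] | None = None,
) -> Path:
    """Write intervals as paired begin/end marks (inverse of :func:`read_annotations`)."""
    symbol_map = symbol_map or DEFAULT_SYMBOL_MAP
    kind_to_aux = {}
    for aux, kind in symbol_map.items():
        kind_to_aux.setdefault(kind, aux)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    marks = []
    for iv in intervals:
        marks.append((iv.start_sample, "(", kind_to_aux[iv.kind]))
        marks.append((iv.end_sample, ")", kind_to_aux[iv.kind]))
    marks.sort(key=lambda m: (m[0], m[1] == "("))
    path.write_text("".join(f"{s}\t{sym}\t{aux}\n" for s, sym, aux in marks))
    return path


# ---------------------------------------------------------------------------
# Ground-truth sidecars for synthetic records
# ---------------------------------------------------------------------------


def write_sidecar(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
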