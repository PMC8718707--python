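"""WFDB ingestion, beat segmentation, AAMI mapping and dataset splitting.

Implements a small, self-contained reader/writer for the WFDB file family
(``.hea`` header, ``.dat`` signal in formats 16 and 212, ``.atr`` MIT-format
annotations) — enough to ingest MIT-BIH-style arrhythmia records and to
round-trip the fixtures the test suite writes. Beats are cut as fixed-length
windows centered on annotated R positions and labelled with the five AAMI
superclasses (N, S, V, F, Q); non-beat annotation symbols are rejected.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import ECGBeat

__all__ = ["ECGRecord", "DatasetSplit", "read_wfdb_record", "write_wfdb_record",
           "map_aami", "segment_beats", "balance_and_split",
           "beats_to_csv", "read_beats_csv", "AAMI_MAPPING"]


# MIT annotation-code <-> symbol table (beat and non-beat annotations).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

# Beat symbol -> AAMI superclass; anything absent is a non-beat annotation.
AAMI_MAPPING = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}


@dataclass
class ECGRecord:
    """A raw multi-lead recording with (sample_index, symbol) annotations."""

    signal: np.ndarray            # (C, L), physical units (mV)
    sampling_rate: float
    lead_names: list
    annotations: list

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError("one lead name per signal channel required")
        length = self.signal.shape[1]
        for idx, _sym in self.annotations:
            if not 0 <= idx < length:
                raise ValueError(f"annotation index {idx} outside [0, {length})")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def length(self) -> int:
        return self.signal.shape[1]


@dataclass
class DatasetSplit:
    """Disjoint train/test beat partitions with per-class bookkeeping."""

    train: list
    test: list
    per_class_train: dict
    per_class_test: dict
    seed: int
    split_ratio: tuple


# ---------------------------------------------------------------------------
# WFDB reading
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, nsig, fs = head[0], int(head[1]), float(head[2].split("/")[0])
    nsamp = int(head[3]) if len(head) > 3 else None
    signals = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_tok = tok[2] if len(tok) > 2 else "200"
        units = None
        if "/" in gain_tok:
            gain_tok, units = gain_tok.split("/", 1)
        baseline = None
        if "(" in gain_tok:
            gain_tok, base = gain_tok.split("(")
            baseline = int(base.rstrip(")"))
        gain = float(gain_tok) if float(gain_tok) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append({"file": fname, "format": fmt, "gain": gain,
                        "baseline": baseline, "units": units, "description": desc})
    return name, nsig, fs, nsamp, signals


def _read_dat(dat_path: Path, fmt: str, nsig: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == "16":
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int64)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        adc = np.empty(2 * len(b), dtype=np.int64)
        adc[0::2], adc[1::2] = s0, s1
        adc[adc > 2047] -= 4096
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt!r}")
    usable = (len(adc) // nsig) * nsig
    return adc[:usable].reshape(-1, nsig).T  # (C, L)


def _read_annotations(atr_path: Path) -> list:
    raw = atr_path.read_bytes()
    annotations = []
    time = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code, data = word >> 10, word & 0x3FF
        if code == 0 and data == 0:          # EOF
            break
        if code == _SKIP:
            high, low = struct.unpack_from("<hH", raw, i)  # PDP-11 long
            pending_skip += (high << 16) | low
            i += 4
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += data + (data & 1)
        else:
            time += pending_skip + data
            pending_skip = 0
            symbol = _CODE_TO_SYMBOL.get(code)
            if symbol is not None:
                annotations.append((time, symbol))
    return annotations


def read_wfdb_record(path, lead: str | None = None) -> ECGRecord:
    """Read ``<path>.hea`` / ``.dat`` / ``.atr`` into an :class:`ECGRecord`.

    ``path`` is the record path without extension. Signal values are
    converted to physical units via ``(adc - baseline) / gain``. ``lead``
    optionally restricts the record to one named lead.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header file: {hea}")
    _name, nsig, fs, _nsamp, signals = _parse_header(hea)

    dat_files = {}
    for sig in signals:
        dat = base.parent / sig["file"]
        if not dat.exists():
            raise FileNotFoundError(f"missing WFDB signal file: {dat}")
        dat_files.setdefault(dat, sig["format"])
    if len(dat_files) != 1:
        raise ValueError("multi-file signal records are not supported")
    (dat, fmt), = dat_files.items()
    adc = _read_dat(dat, fmt, nsig)
    gains = np.array([s["gain"] for s in signals])
    baselines = np.array([s["baseline"] for s in signals])
    physical = (adc - baselines[:, None]) / gains[:, None]

    atr = base.with_suffix(".atr")
    if not atr.exists():
        raise FileNotFoundError(f"missing WFDB annotation file: {atr}")
    annotations = [(t, s) for t, s in _read_annotations(atr) if t < physical.shape[1]]

    lead_names = [s["description"] for s in signals]
    if lead is not None:
        if lead not in lead_names:
            raise ValueError(f"lead {lead!r} not in record leads {lead_names}")
        idx = lead_names.index(lead)
        physical, lead_names = physical[idx:idx + 1], [lead]
    return ECGRecord(signal=physical, sampling_rate=fs,
                     lead_names=lead_names, annotations=annotations)


# ---------------------------------------------------------------------------
# WFDB writing (fixture support)
# ---------------------------------------------------------------------------


def write_wfdb_record(record: ECGRecord, directory, name: str,
                      gain: float = 200.0, adc_zero: int = 0) -> Path:
    """Write a record as ``.hea``/``.dat`` (format 16) and ``.atr`` files.

    Quantizes to 16-bit ADC units; round-trip error is bounded by
    ``0.5/gain`` per sample. Returns the record base path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / name
    c, length = record.signal.shape

    adc = np.clip(np.round(record.signal * gain + adc_zero), -32768, 32767).astype("<i2")
    base.with_suffix(".dat").write_bytes(adc.T.reshape(-1).tobytes())

    lines = [f"{name} {c} {record.sampling_rate:g} {length}"]
    for i in range(c):
        lines.append(f"{name}.dat 16 {gain:g}({adc_zero})/mV 16 {adc_zero} 0 0 0 "
                     f"{record.lead_names[i]}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")

    out = bytearray()
    prev = 0
    for t, symbol in sorted(record.annotations):
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"unknown annotation symbol {symbol!r}")
        delta = t - prev
        if delta < 0:
            raise ValueError("annotation times must be non-decreasing")
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<hH", delta >> 16, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = t
    out += struct.pack("<H", 0)
    base.with_suffix(".atr").write_bytes(bytes(out))
    return base


# ---------------------------------------------------------------------------
# Segmentation and splitting
# ---------------------------------------------------------------------------


def map_aami(symbol: str):
    """Map one MIT-BIH beat symbol to its AAMI superclass, or None.

    Returns ``None`` for every non-beat annotation (rhythm changes, signal
    quality marks, waveform boundaries, ...): rejection is a value, not an
    error.
    """
    return AAMI_MAPPING.get(symbol)


def segment_beats(record: ECGRecord, window: int = 235,
                  lead: str | None = None, record_id: str | None = None) -> list:
    """Cut one fixed-length window per annotated beat, centered on the R index.

    For the default 235-sample window the beat spans 117 samples before and
    117 after the annotation. Beats whose window would cross a record edge
    are discarded; annotations whose symbol has no AAMI class are skipped.
    Windows are half-open ``[start, start + window)`` on 0-based indices.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if lead is None:
        idx = record.lead_names.index("MLII") if "MLII" in record.lead_names else 0
    else:
        if lead not in record.lead_names:
            raise ValueError(f"lead {lead!r} not in {record.lead_names}")
        idx = record.lead_names.index(lead)
    trace = record.signal[idx]
    pre = (window - 1) // 2
    beats = []
    for t, symbol in record.annotations:
        label = map_aami(symbol)
        if label is None:
            continue
        start = t - pre
        if start < 0 or start + window > trace.shape[0]:
            continue
        beats.append(ECGBeat(samples=trace[None, start:start + window].copy(),
                             label=label,
                             source_id=f"{record_id or 'rec'}:{t}"))
    return beats


def balance_and_split(beats: list, ratio: tuple = (3, 1), n_test: int | None = None,
                      seed: int = 0) -> DatasetSplit:
    """Class-balanced, seeded, disjoint train/test split.

    Classes are undersampled to a common size and split per class at
    ``ratio`` (train:test). When ``n_test`` is given it must divide evenly
    across classes (e.g. 600 test beats over 5 classes = 120 per class), and
    each class must supply ``(ratio_sum / ratio_test) *`` that many beats.
    """
    r_train, r_test = ratio
    if r_train < 1 or r_test < 1:
        raise ValueError("ratio parts must be >= 1")
    by_label: dict = {}
    for b in beats:
        if b.label is None:
            raise ValueError("all beats must be labelled")
        by_label.setdefault(b.label, []).append(b)
    if len(by_label) < 2:
        raise ValueError("need at least two classes to split")
    units = r_train + r_test

    if n_test is not None:
        k = len(by_label)
        if n_test % k:
            raise ValueError(f"n_test={n_test} not divisible by {k} classes")
        test_per_class = n_test // k
        if test_per_class % r_test:
            raise ValueError("per-class test count incompatible with ratio")
        total_per_class = test_per_class // r_test * units
    else:
        smallest = min(len(v) for v in by_label.values())
        total_per_class = (smallest // units) * units
        test_per_class = total_per_class // units * r_test
    if total_per_class < units:
        raise ValueError("too few beats per class for the requested ratio")

    rng = np.random.default_rng(seed)
    train, test = [], []
    per_class_train, per_class_test = {}, {}
    for label in sorted(by_label):
        group = by_label[label]
        if len(group) < total_per_class:
            raise ValueError(
                f"class {label!r} has {len(group)} beats, needs {total_per_class} "
                f"(short by {total_per_class - len(group)})")
        chosen = rng.permutation(len(group))[:total_per_class]
        n_train = total_per_class - test_per_class
        train += [group[i] for i in chosen[:n_train]]
        test += [group[i] for i in chosen[n_train:]]
        per_class_train[label] = n_train
        per_class_test[label] = test_per_class
    return DatasetSplit(train=train, test=test,
                        per_class_train=per_class_train,
                        per_class_test=per_class_test,
                        seed=seed, split_ratio=(r_train, r_test))


# ---------------------------------------------------------------------------
# CSV beat tables
# ---------------------------------------------------------------------------


def beats_to_csv(beats: list, path) -> None:
    """Write single-lead beats as a CSV table: sample_0..sample_{T-1}, label, source_id."""
    rows = []
    for b in beats:
        if b.channels != 1:
            raise ValueError("CSV beat tables hold single-lead beats only")
        row = {f"sample_{i}": v for i, v in enumerate(b.samples[0])}
        row["label"] = b.label
        row["source_id"] = b.source_id
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_beats_csv(path) -> list:
    df = pd.read_csv(path)
    sample_cols = sorted((c for c in df.columns if c.startswith("sample_")),
                         key=lambda c: int(c.split("_")[1]))
    if not sample_cols:
        raise ValueError(f"no sample_* columns in {path}")
    beats = []
    for _, row in df.iterrows():
        label = row.get("label")
        source = row.get("source_id")
        beats.append(ECGBeat(
            samples=row[sample_cols].to_numpy(dtype=np.float64)[None, :],
            label=None if pd.isna(label) else str(label),
            source_id=None if pd.isna(source) else str(source)))
    return beats
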