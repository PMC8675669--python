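"""Reading and writing records in a WFDB-compatible subset.

Implements the standard WFDB layout (text ``.hea`` header, binary ``.dat``
signal, binary ``.atr`` beat annotations) for the cases this package needs:
format-16 signals for writing, formats 16 and 212 for reading, and the MIT
annotation word stream (including SKIP for long intervals and the NUM / SUB /
CHN / AUX modifier words, which are parsed and ignored).  This keeps one
reader path for both synthetic and externally supplied records.

Raw beat symbols are mapped to the four AAMI classes (N, S, V, F); beats
outside those groups (paced, unclassifiable, ...) are dropped with a logged
count.
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from pathlib import Path

import numpy as np

from icawave.records import ECGRecord, Heartbeat

logger = logging.getLogger(__name__)

# MIT annotation type codes <-> beat symbols (the commonly used subset).
MIT_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
SYMBOL_TO_MIT_CODE = {v: k for k, v in MIT_CODE_TO_SYMBOL.items()}

# AAMI EC57 beat grouping.
AAMI_MAP = {
    **{s: "N" for s in ("N", "L", "R", "e", "j")},
    **{s: "S" for s in ("A", "a", "J", "S")},
    **{s: "V" for s in ("V", "E")},
    "F": "F",
}

#: Pacemaker records conventionally excluded from classification studies.
DEFAULT_RECORD_BLOCKLIST = frozenset({"102", "104", "107", "217"})

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

DEFAULT_GAIN = 200.0  # ADC units per millivolt


def write_record(record: ECGRecord, base_path: str | Path, gain: float = DEFAULT_GAIN) -> Path:
    """Write ``record`` as ``base.hea`` / ``base.dat`` (+ ``base.atr``).

    Signals are stored in format 16 (little-endian int16) after quantization
    at ``gain`` ADC units per millivolt.  Returns the header path.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    digital = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    checksum = int(np.asarray(digital, dtype=np.int64).sum() % 65536)
    if checksum >= 32768:
        checksum -= 65536
    first = int(digital[0]) if len(digital) else 0
    header = base.with_suffix(".hea")
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    header.write_text(
        f"{name} 1 {fs_str} {len(digital)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 MLII\n"
    )
    base.with_suffix(".dat").write_bytes(digital.tobytes())
    if record.annotations:
        _write_annotations(base.with_suffix(".atr"), record.annotations)
    return header


def _write_annotations(path: Path, annotations: list[tuple[int, str]]) -> None:
    words = bytearray()
    prev = 0
    for idx, label in sorted(annotations):
        code = SYMBOL_TO_MIT_CODE.get(label)
        if code is None:
            logger.warning("skipping annotation with unknown symbol %r", label)
            continue
        delta = idx - prev
        if delta >= 1024 or delta < 0:
            # SKIP word, then the 32-bit interval (high 16 bits first)
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<H", (delta >> 16) & 0xFFFF)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (code << 10) | (delta & 0x3FF))
        prev = idx
    words += struct.pack("<H", 0)  # end of stream
    path.write_bytes(bytes(words))


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Parse a MIT annotation file into ``(sample_index, symbol)`` pairs."""
    data = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    while i + 1 < len(data):
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(data):
                raise ValueError("truncated SKIP interval in annotation file")
            high = struct.unpack_from("<H", data, i)[0]
            low = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            time += (high << 16) | low
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even length
        else:
            time += interval
            symbol = MIT_CODE_TO_SYMBOL.get(code)
            if symbol is not None:
                out.append((time, symbol))
    return out


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(float)
        usable = (len(flat) // n_sig) * n_sig
        return flat[:usable].reshape(-1, n_sig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        usable = (len(b) // 3) * 3
        b = b[:usable].reshape(-1, 3)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * len(b), dtype=float)
        flat[0::2], flat[1::2] = first, second
        usable = (len(flat) // n_sig) * n_sig
        return flat[:usable].reshape(-1, n_sig)
    raise ValueError(f"unsupported WFDB signal format {fmt}")


def read_record(path: str | Path, keep_unmapped: bool = False) -> ECGRecord:
    """Read a WFDB record, selecting lead MLII when present.

    Annotation symbols are grouped into the AAMI classes; unmapped beats are
    dropped (with a logged count) unless ``keep_unmapped`` is set.
    """
    header = Path(path)
    if header.suffix != ".hea":
        header = header.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(header)
    lines = [
        ln.strip()
        for ln in header.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    if n_sig < 1:
        raise ValueError(f"record {name} declares no signal channels")
    sig_lines = [ln.split() for ln in lines[1 : 1 + n_sig]]

    chan = 0
    for j, fields in enumerate(sig_lines):
        if fields and "MLII" in fields[-1]:
            chan = j
            break
    fields = sig_lines[chan]
    fmt = int(fields[1].split("x")[0].split(":")[0].split("+")[0])
    gain_field = fields[2] if len(fields) > 2 else "200"
    gain_str = gain_field.split("/")[0]
    baseline = 0.0
    if "(" in gain_str:
        gain_str, rest = gain_str.split("(")
        baseline = float(rest.rstrip(")"))
    gain = float(gain_str) or DEFAULT_GAIN
    adc_zero = float(fields[4]) if len(fields) > 4 else 0.0

    dat_path = header.parent / fields[0]
    digital = _read_dat(dat_path, fmt, n_sig)
    samples = (digital[:, chan] - (baseline or adc_zero)) / gain

    annotations: list[tuple[int, str]] = []
    atr = header.with_suffix(".atr")
    if atr.exists():
        raw_anns = read_annotations(atr)
        dropped = 0
        for idx, symbol in raw_anns:
            if idx >= len(samples):
                raise ValueError(
                    f"annotation index {idx} beyond signal end ({len(samples)})"
                )
            mapped = AAMI_MAP.get(symbol)
            if mapped is None and not keep_unmapped:
                dropped += 1
                continue
            annotations.append((idx, mapped if mapped is not None else symbol))
        if dropped:
            logger.warning("%s: dropped %d beats outside the AAMI N/S/V/F groups", name, dropped)
        if not annotations:
            logger.warning("%s: no mappable beat annotations", name)
    return ECGRecord(samples=samples, sampling_rate=fs, annotations=annotations, subject_id=name)


def write_csv(record: ECGRecord, path: str | Path) -> None:
    """Plain-text dump, one ``sample_index,value`` row per sample."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_index", "value"])
        for i, v in enumerate(record.samples):
            w.writerow([i, f"{v:.6f}"])


def write_beats(beats: list[Heartbeat], path: str | Path) -> None:
    """Write segmented beats as CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    if not beats:
        raise ValueError("no beats to write")
    d = beats[0].d
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label", "alpha"] + [f"s{i}" for i in range(d)])
        for b in beats:
            w.writerow([b.subject_id, b.class_label, f"{b.alpha:.6f}"]
                       + [f"{v:.6f}" for v in b.window])
    sidecar = {"d": d, "n_beats": len(beats),
               "classes": sorted({b.class_label for b in beats})}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_beats(path: str | Path) -> list[Heartbeat]:
    """Inverse of :func:`write_beats`."""
    path = Path(path)
    beats = []
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader)
        d = len(header) - 3
        for row in reader:
            window = np.array(row[3:], dtype=float)
            alpha = float(row[2])
            half = d // 2
            r_index = half + round(alpha * half)
            if r_index >= d:
                r_index = d - 1
            beats.append(
                Heartbeat(window=window, r_index=r_index,
                          class_label=row[1], subject_id=row[0])
            )
    return beats
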