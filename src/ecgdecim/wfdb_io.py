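"""Minimal native WFDB codec.

Covers the subset of the WFDB specification needed for single-channel ECG
work with the MIT-BIH / QT corpora and for round-tripping this package's own
records:

* text headers (``.hea``) for single-segment records;
* signal formats ``16`` (little-endian int16, channel-interleaved) and
  ``212`` (packed 12-bit pairs, the MIT-BIH distribution format);
* MIT annotation files (``.atr``) including SKIP/NUM/SUB/CHN/AUX pseudo
  annotations.

Only the fields this package consumes are parsed; everything else in a
header line is ignored. Amplitudes are converted to physical units with
``(adc - baseline) / gain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EcgFormatError

# Annotation code <-> symbol table (beat and non-beat codes).
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True)
class SignalSpec:
    file_name: str
    fmt: str
    gain: float
    baseline: int
    units: str


@dataclass(frozen=True)
class WfdbHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: tuple[SignalSpec, ...]
    base_path: str  # record path without extension


def _strip_extension(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix == ".hea" else path


def read_header(path: str | Path) -> WfdbHeader:
    base = _strip_extension(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise EcgFormatError(f"WFDB header not found: {hea}")
    lines = [
        l.strip() for l in hea.read_text().splitlines()
        if l.strip() and not l.strip().startswith("#")
    ]
    if not lines:
        raise EcgFormatError(f"{hea}: empty header")
    fields = lines[0].split()
    if len(fields) < 2:
        raise EcgFormatError(f"{hea}: malformed record line {lines[0]!r}")
    record_name = fields[0]
    if "/" in record_name:
        raise EcgFormatError(f"{hea}: multi-segment records are not supported")
    try:
        n_sig = int(fields[1])
        fs = float(fields[2].split("/")[0]) if len(fields) > 2 else 250.0
        n_samples = int(fields[3]) if len(fields) > 3 else 0
    except ValueError as exc:
        raise EcgFormatError(f"{hea}: malformed record line {lines[0]!r}") from exc

    signals = []
    for line in lines[1 : 1 + n_sig]:
        parts = line.split()
        if len(parts) < 2:
            raise EcgFormatError(f"{hea}: malformed signal line {line!r}")
        file_name = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, 0, "adu"
        adc_zero = 0
        if len(parts) > 2:
            gain_field = parts[2]
            if "/" in gain_field:
                gain_field, units = gain_field.split("/", 1)
            if "(" in gain_field:
                gain_str, base_str = gain_field.rstrip(")").split("(")
                baseline_explicit: int | None = int(base_str)
                gain = float(gain_str)
            else:
                baseline_explicit = None
                gain = float(gain_field)
            if gain == 0:
                gain = 200.0
            if len(parts) > 4:
                try:
                    adc_zero = int(parts[4])
                except ValueError:
                    adc_zero = 0
            baseline = baseline_explicit if baseline_explicit is not None else adc_zero
        signals.append(SignalSpec(file_name, fmt, gain, baseline, units))
    if len(signals) != n_sig:
        raise EcgFormatError(f"{hea}: expected {n_sig} signal lines")
    return WfdbHeader(
        record_name=record_name,
        n_sig=n_sig,
        fs=fs,
        n_samples=n_samples,
        signals=tuple(signals),
        base_path=str(base),
    )


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    s1 = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    out = np.empty(raw.shape[0] * 2, dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    values = np.asarray(values, dtype=np.int32)
    if np.any((values < -2048) | (values > 2047)):
        raise ValueError("format 212 requires 12-bit samples")
    if values.size % 2:
        values = np.r_[values, 0]
    v = np.where(values < 0, values + 4096, values).reshape(-1, 2)
    b = np.empty((v.shape[0], 3), dtype=np.uint8)
    b[:, 0] = v[:, 0] & 0xFF
    b[:, 1] = ((v[:, 0] >> 8) & 0x0F) | (((v[:, 1] >> 8) & 0x0F) << 4)
    b[:, 2] = v[:, 1] & 0xFF
    return b.tobytes()


def read_signal(header: WfdbHeader, channel: int) -> np.ndarray:
    """Read one channel, converted to physical units (float64)."""
    spec = header.signals[channel]
    dat = Path(header.base_path).parent / spec.file_name
    if not dat.exists():
        raise EcgFormatError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)
    n_total = header.n_samples * header.n_sig if header.n_samples else None
    if spec.fmt == "16":
        adc = raw[: (raw.size // 2) * 2].view("<i2").astype(np.int32)
        if n_total:
            adc = adc[:n_total]
    elif spec.fmt == "212":
        adc = _decode_212(raw, n_total if n_total else (raw.size // 3) * 2)
    else:
        raise EcgFormatError(f"unsupported WFDB signal format {spec.fmt!r}")
    adc = adc.reshape(-1, header.n_sig)[:, channel]
    return (adc.astype(np.float64) - spec.baseline) / spec.gain


def read_annotations(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a MIT-format annotation file -> (sample indices, symbols)."""
    raw = np.fromfile(Path(path), dtype="<u2")
    times: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    while i < raw.size:
        word = int(raw[i])
        code, interval = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 1 >= raw.size:
                raise EcgFormatError(f"{path}: truncated SKIP annotation")
            t += (int(raw[i]) << 16) + int(raw[i + 1])
            i += 2
        elif code == _AUX:
            i += (interval + 1) // 2  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += interval
            times.append(t)
            symbols.append(CODE_TO_SYMBOL.get(code, "?"))
    return np.asarray(times, dtype=np.int64), symbols


def write_annotations(path: str | Path, indices: np.ndarray,
                      symbols: list[str] | tuple[str, ...]) -> None:
    words: list[int] = []
    prev = 0
    for idx, sym in zip(np.asarray(indices, dtype=np.int64), symbols):
        delta = int(idx) - prev
        if delta < 0:
            raise ValueError("annotation indices must be non-decreasing")
        code = SYMBOL_TO_CODE.get(sym, SYMBOL_TO_CODE["?"])
        if delta > 1023:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = int(idx)
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(Path(path))


def write_record(rec, directory: str | Path, fmt: str = "16",
                 gain: float = 200.0, units: str = "mV") -> Path:
    """Write an EcgRecord as ``<record_id>.hea/.dat/.atr`` under directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.record_id
    adc = np.rint(rec.samples * gain).astype(np.int32)
    if fmt == "16":
        if np.any((adc < -32768) | (adc > 32767)):
            raise ValueError("format 16 requires 16-bit samples; lower the gain")
        payload = adc.astype("<i2").tobytes()
        adc_res = 16
    elif fmt == "212":
        payload = _encode_212(adc)
        adc_res = 12
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt!r}")

    dat = directory / f"{name}.dat"
    dat.write_bytes(payload)
    first = int(adc[0]) if adc.size else 0
    hea = directory / f"{name}.hea"
    fs_str = f"{rec.fs:.12g}"
    hea.write_text(
        f"{name} 1 {fs_str} {rec.samples.size}\n"
        f"{name}.dat {fmt} {gain:.12g}(0)/{units} {adc_res} 0 {first} 0 0 ECG\n"
    )
    if rec.beat_indices.size:
        write_annotations(directory / f"{name}.atr", rec.beat_indices,
                          rec.beat_labels)
    return hea
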