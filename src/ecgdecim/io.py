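"""Reading and writing single-lead ECG waveforms and beat annotations.

Two on-disk formats are supported and normalised into :class:`EcgRecord`:

* WFDB records (``.hea`` header + ``.dat`` signal + ``.atr`` annotations),
  the format of the MIT-BIH Arrhythmia and QT databases, via the native
  codec in :mod:`ecgdecim.wfdb_io`;
* plain CSV with one amplitude column (an optional leading time column is
  ignored) plus an optional side-car annotation file with one 0-based
  sample index per line.

All sample indices are 0-based everywhere in the package; amplitudes are in
millivolt when an ADC gain is available and raw units otherwise (the QRS
detector is amplitude-scale invariant, so either works).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EcgFormatError

#: WFDB annotation symbols that mark a beat (normal, ectopic or paced), as
#: opposed to rhythm changes, signal-quality flags or waveform boundaries.
DEFAULT_BEAT_CODES = frozenset(
    {"N", "L", "R", "B", "A", "a", "J", "S", "V", "r", "F", "e", "j", "n",
     "E", "/", "f", "Q", "?"}
)


@dataclass(frozen=True)
class AnnotationFilter:
    """Set of annotation codes counted as true beats."""

    beat_codes: frozenset[str] = DEFAULT_BEAT_CODES

    def __post_init__(self) -> None:
        if not self.beat_codes:
            raise ValueError("AnnotationFilter.beat_codes must be non-empty")

    def apply(
        self, indices: np.ndarray, labels: Sequence[str]
    ) -> tuple[np.ndarray, tuple[str, ...]]:
        keep = [i for i, lab in enumerate(labels) if lab in self.beat_codes]
        return np.asarray(indices)[keep], tuple(labels[i] for i in keep)


@dataclass(frozen=True, eq=False)
class EcgRecord:
    """A uniformly sampled ECG waveform with beat annotations.

    Parameters
    ----------
    record_id:
        Free-form identifier (e.g. the WFDB record name).
    samples:
        Amplitude sequence, float64.
    fs:
        Sampling rate in Hz, > 0.
    beat_indices:
        0-based sample index of each annotated beat, strictly increasing,
        all inside ``[0, len(samples))``.
    beat_labels:
        Annotation code per beat (same length as ``beat_indices``).
    """

    record_id: str
    samples: np.ndarray
    fs: float
    beat_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    beat_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.ascontiguousarray(self.samples, dtype=np.float64)
        idx = np.ascontiguousarray(self.beat_indices, dtype=np.int64)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "beat_indices", idx)
        labels = tuple(self.beat_labels)
        if not labels and idx.size:
            labels = ("N",) * idx.size
        object.__setattr__(self, "beat_labels", labels)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if len(labels) != idx.size:
            raise ValueError("beat_labels and beat_indices must have equal length")
        if idx.size:
            if np.any(np.diff(idx) <= 0):
                raise ValueError("beat_indices must be strictly increasing")
            if idx[0] < 0 or idx[-1] >= samples.size:
                raise ValueError("beat_indices must lie within [0, len(samples))")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with ``samples`` replaced (annotations kept)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


# ---------------------------------------------------------------------------
# CSV

def _parse_fs_header(lines: list[str]) -> float | None:
    for line in lines:
        if line.startswith("#") and "fs=" in line:
            try:
                return float(line.split("fs=")[1].split()[0].split(",")[0])
            except (IndexError, ValueError):
                return None
    return None


def read_csv(path: str | Path, fs: float | None = None,
             ann_path: str | Path | None = None,
             record_id: str | None = None) -> EcgRecord:
    """Read an ECG waveform from CSV.

    The file may carry a ``# fs=<Hz>`` comment header (used when ``fs`` is
    None) and one or two numeric columns; with two columns the first is
    treated as time and discarded.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    header_fs = _parse_fs_header(raw_lines[:5])
    if fs is None:
        fs = header_fs
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no '# fs=' header")

    values: list[float] = []
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.replace(",", " ").split()
        try:
            row = [float(f) for f in fields]
        except ValueError:
            raise EcgFormatError(f"{path}:{lineno}: non-numeric row {stripped!r}")
        values.append(row[-1])

    samples = np.asarray(values, dtype=np.float64)
    beat_indices = np.array([], dtype=np.int64)
    if ann_path is not None:
        beat_indices = read_annotation_list(ann_path, n_samples=samples.size)
    return EcgRecord(
        record_id=record_id or path.stem,
        samples=samples,
        fs=float(fs),
        beat_indices=beat_indices,
        beat_labels=("N",) * beat_indices.size,
    )


def read_annotation_list(path: str | Path, n_samples: int | None = None) -> np.ndarray:
    """Read one 0-based beat index per line; validates range when given."""
    path = Path(path)
    idx: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            idx.append(int(stripped))
        except ValueError:
            raise EcgFormatError(f"{path}:{lineno}: non-integer index {stripped!r}")
    arr = np.asarray(idx, dtype=np.int64)
    if n_samples is not None and arr.size and (arr.min() < 0 or arr.max() >= n_samples):
        raise ValueError(
            f"{path}: annotation index out of range [0, {n_samples})"
        )
    return arr


def write_csv(rec: EcgRecord, path: str | Path,
              ann_path: str | Path | None = None) -> None:
    """Write samples as CSV with a ``# fs=`` header at full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs:.17g}\n")
        for v in rec.samples:
            fh.write(f"{v:.17g}\n")
    if ann_path is not None:
        with Path(ann_path).open("w") as fh:
            for i in rec.beat_indices:
                fh.write(f"{int(i)}\n")


# ---------------------------------------------------------------------------
# Compressed-signal CSV (fs_out plus (B, K) provenance in header comments)

def write_compressed(sig, path: str | Path) -> None:
    """Write a :class:`~ecgdecim.compress.CompressedSignal` as annotated CSV.

    Header comments carry the output rate and the (B, K, fs_in, n_in)
    provenance so the file round-trips through :func:`read_compressed`.
    """
    samples = np.asarray(sig.samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("refusing to write an empty compressed signal")
    path = Path(path)
    spec = sig.spec
    with path.open("w") as fh:
        fh.write(f"# fs={sig.fs_out:.17g}\n")
        fh.write(f"# B={spec.B:.17g} K={spec.K:.17g} fs_in={spec.fs_in:.17g} "
                 f"n_in={sig.n_in}\n")
        for v in samples:
            fh.write(f"{v:.17g}\n")


def read_compressed(path: str | Path):
    """Read a compressed-signal CSV written by :func:`write_compressed`."""
    from .compress import CompressedSignal, ResampleSpec

    path = Path(path)
    lines = path.read_text().splitlines()
    fs_out = _parse_fs_header(lines[:2])
    meta: dict[str, float] = {}
    for line in lines[:3]:
        if line.startswith("#") and "B=" in line:
            for tok in line.lstrip("# ").split():
                key, _, val = tok.partition("=")
                meta[key] = float(val)
    if fs_out is None or not {"B", "K", "fs_in", "n_in"} <= meta.keys():
        raise EcgFormatError(f"{path}: missing compressed-signal metadata header")
    values = [float(l) for l in lines if l.strip() and not l.startswith("#")]
    spec = ResampleSpec.create(fs_in=meta["fs_in"], B=meta["B"], K=meta["K"])
    return CompressedSignal(
        samples=np.asarray(values, dtype=np.float64),
        fs_out=float(fs_out),
        spec=spec,
        filter=None,
        n_in=int(meta["n_in"]),
    )


# ---------------------------------------------------------------------------
# WFDB (delegates to the native codec)

def read_wfdb(path: str | Path, channel: int = 0,
              ann_ext: str = "atr",
              beat_filter: AnnotationFilter | None = None) -> EcgRecord:
    """Read a WFDB record (header path or record path without extension).

    Annotations are filtered to beat-type codes by ``beat_filter``
    (default: the standard beat family); out-of-range indices are dropped.
    """
    from . import wfdb_io

    beat_filter = beat_filter or AnnotationFilter()
    header = wfdb_io.read_header(path)
    if not 0 <= channel < header.n_sig:
        raise ValueError(
            f"channel {channel} out of range for {header.record_name} "
            f"({header.n_sig} signals)"
        )
    signal = wfdb_io.read_signal(header, channel)
    ann_file = Path(header.base_path).with_suffix("." + ann_ext)
    indices = np.array([], dtype=np.int64)
    labels: tuple[str, ...] = ()
    if ann_file.exists():
        raw_idx, raw_lab = wfdb_io.read_annotations(ann_file)
        in_range = (raw_idx >= 0) & (raw_idx < signal.size)
        raw_idx, raw_lab = raw_idx[in_range], [
            l for l, ok in zip(raw_lab, in_range) if ok
        ]
        indices, labels = beat_filter.apply(raw_idx, raw_lab)
    return EcgRecord(
        record_id=header.record_name,
        samples=signal,
        fs=header.fs,
        beat_indices=indices,
        beat_labels=labels,
    )


def write_wfdb(rec: EcgRecord, directory: str | Path, fmt: str = "16",
               gain: float = 200.0, units: str = "mV") -> Path:
    """Write the record as a WFDB header/signal/annotation triple.

    Returns the header path. Samples are digitised with ``gain`` ADC units
    per physical unit, so the analog round-trip is exact to 1/(2*gain).
    """
    from . import wfdb_io

    return wfdb_io.write_record(rec, directory, fmt=fmt, gain=gain, units=units)
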