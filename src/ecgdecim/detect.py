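"""TERMA QRS detection (two event-related moving averages).

The detector runs in four stages on a (possibly compressed) single-lead
ECG:

1. *Filtering*: third-order Butterworth bandpass between ``f1`` and ``f2``
   (defaults 8 and 20 Hz, the band where QRS energy concentrates), applied
   forward-backward so blocks stay centred on the R peaks.
2. *Enhancing*: element-wise squaring.
3. *Block generation*: two centred moving averages of the squared signal —
   a short event window ``w1_s`` (97 ms, about one QRS width) and a long
   cycle window ``w2_s`` (611 ms, about one heart cycle).
4. *Thresholding*: candidate blocks are maximal runs where the event
   average exceeds the cycle average plus a rejection offset
   ``beta * beta_scale * mean(squared)``; blocks narrower than the event
   window are rejected and each surviving block contributes one R peak at
   the argmax of the absolute filtered signal.

The rejection weight ``beta`` is the dimensionless percentage of the
signal's mean squared energy (``beta_scale = 0.01`` turns the published
``beta = 8`` into an 8% offset); ``beta_scale`` is the tuning hook if a
different scaling convention is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermaParams:
    f1: float = 8.0
    f2: float = 20.0
    filter_order: int = 3
    w1_s: float = 0.097
    w2_s: float = 0.611
    beta: float = 8.0
    beta_scale: float = 0.01
    causal: bool = False  # single-pass filtering for streaming parity

    def __post_init__(self) -> None:
        if not 0 < self.f1 < self.f2:
            raise ValueError("need 0 < f1 < f2")
        if not self.w1_s < self.w2_s:
            raise ValueError("need w1_s < w2_s")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


DEFAULT_QRS_PARAMS = TermaParams()


@dataclass(frozen=True, eq=False)
class TermaTrace:
    filtered: np.ndarray
    squared: np.ndarray
    ma_event: np.ndarray
    ma_cycle: np.ndarray
    threshold: np.ndarray
    blocks: tuple[tuple[int, int], ...]  # half-open [start, end)


@dataclass(frozen=True, eq=False)
class DetectionResult:
    r_indices: np.ndarray
    fs: float
    trace: TermaTrace | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.r_indices, dtype=np.int64)
        object.__setattr__(self, "r_indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("r_indices must be strictly increasing")

    def map_indices(self, fs_target: float) -> np.ndarray:
        """Map detected indices to another sampling rate: round(i*fs'/fs)."""
        return np.rint(self.r_indices * (fs_target / self.fs)).astype(np.int64)


def window_samples(window_s: float, fs: float, minimum: int = 3) -> int:
    """Nearest odd sample count for a window duration (floor at ``minimum``)."""
    w = window_s * fs
    odd = 2 * int(round((w - 1) / 2.0)) + 1
    return max(minimum, odd)


def bandpass(samples: np.ndarray, fs: float, p: TermaParams = DEFAULT_QRS_PARAMS
             ) -> np.ndarray:
    """Butterworth bandpass; zero-phase (forward-backward) unless causal."""
    if p.f2 >= fs / 2.0:
        raise ValueError(
            f"f2={p.f2} Hz requires a sampling rate above {2 * p.f2} Hz, got {fs}"
        )
    sos = sps.butter(p.filter_order, [p.f1, p.f2], btype="bandpass",
                     fs=fs, output="sos")
    x = np.asarray(samples, dtype=np.float64)
    if p.causal:
        return sps.sosfilt(sos, x)
    return sps.sosfiltfilt(sos, x)


def enhance(filtered: np.ndarray) -> np.ndarray:
    """Point-wise energy: the squared bandpassed signal."""
    x = np.asarray(filtered, dtype=np.float64)
    return x * x


def moving_average(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centred moving mean with shrinking windows at the edges.

    The window is the nearest odd number of samples to ``window_s * fs``
    (minimum 3); output has the same length as the input.
    """
    x = np.asarray(x, dtype=np.float64)
    w = window_samples(window_s, fs)
    if w > x.size:
        raise DegenerateSignalError(
            f"moving-average window of {w} samples exceeds signal length {x.size}"
        )
    half = w // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(x.size)
    lo = np.maximum(0, i - half)
    hi = np.minimum(x.size, i + half + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def _blocks_from_energy(energy: np.ndarray, fs: float, p: TermaParams
                        ) -> tuple[tuple[tuple[int, int], ...], np.ndarray,
                                   np.ndarray, np.ndarray]:
    """Stages 3-4 on an energy trace: moving averages, threshold, blocks."""
    ma_event = moving_average(energy, p.w1_s, fs)
    ma_cycle = moving_average(energy, p.w2_s, fs)
    offset = p.beta * p.beta_scale * float(energy.mean())
    threshold = ma_cycle + offset
    active = ma_event > threshold
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    starts, ends = edges[0::2], edges[1::2]
    min_width = window_samples(p.w1_s, fs)
    blocks = tuple(
        (int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_width
    )
    return blocks, ma_event, ma_cycle, threshold


def detect(rec_or_sig, p: TermaParams = DEFAULT_QRS_PARAMS,
           keep_trace: bool = False) -> DetectionResult:
    """Run the full TERMA detector on an EcgRecord or CompressedSignal.

    Returns indices at the analysed rate (``.fs`` of the input object); use
    :meth:`DetectionResult.map_indices` to express them at another rate.
    A flat (zero-variance) signal yields an empty result with a warning.
    """
    samples = np.asarray(rec_or_sig.samples, dtype=np.float64)
    fs = float(rec_or_sig.fs)
    if samples.size <= window_samples(p.w2_s, fs):
        raise DegenerateSignalError(
            "signal shorter than the cycle moving-average window"
        )
    if samples.size == 0 or float(np.ptp(samples)) == 0.0:
        logger.warning("flat signal: no QRS detection possible")
        return DetectionResult(r_indices=np.array([], dtype=np.int64), fs=fs)

    filtered = bandpass(samples, fs, p)
    squared = enhance(filtered)
    blocks, ma_event, ma_cycle, threshold = _blocks_from_energy(squared, fs, p)
    abs_filtered = np.abs(filtered)
    r_indices = np.asarray(
        [s + int(np.argmax(abs_filtered[s:e])) for s, e in blocks], dtype=np.int64
    )
    trace = None
    if keep_trace:
        trace = TermaTrace(filtered=filtered, squared=squared,
                           ma_event=ma_event, ma_cycle=ma_cycle,
                           threshold=threshold, blocks=blocks)
    return DetectionResult(r_indices=r_indices, fs=fs, trace=trace)
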