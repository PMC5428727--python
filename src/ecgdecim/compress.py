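"""Lossy ECG compression by rational sampling-rate conversion.

The compressor lowers the sampling rate of an ECG record from ``fs_in`` to
an effective target rate ``K`` through an intermediate interpolation rate
``B``: conceptually the signal is zero-stuffed up to a common design grid,
passed through a single linear-phase low-pass FIR that acts simultaneously
as anti-imaging filter for the interpolator and anti-aliasing filter for
the decimator (passband gain equal to the upsampling factor, cutoff at the
smallest Nyquist frequency involved), and then downsampled. The common grid
is the least common multiple of ``fs_in``, ``B`` and ``K``, so the choice
of ``B`` shapes the realized filter even though the output rate is always
``K``. With equal per-sample bit widths the bit compression ratio is
``fs_in / K`` (e.g. 360 Hz -> 80 Hz gives 4.5).

The fast path uses :func:`scipy.signal.upfirdn`; an intentionally literal
three-step reference (zero-stuff, convolve, downsample) is provided for
verification and must agree to 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError
from .io import EcgRecord


def _as_fraction(x: float | int) -> Fraction:
    # Rates are given in Hz, typically integers; repr keeps e.g. 128.125 exact.
    return Fraction(repr(float(x))) if not float(x).is_integer() else Fraction(int(x))


@dataclass(frozen=True)
class ResampleSpec:
    """Rational conversion of ``fs_in`` to effective rate ``K`` via grid ``B``.

    ``up_factor``/``down_factor`` are the gcd-reduced integers realizing
    ``fs_in * up / down == K`` exactly; ``B`` only influences the design
    grid of the combined low-pass filter.
    """

    B: float
    K: float
    fs_in: float
    up_factor: int
    down_factor: int

    @classmethod
    def create(cls, fs_in: float, B: float, K: float,
               k_floor: float | None = 50.0) -> "ResampleSpec":
        if fs_in <= 0 or B <= 0 or K <= 0:
            raise ValueError("rates must be positive")
        if K > B:
            raise ValueError(f"K={K} must not exceed B={B}")
        if k_floor is not None and K < k_floor:
            raise ValueError(
                f"K={K} Hz below the configured floor of {k_floor} Hz "
                "(pass k_floor=None to disable)"
            )
        ratio = _as_fraction(K) / _as_fraction(fs_in)
        return cls(B=float(B), K=float(K), fs_in=float(fs_in),
                   up_factor=ratio.numerator, down_factor=ratio.denominator)

    @property
    def is_identity(self) -> bool:
        return self.up_factor == self.down_factor == 1

    @property
    def design_grid_hz(self) -> float:
        """lcm(fs_in, B, K) as an exact rational rate, in Hz."""
        fracs = [_as_fraction(self.fs_in), _as_fraction(self.B), _as_fraction(self.K)]
        den = math.lcm(*(f.denominator for f in fracs))
        ints = [int(f * den) for f in fracs]
        return math.lcm(*ints) / den

    def grid_factors(self) -> tuple[int, int]:
        """(up, down) realizing fs_in -> K on the B-inclusive design grid."""
        grid = self.design_grid_hz
        up = round(grid / self.fs_in)
        down = round(grid / self.K)
        return up, down

    def inverted(self) -> "ResampleSpec":
        """Spec for the reverse conversion K -> fs_in (same design grid)."""
        return ResampleSpec(B=self.B, K=self.fs_in, fs_in=self.K,
                            up_factor=self.down_factor,
                            down_factor=self.up_factor)


@dataclass(frozen=True, eq=False)
class FilterSpec:
    """Linear-phase FIR realizing the combined ideal low-pass response."""

    taps: np.ndarray
    gain: float                 # passband gain = upsampling factor on the grid
    cutoff: float               # normalized angular cutoff on the design grid
    transition_width: float     # normalized angular transition width
    stopband_atten_db: float
    up: int = 1                 # grid factors actually applied
    down: int = 1

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        object.__setattr__(self, "taps", taps)
        if not np.allclose(taps, taps[::-1], atol=1e-12 * max(1.0, self.gain)):
            raise ValueError("filter taps must be symmetric (linear phase)")
        dc = taps.sum()
        if abs(dc - self.gain) > 1e-6 * abs(self.gain):
            raise ValueError("DC response must equal the passband gain")


@dataclass(frozen=True, eq=False)
class CompressedSignal:
    """Decimated waveform plus the provenance needed to reconstruct."""

    samples: np.ndarray
    fs_out: float
    spec: ResampleSpec
    filter: FilterSpec | None
    n_in: int

    @property
    def fs(self) -> float:
        return self.fs_out

    @property
    def n(self) -> int:
        return np.asarray(self.samples).size


@dataclass(frozen=True, eq=False)
class ResampleTrace:
    """Intermediate signals of the literal interpolate/filter/decimate chain."""

    J: np.ndarray  # zero-stuffed signal on the design grid
    P: np.ndarray  # filtered grid signal


# ---------------------------------------------------------------------------
# Filter design

def design_filter(spec: ResampleSpec, stopband_atten_db: float = 60.0,
                  taps_hint: int | None = None) -> FilterSpec:
    """Design the combined anti-imaging/anti-aliasing low-pass FIR.

    A Kaiser-windowed sinc with passband gain equal to the grid upsampling
    factor, stopband edge at the smallest Nyquist frequency of the three
    rates involved and a transition band occupying 10% of that cutoff
    (stopband edge at the cutoff, passband edge 10% below it).
    """
    if spec.is_identity:
        return FilterSpec(taps=np.array([1.0]), gain=1.0, cutoff=np.pi,
                          transition_width=0.0,
                          stopband_atten_db=stopband_atten_db, up=1, down=1)
    up, down = spec.grid_factors()
    grid = spec.design_grid_hz
    f_c = min(spec.fs_in, spec.B, spec.K) / 2.0  # Hz; stopband edge
    if f_c <= 0:
        raise ValueError("infeasible resample spec: non-positive cutoff")
    width_hz = 0.1 * f_c
    if taps_hint is not None:
        numtaps = int(taps_hint)
        beta = sps.kaiser_beta(stopband_atten_db)
    else:
        numtaps, beta = sps.kaiserord(stopband_atten_db, width_hz / (grid / 2.0))
    numtaps |= 1  # odd length -> integer group delay, exact symmetry
    taps = sps.firwin(numtaps, (f_c - width_hz / 2.0), window=("kaiser", beta),
                      fs=grid)
    taps = taps * (up / taps.sum())
    return FilterSpec(
        taps=taps,
        gain=float(up),
        cutoff=2.0 * np.pi * f_c / grid,
        transition_width=2.0 * np.pi * width_hz / grid,
        stopband_atten_db=float(stopband_atten_db),
        up=up,
        down=down,
    )


# ---------------------------------------------------------------------------
# Rational resampling core

def _output_length(n_in: int, up: int, down: int) -> int:
    # ceil convention; documented edge rule for the whole package
    return -((-n_in * up) // down)


def rational_resample(x: np.ndarray, taps: np.ndarray, up: int, down: int) -> np.ndarray:
    """Zero-delay rational resampling (fast path, polyphase via upfirdn).

    Output sample ``m`` equals the zero-stuffed-and-filtered grid signal at
    grid index ``m*down + (len(taps)-1)//2``, i.e. the group delay of the
    symmetric FIR is compensated exactly. Output length is
    ``ceil(len(x)*up/down)``.
    """
    x = np.asarray(x, dtype=np.float64)
    taps = np.asarray(taps, dtype=np.float64)
    if taps.size % 2 == 0:
        raise ValueError("taps length must be odd")
    n_out = _output_length(x.size, up, down)
    delay = (taps.size - 1) // 2
    shift = (-delay) % down
    q = (delay + shift) // down
    h = np.concatenate([np.zeros(shift), taps]) if shift else taps
    # upfirdn yields ceil(((n-1)*up + len(h)) / down) samples; zero-pad the
    # tail so indices q .. q+n_out-1 of the compensated output all exist
    need = (q + n_out) * down - h.size
    n_needed = max(x.size, -(-need // up) + 2)
    pad = n_needed - x.size
    y = sps.upfirdn(h, np.concatenate([x, np.zeros(pad)]) if pad else x,
                    up=up, down=down)
    return y[q : q + n_out]


def resample_literal(x: np.ndarray, taps: np.ndarray, up: int, down: int
                     ) -> tuple[np.ndarray, ResampleTrace]:
    """Reference implementation: explicit zero-stuffing, convolution and
    downsampling, sharing only the output-index convention with the fast
    path. Used as the correctness oracle; O(n * len(taps))."""
    x = np.asarray(x, dtype=np.float64)
    taps = np.asarray(taps, dtype=np.float64)
    n_out = _output_length(x.size, up, down)
    J = np.zeros(x.size * up)
    J[::up] = x
    P = np.convolve(J, taps)  # P[r] = sum_l taps[r - l] J[l]
    delay = (taps.size - 1) // 2
    idx = np.arange(n_out) * down + delay
    P_padded = np.concatenate([P, np.zeros(max(0, idx[-1] + 1 - P.size) if n_out else 0)])
    y = P_padded[idx] if n_out else np.array([])
    return y, ResampleTrace(J=J, P=P)


def resample(rec: EcgRecord, spec: ResampleSpec, keep_trace: bool = False,
             stopband_atten_db: float = 60.0,
             filt: FilterSpec | None = None):
    """Compress an ECG record to the effective rate ``K``.

    Returns a :class:`CompressedSignal`, or ``(CompressedSignal,
    ResampleTrace)`` when ``keep_trace`` is set (the trace comes from the
    literal reference path and is intended for inspection/verification).
    """
    if filt is None:
        filt = design_filter(spec, stopband_atten_db=stopband_atten_db)
    x = rec.samples
    if spec.is_identity:
        y = x.copy()
        trace = ResampleTrace(J=x.copy(), P=x.copy())
    else:
        if x.size * filt.up < filt.taps.size:
            raise DegenerateSignalError(
                f"signal of {x.size} samples is shorter than the "
                f"{filt.taps.size}-tap filter on the design grid"
            )
        y = rational_resample(x, filt.taps, filt.up, filt.down)
        trace = None
        if keep_trace:
            _, trace = resample_literal(x, filt.taps, filt.up, filt.down)
    sig = CompressedSignal(samples=y, fs_out=spec.K, spec=spec, filter=filt,
                           n_in=x.size)
    return (sig, trace) if keep_trace else sig


def reconstruct(sig: CompressedSignal, stopband_atten_db: float = 60.0) -> EcgRecord:
    """Resample a compressed signal back to the original rate.

    Uses the same rational machinery with the factors inverted, then trims
    or zero-pads to the original sample count; the result is delay-aligned
    with the original and is the reconstruction used for PRD.
    """
    inv = sig.spec.inverted()
    if inv.is_identity:
        x_hat = np.asarray(sig.samples, dtype=np.float64).copy()
    else:
        filt = design_filter(inv, stopband_atten_db=stopband_atten_db)
        x_hat = rational_resample(np.asarray(sig.samples, dtype=np.float64),
                                  filt.taps, filt.up, filt.down)
    if x_hat.size < sig.n_in:
        x_hat = np.concatenate([x_hat, np.zeros(sig.n_in - x_hat.size)])
    return EcgRecord(record_id="reconstructed", samples=x_hat[: sig.n_in],
                     fs=sig.spec.fs_in)
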