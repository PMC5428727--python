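"""Linear forward-prediction baseline (lossless-compression reference).

A fixed-coefficient linear predictor estimates each sample from its ``m``
predecessors, ``x_hat[n] = sum_k h_k x[n-k]``; the prediction error
``e = x - x_hat`` has low dynamic range except around the steep QRS
deflections, so its magnitude doubles as a QRS marker. For detection the
error magnitude is Savitzky-Golay smoothed (default polynomial order 3,
window 15 samples) and fed through the same block-thresholding stages as
the main TERMA detector.

The predictor here is deliberately fixed-coefficient; an optional
sign-sign LMS adaptation is provided behind
:func:`predict_adaptive` as an extrapolation for experimentation, not as a
reproduction of any published update rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .detect import DEFAULT_QRS_PARAMS, DetectionResult, TermaParams, _blocks_from_energy
from .io import EcgRecord


@dataclass(frozen=True)
class PredictorConfig:
    m: int = 2
    coeffs: tuple[float, ...] = (2.0, -1.0)  # slope predictor
    sg_order: int = 3
    sg_window: int = 15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("prediction order m must be >= 1")
        if len(self.coeffs) != self.m:
            raise ValueError("len(coeffs) must equal m")
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if not self.sg_order < self.sg_window:
            raise ValueError("sg_order must be smaller than sg_window")


@dataclass(frozen=True, eq=False)
class PredictionResult:
    predicted: np.ndarray
    error: np.ndarray


def predict(rec: EcgRecord, cfg: PredictorConfig = PredictorConfig()
            ) -> PredictionResult:
    """Forward-predict each sample from its past ``m`` samples.

    The first ``m`` samples are a warm-up where ``x_hat = x`` (zero error).
    """
    x = rec.samples
    if x.size <= cfg.m:
        raise ValueError(f"signal of {x.size} samples too short for order {cfg.m}")
    predicted = x.copy()
    acc = np.zeros(x.size - cfg.m)
    for k, h in enumerate(cfg.coeffs, start=1):
        acc += h * x[cfg.m - k : x.size - k]
    predicted[cfg.m :] = acc
    return PredictionResult(predicted=predicted, error=x - predicted)


def predict_adaptive(rec: EcgRecord, m: int = 2, mu: float = 1e-3
                     ) -> PredictionResult:
    """Sign-sign LMS variant (experimental extrapolation; see module docs)."""
    x = rec.samples
    if x.size <= m:
        raise ValueError(f"signal of {x.size} samples too short for order {m}")
    h = np.zeros(m)
    predicted = x.copy()
    for n in range(m, x.size):
        past = x[n - 1 :: -1][:m]
        predicted[n] = float(h @ past)
        err = x[n] - predicted[n]
        h += mu * np.sign(err) * np.sign(past)
    return PredictionResult(predicted=predicted, error=x - predicted)


def detect_from_error(res: PredictionResult, fs: float,
                      cfg: PredictorConfig = PredictorConfig(),
                      p: TermaParams = DEFAULT_QRS_PARAMS) -> DetectionResult:
    """Locate QRS complexes from the prediction-error magnitude.

    Smooths ``|e|`` with a Savitzky-Golay filter, squares it and reuses the
    TERMA moving-average block thresholding; one R index per surviving
    block at the argmax of the smoothed magnitude.
    """
    e = np.asarray(res.error, dtype=np.float64)
    if cfg.sg_window >= e.size:
        raise ValueError("sg_window must be smaller than the signal length")
    smooth = savgol_filter(np.abs(e), cfg.sg_window, cfg.sg_order)
    if float(np.ptp(smooth)) == 0.0:
        return DetectionResult(r_indices=np.array([], dtype=np.int64), fs=fs)
    energy = smooth * smooth
    blocks, *_ = _blocks_from_energy(energy, fs, p)
    r_indices = np.asarray(
        [s + int(np.argmax(smooth[s:e_])) for s, e_ in blocks], dtype=np.int64
    )
    return DetectionResult(r_indices=r_indices, fs=fs)
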