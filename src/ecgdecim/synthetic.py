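"""Synthetic single-lead ECG with exact ground-truth R-peak positions.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) at fixed
latencies relative to the R peak; the RR schedule is the nominal heart
period plus truncated Gaussian jitter. The generator reproduces the stress
conditions a compressed-domain QRS detector must survive: tall T waves
(``t_amp`` above ``r_amp``), PVC-like ectopic beats (widened QRS, absent P,
inverted T, compensatory pause) and additive baseline wander plus
broadband noise. Ground-truth ``beat_indices`` are the exact sample
positions of the generated R maxima, which makes every downstream module
testable without any database download.

The single integer ``seed`` governs all randomness (jitter, PVC placement,
noise), so identical specs produce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import EcgRecord

# (latency offset s relative to R, amplitude as fraction of r_amp or
#  absolute for P/T, width sd in s) -- see _beat_waveform
_P_OFFSET, _P_SD = -0.20, 0.022
_Q_OFFSET_FRAC, _QS_AMP_FRAC = -0.5, -0.15   # offsets as fraction of qrs_width_s
_S_OFFSET_FRAC = 0.5
_T_OFFSET, _T_SD = 0.30, 0.050
_EDGE_MARGIN_S = 0.45


@dataclass(frozen=True)
class SyntheticEcgSpec:
    duration_s: float = 60.0
    fs: float = 360.0
    heart_rate_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.0
    r_amp: float = 1.0
    t_amp: float = 0.3
    p_amp: float = 0.15
    qrs_width_s: float = 0.08
    pvc_rate: float = 0.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.pvc_rate <= 1.0:
            raise ValueError("pvc_rate must lie in [0, 1]")
        if self.qrs_width_s * self.fs < 3:
            raise ValueError(
                f"fs={self.fs} Hz gives fewer than 3 samples across a "
                f"{self.qrs_width_s * 1e3:.0f} ms QRS"
            )


def _beat_times(spec: SyntheticEcgSpec, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """RR schedule -> (R times in s, PVC flags)."""
    rr_nominal = 60.0 / spec.heart_rate_bpm
    times: list[float] = []
    is_pvc: list[bool] = []
    t = _EDGE_MARGIN_S
    while t < spec.duration_s - _EDGE_MARGIN_S:
        pvc = bool(times) and rng.random() < spec.pvc_rate
        times.append(t)
        is_pvc.append(pvc)
        jitter = rng.normal(0.0, 1.0) * spec.rr_jitter_sd_s
        jitter = float(np.clip(jitter, -3 * spec.rr_jitter_sd_s,
                               3 * spec.rr_jitter_sd_s))
        rr = max(0.3, rr_nominal + jitter)
        if pvc:
            rr *= 1.5  # compensatory pause after the ectopic beat
        t += rr
    return np.asarray(times), np.asarray(is_pvc, dtype=bool)


def _add_gaussian(sig: np.ndarray, t: np.ndarray, center: float,
                  amp: float, sd: float) -> None:
    lo = np.searchsorted(t, center - 5 * sd)
    hi = np.searchsorted(t, center + 5 * sd)
    seg = t[lo:hi]
    sig[lo:hi] += amp * np.exp(-0.5 * ((seg - center) / sd) ** 2)


def _beat_waveform(sig: np.ndarray, t: np.ndarray, r_time: float,
                   spec: SyntheticEcgSpec, pvc: bool) -> None:
    qrs = spec.qrs_width_s * (2.0 if pvc else 1.0)
    r_sd = qrs / 5.0
    r_amp = spec.r_amp * (1.2 if pvc else 1.0)
    if not pvc:
        _add_gaussian(sig, t, r_time + _P_OFFSET, spec.p_amp, _P_SD)
    _add_gaussian(sig, t, r_time + _Q_OFFSET_FRAC * qrs,
                  _QS_AMP_FRAC * spec.r_amp, qrs / 10.0)
    _add_gaussian(sig, t, r_time, r_amp, r_sd)
    _add_gaussian(sig, t, r_time + _S_OFFSET_FRAC * qrs,
                  _QS_AMP_FRAC * spec.r_amp, qrs / 10.0)
    t_amp = -0.5 * spec.t_amp if pvc else spec.t_amp
    _add_gaussian(sig, t, r_time + _T_OFFSET, t_amp, _T_SD)


def generate(spec: SyntheticEcgSpec) -> EcgRecord:
    """Generate a synthetic record; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    sig = np.zeros(n)
    r_times, pvc_flags = _beat_times(spec, rng)
    for r_time, pvc in zip(r_times, pvc_flags):
        _beat_waveform(sig, t, r_time, spec, pvc)

    # exact ground truth: snap each nominal R sample to the local maximum of
    # the clean signal (the neighbouring P/Q/S/T bumps shift it marginally)
    beat_idx = []
    for r_time in r_times:
        nominal = int(round(r_time * spec.fs))
        lo, hi = max(0, nominal - 3), min(n, nominal + 4)
        beat_idx.append(lo + int(np.argmax(sig[lo:hi])))
    labels = tuple("V" if p else "N" for p in pvc_flags)

    rec = EcgRecord(
        record_id=f"synthetic-{spec.seed}",
        samples=sig,
        fs=spec.fs,
        beat_indices=np.asarray(beat_idx, dtype=np.int64),
        beat_labels=labels,
    )
    if spec.noise_sd > 0 or spec.baseline_wander_amp > 0:
        rec = add_noise(rec, spec.noise_sd, spec.baseline_wander_amp,
                        spec.baseline_wander_freq, seed=spec.seed + 1)
    return rec


def add_noise(rec: EcgRecord, noise_sd: float, wander_amp: float = 0.0,
              wander_freq: float = 0.3, seed: int = 0) -> EcgRecord:
    """Add white Gaussian noise and a sinusoidal baseline wander.

    Annotations are untouched. The white-noise draw is a standard-normal
    sample scaled by ``noise_sd``, so for a fixed seed the perturbation
    grows proportionally with the requested level.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if wander_amp < 0:
        raise ValueError("wander_amp must be >= 0")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    unit_noise = rng.standard_normal(rec.n)
    t = np.arange(rec.n) / rec.fs
    perturbed = (rec.samples
                 + noise_sd * unit_noise
                 + wander_amp * np.sin(2.0 * np.pi * wander_freq * t + phase))
    return rec.with_samples(perturbed)


def tall_t_spec(base: SyntheticEcgSpec | None = None) -> SyntheticEcgSpec:
    """Variant with T waves 1.5x the R amplitude (the classic false-positive
    trap for amplitude-threshold detectors)."""
    base = base or SyntheticEcgSpec()
    return replace(base, t_amp=1.5 * base.r_amp)
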