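"""Ciliary-beat-frequency (CBF) estimation from bead-displacement traces.

Beads resting on a beating ciliated epithelium oscillate at the ciliary beat
frequency; a camera recording at ``fs`` frames per second turns each bead
into a uniformly sampled displacement series. The dominant frequency of that
series, restricted to a physiological band, is the CBF in Hz (beats per
second).

Estimation: linear detrend -> Hann window -> magnitude spectrum (real FFT)
-> dominant in-band peak -> parabolic interpolation over the peak bin and
its two neighbors for sub-bin frequency resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sig

from .errors import NoSignalError, ValidationError

MIN_SAMPLES = 64


@dataclass
class BeadTrace:
    """Uniformly sampled bead displacement (pixels) at ``fs`` frames per second."""

    displacement: np.ndarray
    fs: float
    bead_id: str = "bead"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs: must be > 0, got {self.fs}")
        if self.displacement.ndim != 1:
            raise ValidationError("displacement: must be a 1-D series")
        if len(self.displacement) < MIN_SAMPLES:
            raise ValidationError(
                f"displacement: need >= {MIN_SAMPLES} samples, got {len(self.displacement)}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValidationError(
                "displacement: missing/non-finite samples; interpolate gaps first"
            )

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass
class CBFEstimate:
    """Dominant beat frequency of one trace.

    ``power_fraction`` is the share of in-band spectral power carried by the
    dominant bin; ``resolution`` is the FFT bin width fs/N in Hz.
    ``harmonic_flag`` marks traces whose first harmonic (2x bin) carries more
    than half the dominant power.
    """

    bead_id: str
    frequency: float
    power_fraction: float
    resolution: float
    harmonic_flag: bool = False


def estimate_cbf(
    trace: BeadTrace,
    band: tuple[float, float] = (2.0, 40.0),
    detrend: Literal["mean", "linear"] = "linear",
    window: Literal["none", "hann"] = "hann",
) -> CBFEstimate:
    """Estimate the dominant in-band frequency of one bead trace.

    Raises :class:`NoSignalError` for traces that are constant (or a pure
    ramp under linear detrending) and :class:`ValidationError` if the band
    is empty after clipping at Nyquist.
    """
    lo, hi = band
    nyquist = trace.fs / 2.0
    if not 0.0 <= lo < hi:
        raise ValidationError(f"band: need 0 <= low < high, got {band}")
    if hi >= nyquist:
        raise ValidationError(f"band: high edge {hi} Hz must be below Nyquist ({nyquist} Hz)")

    x = sig.detrend(trace.displacement, type="constant" if detrend == "mean" else "linear")
    if np.allclose(x, 0.0, atol=1e-12 * max(1.0, np.abs(trace.displacement).max())):
        raise NoSignalError(f"trace {trace.bead_id!r}: zero variance after detrending")
    if window == "hann":
        x = x * np.hanning(len(x))

    n = len(x)
    spectrum = np.abs(np.fft.rfft(x))
    power = spectrum ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.fs)
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValidationError(f"band: no FFT bin falls inside {band} at resolution fs/N")

    band_idx = np.flatnonzero(in_band)
    k = band_idx[np.argmax(power[band_idx])]

    # parabolic interpolation over (k-1, k, k+1) magnitudes
    freq = freqs[k]
    if 0 < k < len(spectrum) - 1:
        a, b, c = spectrum[k - 1], spectrum[k], spectrum[k + 1]
        denom = a - 2.0 * b + c
        if denom != 0.0:
            delta = 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            freq = freqs[k] + delta * trace.fs / n
    freq = float(np.clip(freq, lo, hi))

    band_power = float(power[band_idx].sum())
    power_fraction = float(power[k] / band_power)

    harmonic_flag = False
    k2 = 2 * k
    if k2 < len(power) and power[k2] > 0.5 * power[k]:
        harmonic_flag = True

    return CBFEstimate(
        bead_id=trace.bead_id,
        frequency=freq,
        power_fraction=power_fraction,
        resolution=trace.fs / n,
        harmonic_flag=harmonic_flag,
    )


def batch_cbf(
    traces: Sequence[BeadTrace],
    band: tuple[float, float] = (2.0, 40.0),
    detrend: Literal["mean", "linear"] = "linear",
    window: Literal["none", "hann"] = "hann",
) -> tuple[list[CBFEstimate], list[tuple[str, str]], dict]:
    """Estimate CBF for a batch of traces.

    Returns (estimates, failures, summary); failures are (bead_id, reason)
    pairs and the summary (n, mean, sd in Hz) covers successes only, with sd
    missing (None) when fewer than two traces succeeded. Raises if every
    trace fails or the batch is empty.
    """
    if len(traces) == 0:
        raise ValidationError("traces: need at least one trace")
    estimates: list[CBFEstimate] = []
    failures: list[tuple[str, str]] = []
    for tr in traces:
        try:
            estimates.append(estimate_cbf(tr, band=band, detrend=detrend, window=window))
        except (NoSignalError, ValidationError) as exc:
            failures.append((tr.bead_id, str(exc)))
    if not estimates:
        raise NoSignalError(f"all {len(traces)} traces failed: {failures[:3]}")
    freqs = np.array([e.frequency for e in estimates])
    summary = {
        "n": int(len(freqs)),
        "mean_hz": float(freqs.mean()),
        "sd_hz": float(freqs.std(ddof=1)) if len(freqs) > 1 else None,
    }
    return estimates, failures, summary
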