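"""Slice-selective RF excitation pulses.

The excitation pulse is represented in the hard-pulse approximation: a train
of short rectangular sub-pulses, each described by a nutation frequency
amplitude (gamma*B1/2pi, in Hz) and a phase (radians).  All pulse shaping is
done on the amplitude waveform; the overall amplitude scale is calibrated so
that the on-resonance hard-pulse flip angle (360 deg * integral of the
nutation frequency over time) equals the pulse's nominal flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RFPulse", "make_hws_pulse", "measure_fwhm", "save_pulse_txt", "load_pulse_txt"]


@dataclass(frozen=True)
class RFPulse:
    """Discretized slice-selective RF pulse.

    Parameters
    ----------
    time_step : float
        Duration of each hard-pulse sample, ms.
    amplitudes : ndarray
        Nutation frequency per sample, Hz (gamma*B1/2pi).
    phases : ndarray
        RF phase per sample, radians.
    nominal_flip : float
        On-resonance hard-pulse flip angle the amplitude scale is calibrated
        to, degrees.
    """

    time_step: float
    amplitudes: np.ndarray
    phases: np.ndarray
    nominal_flip: float = 90.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=float)
        ph = np.asarray(self.phases, dtype=float)
        if amp.ndim != 1 or amp.shape != ph.shape:
            raise ValueError("amplitudes and phases must be 1-D arrays of equal length")
        if not np.all(np.isfinite(amp)) or not np.all(np.isfinite(ph)):
            raise ValueError("pulse samples must be finite")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "phases", ph)

    @property
    def n_samples(self) -> int:
        return self.amplitudes.size

    @property
    def duration(self) -> float:
        """Total pulse duration, ms."""
        return self.n_samples * self.time_step

    @property
    def flip_integral_deg(self) -> float:
        """On-resonance hard-pulse flip angle, degrees."""
        return 360.0 * np.sum(self.amplitudes) * self.time_step * 1e-3

    def scaled_to(self, flip_deg: float) -> "RFPulse":
        """Return a copy with amplitudes rescaled to the given on-resonance flip."""
        factor = flip_deg / self.flip_integral_deg
        return RFPulse(self.time_step, self.amplitudes * factor, self.phases,
                       nominal_flip=flip_deg, meta=dict(self.meta))


def _hws_envelope(tau: np.ndarray, tbw: float) -> np.ndarray:
    # tau in [-1/2, 1/2]; Hamming apodization over the full window
    x = tbw * tau
    return np.sinc(x) * (0.54 + 0.46 * np.cos(2.0 * np.pi * tau))


def measure_fwhm(t: np.ndarray, w: np.ndarray) -> float:
    """Full width at half maximum of the main lobe of waveform ``w(t)``.

    Half-max crossings adjacent to the global peak are located by linear
    interpolation between samples.
    """
    w = np.asarray(w, float)
    ipk = int(np.argmax(w))
    half = w[ipk] / 2.0
    # walk left
    i = ipk
    while i > 0 and w[i - 1] >= half:
        i -= 1
    if i == 0:
        raise ValueError("main lobe does not fall below half maximum on the left")
    tl = t[i - 1] + (t[i] - t[i - 1]) * (half - w[i - 1]) / (w[i] - w[i - 1])
    # walk right
    j = ipk
    n = w.size
    while j < n - 1 and w[j + 1] >= half:
        j += 1
    if j == n - 1:
        raise ValueError("main lobe does not fall below half maximum on the right")
    tr = t[j] + (t[j + 1] - t[j]) * (half - w[j]) / (w[j + 1] - w[j])
    return float(tr - tl)


def make_hws_pulse(duration: float, fwhm_target: float, n_samples: int = 512,
                   nominal_flip: float = 90.0) -> RFPulse:
    """Construct a Hamming-windowed sinc excitation pulse.

    The sinc time-bandwidth parameter is found by bisection so that the
    measured FWHM of the amplitude main lobe equals ``fwhm_target`` (ms)
    within one time sample.  The waveform is symmetric about the pulse
    center and scaled so the on-resonance hard-pulse flip equals
    ``nominal_flip`` degrees.

    Parameters
    ----------
    duration : float
        Pulse (simulation window) length, ms.
    fwhm_target : float
        Target main-lobe FWHM of the amplitude waveform, ms.
    n_samples : int
        Number of hard-pulse samples (>= 64).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0 < fwhm_target < duration):
        raise ValueError("fwhm_target must lie in (0, duration)")
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")

    dt = duration / n_samples
    # sample centers, tau in (-1/2, 1/2)
    tau = (np.arange(n_samples) + 0.5) / n_samples - 0.5
    t = (tau + 0.5) * duration

    def fwhm_of(tbw: float) -> float:
        return measure_fwhm(t, _hws_envelope(tau, tbw))

    # Larger time-bandwidth -> narrower main lobe.  Bracket the target.
    lo, hi = 1.0, 2.0 * duration / fwhm_target + 8.0
    f_lo, f_hi = fwhm_of(lo), fwhm_of(hi)
    if not (f_hi <= fwhm_target <= f_lo):
        raise ValueError(
            f"fwhm_target={fwhm_target} ms unreachable for duration={duration} ms; "
            f"feasible range is about [{f_hi:.4g}, {f_lo:.4g}] ms")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fwhm_of(mid) > fwhm_target:
            lo = mid
        else:
            hi = mid
    tbw = 0.5 * (lo + hi)

    env = _hws_envelope(tau, tbw)
    # calibrate: 360 deg * sum(amp)*dt[s] == nominal_flip; side lobes carry
    # their sign in the (real) amplitude, phase stays zero
    scale = nominal_flip / (360.0 * np.sum(env) * dt * 1e-3)
    amp = env * scale
    phases = np.zeros_like(amp)
    pulse = RFPulse(dt, amp, phases, nominal_flip=nominal_flip,
                    meta={"shape": "hamming-windowed-sinc", "tbw": float(tbw),
                          "fwhm_ms": float(fwhm_of(tbw)), "duration_ms": float(duration)})
    return pulse


def save_pulse_txt(pulse: RFPulse, path) -> None:
    """Write the pulse as plain text: time (ms), amplitude (Hz), phase (rad)."""
    t = (np.arange(pulse.n_samples) + 0.5) * pulse.time_step
    # signed amplitude reconstructed for readability; phase column kept as-is
    data = np.column_stack([t, pulse.amplitudes, pulse.phases])
    header = (f"nominal_flip_deg={pulse.nominal_flip} time_step_ms={pulse.time_step}\n"
              "time_ms amplitude_hz phase_rad")
    np.savetxt(path, data, header=header)


def load_pulse_txt(path, nominal_flip: float | None = None) -> RFPulse:
    data = np.loadtxt(path)
    t, amp, ph = data[:, 0], data[:, 1], data[:, 2]
    dt = float(np.median(np.diff(t)))
    pulse = RFPulse(dt, amp, ph, nominal_flip=90.0)
    flip = pulse.flip_integral_deg if nominal_flip is None else nominal_flip
    return RFPulse(dt, amp, ph, nominal_flip=flip)
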