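"""Charge-balanced biphasic stimulus waveform calculus.

Conventions
-----------
All amplitudes are peak currents in microamperes (μA), durations in
microseconds (μs) and charges in microcoulombs (μC); 1 μA·μs = 1 pC =
1e-6 μC. Phase envelopes are:

* ``RECT`` — constant at the peak amplitude,
* ``SINE`` — half-sine, ``A·sin(πt/PW)``,
* ``TRI`` — symmetric isosceles triangle peaking at ``PW/2``,
* ``LIN_DEC`` — linearly decaying ramp from the peak to zero.

A full pulse is biphasic and charge balanced: the second phase is the
time-mirrored negative of the first, separated by a zero-current
interphase gap. Polarity defaults to cathodic-first.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DomainError, PrecisionError

__all__ = [
    "PulseShape",
    "PulseTrainSpec",
    "ElectrodeSpec",
    "SampledWaveform",
    "charge_per_phase",
    "equivalent_amplitude",
    "charge_rate",
    "charge_multiplier",
    "teed",
    "sample_pulse",
    "sample_train",
    "write_waveform_csv",
]

PC_PER_UC = 1e6  # picocoulombs per microcoulomb
UC_PER_PC = 1e-6


class PulseShape(enum.Enum):
    """The four accepted single-phase envelopes."""

    RECT = "RECT"
    SINE = "SINE"
    TRI = "TRI"
    LIN_DEC = "LIN_DEC"

    @classmethod
    def coerce(cls, value: "PulseShape | str") -> "PulseShape":
        """Accept a member, its name, or common spellings like ``Lin.Dec.``."""
        if isinstance(value, cls):
            return value
        key = str(value).upper().replace(".", "").replace("-", "_").replace(" ", "")
        aliases = {
            "RECT": cls.RECT,
            "RECTANGULAR": cls.RECT,
            "SINE": cls.SINE,
            "SINUSOIDAL": cls.SINE,
            "TRI": cls.TRI,
            "TRIANGULAR": cls.TRI,
            "LIN_DEC": cls.LIN_DEC,
            "LINDEC": cls.LIN_DEC,
            "SAWTOOTH": cls.LIN_DEC,
        }
        if key not in aliases:
            raise DomainError(f"unknown pulse shape: {value!r}")
        return aliases[key]

    @property
    def display(self) -> str:
        return {"RECT": "Rect", "SINE": "Sine", "TRI": "Tri", "LIN_DEC": "LinDec"}[self.value]


# Fraction of the bounding rectangle A·PW filled by one phase of each shape.
_PHASE_AREA_FRACTION = {
    PulseShape.RECT: 1.0,
    PulseShape.SINE: 2.0 / math.pi,
    PulseShape.TRI: 0.5,
    PulseShape.LIN_DEC: 0.5,
}


@dataclass(frozen=True)
class ElectrodeSpec:
    """Electrode-tissue interface parameters; impedance in ohms."""

    impedance_ohm: float

    def __post_init__(self) -> None:
        if not self.impedance_ohm > 0:
            raise DomainError("electrode impedance must be positive")


@dataclass(frozen=True)
class PulseTrainSpec:
    """One stimulation condition.

    ``amplitude_ua`` is the peak of the first phase, ``pulse_width_us`` the
    per-phase duration, ``interphase_us`` the zero-current gap between the
    two phases.
    """

    shape: PulseShape
    amplitude_ua: float
    pulse_width_us: float
    frequency_hz: float
    interphase_us: float = 0.0
    polarity: str = "cathodic_first"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", PulseShape.coerce(self.shape))
        for name in ("amplitude_ua", "pulse_width_us", "frequency_hz"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.interphase_us < 0:
            raise DomainError("interphase_us must be >= 0")
        if self.polarity not in ("cathodic_first", "anodic_first"):
            raise DomainError(f"unknown polarity: {self.polarity!r}")
        if self.period_us < 2 * self.pulse_width_us + self.interphase_us:
            raise DomainError(
                "pulse does not fit in the period: need 1/f >= 2*PW + interphase"
            )

    @property
    def period_us(self) -> float:
        return 1e6 / self.frequency_hz


@dataclass
class SampledWaveform:
    """A uniformly sampled current waveform (``dt_us`` step, μA samples)."""

    dt_us: float
    samples: np.ndarray = field(repr=False)

    @property
    def net_charge_pc(self) -> float:
        """Signed net charge in pC — ~0 for a charge-balanced pulse."""
        return float(np.sum(self.samples) * self.dt_us)

    @property
    def time_us(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_us

    def phase_charge_pc(self) -> float:
        """Absolute charge in the leading phase, pC (numeric integral)."""
        return float(np.sum(np.abs(self.samples)) * self.dt_us / 2.0)


def charge_per_phase(
    shape: PulseShape | str, amplitude_ua: float, pulse_width_us: float
) -> float:
    """Absolute charge in one phase, in μC.

    The phase envelope has peak ``amplitude_ua`` and base ``pulse_width_us``;
    the integral is the area fraction of the bounding rectangle (1 for RECT,
    2/π for SINE, 1/2 for TRI and LIN_DEC).
    """
    shape = PulseShape.coerce(shape)
    if not amplitude_ua > 0:
        raise DomainError("amplitude must be strictly positive")
    if not pulse_width_us > 0:
        raise DomainError("pulse width must be strictly positive")
    return _PHASE_AREA_FRACTION[shape] * amplitude_ua * pulse_width_us * UC_PER_PC


def equivalent_amplitude(
    shape: PulseShape | str, target_charge_uc: float, pulse_width_us: float
) -> float:
    """Peak amplitude (μA) so one phase of ``shape`` carries ``target_charge_uc``.

    Exact inverse of :func:`charge_per_phase` in the amplitude argument.
    """
    shape = PulseShape.coerce(shape)
    if not target_charge_uc > 0:
        raise DomainError("target charge must be strictly positive")
    if not pulse_width_us > 0:
        raise DomainError("pulse width must be strictly positive")
    return target_charge_uc * PC_PER_UC / (_PHASE_AREA_FRACTION[shape] * pulse_width_us)


def charge_rate(spec: PulseTrainSpec) -> float:
    """Magnitude of injected charge per second, μC/s.

    Both phases of the charge-balanced pulse count, hence the factor 2.
    Linear in amplitude and in frequency.
    """
    return 2.0 * charge_per_phase(spec.shape, spec.amplitude_ua, spec.pulse_width_us) * spec.frequency_hz


def charge_multiplier(
    frequency_hz: float, baseline_frequency_hz: float, truncate_1dp: bool = False
) -> float:
    """Injected-charge ratio of two trains differing only in frequency.

    With amplitude and pulse width held fixed the ratio is ``f / f0``. When
    ``truncate_1dp`` is set the value is truncated (floored) to one decimal,
    e.g. 100/15 = 6.67 → 6.6 and 130/15 = 8.67 → 8.6.
    """
    if not frequency_hz > 0 or not baseline_frequency_hz > 0:
        raise DomainError("frequencies must be strictly positive")
    ratio = frequency_hz / baseline_frequency_hz
    if truncate_1dp:
        return math.floor(ratio * 10.0 + 1e-9) / 10.0
    return ratio


def teed(
    amplitude_ua: float,
    frequency_hz: float,
    pulse_width_us: float,
    electrode: ElectrodeSpec,
) -> float:
    """Total electrical energy delivered per second: ``I²·f·PW / Z``.

    ``I`` is converted to amperes and ``PW`` to seconds before evaluating.

    .. note::
        This is the literature's voltage-era expression applied verbatim to a
        current amplitude: dividing (rather than multiplying) by the
        electrode-tissue impedance ``Z`` is dimensionally odd for a
        current-controlled stimulator, so the result carries units A²·Ω⁻¹·s⁻¹
        scaled by PW rather than watts. It is kept as printed for
        comparability; treat it as a relative index.
    """
    for name, v in (
        ("amplitude", amplitude_ua),
        ("frequency", frequency_hz),
        ("pulse width", pulse_width_us),
    ):
        if not v > 0:
            raise DomainError(f"{name} must be strictly positive")
    i_a = amplitude_ua * 1e-6
    pw_s = pulse_width_us * 1e-6
    return i_a * i_a * frequency_hz * pw_s / electrode.impedance_ohm


def _phase_envelope(shape: PulseShape, amplitude_ua: float, pulse_width_us: float, t_us: np.ndarray) -> np.ndarray:
    """Instantaneous |current| of one phase at times ``t_us`` in [0, PW)."""
    u = t_us / pulse_width_us
    if shape is PulseShape.RECT:
        return np.full_like(u, amplitude_ua)
    if shape is PulseShape.SINE:
        return amplitude_ua * np.sin(np.pi * u)
    if shape is PulseShape.TRI:
        return amplitude_ua * (1.0 - np.abs(2.0 * u - 1.0))
    if shape is PulseShape.LIN_DEC:
        return amplitude_ua * (1.0 - u)
    raise DomainError(f"unknown shape {shape!r}")  # pragma: no cover


def sample_pulse(spec: PulseTrainSpec, dt_us: float) -> SampledWaveform:
    """Sample one biphasic pulse on a uniform ``dt_us`` grid.

    Envelope values are taken at midpoints of each sample bin. The second
    phase is the time-mirrored negative of the first, so the net sampled
    charge is zero to machine precision.
    """
    if not dt_us > 0:
        raise DomainError("dt must be strictly positive")
    if dt_us > spec.pulse_width_us / 10.0:
        raise PrecisionError(
            f"dt={dt_us} μs too coarse: need dt <= pulse_width/10 = "
            f"{spec.pulse_width_us / 10.0} μs"
        )
    n_phase = max(1, int(round(spec.pulse_width_us / dt_us)))
    n_gap = int(round(spec.interphase_us / dt_us))
    mid = (np.arange(n_phase) + 0.5) * dt_us
    first = _phase_envelope(spec.shape, spec.amplitude_ua, spec.pulse_width_us, mid)
    sign = -1.0 if spec.polarity == "cathodic_first" else 1.0
    samples = np.concatenate(
        [sign * first, np.zeros(n_gap), -sign * first[::-1]]
    )
    return SampledWaveform(dt_us=dt_us, samples=samples)


def sample_train(spec: PulseTrainSpec, dt_us: float, duration_us: float) -> SampledWaveform:
    """Sample a periodic pulse train for ``duration_us`` (pulse at each period start)."""
    pulse = sample_pulse(spec, dt_us)
    n_total = int(round(duration_us / dt_us))
    out = np.zeros(n_total)
    stride = spec.period_us / dt_us
    k = 0
    while True:
        start = int(round(k * stride))
        if start >= n_total:
            break
        stop = min(start + pulse.samples.size, n_total)
        out[start:stop] = pulse.samples[: stop - start]
        k += 1
    return SampledWaveform(dt_us=dt_us, samples=out)


def write_waveform_csv(path, waveform: SampledWaveform) -> None:
    """Write ``time_us,current_uA`` columns for a sampled waveform."""
    import pandas as pd

    pd.DataFrame(
        {"time_us": waveform.time_us, "current_uA": waveform.samples}
    ).to_csv(path, index=False)
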