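"""Session timelines for the three stimulation paradigms.

A session is an alternating sequence of DBS-on episodes and off periods,
with the time origin ``t = 0`` at the onset of the first episode and the
session ending at the offset of the last one. Episode windows are half-open
intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import yaml

from .errors import DomainError
from .waveforms import PulseShape, PulseTrainSpec, charge_per_phase, equivalent_amplitude

__all__ = [
    "StimulationEpisode",
    "SessionProtocol",
    "AMPLITUDE_MULTIPLIERS",
    "FREQUENCY_LEVELS_HZ",
    "CHARGE_MULTIPLIERS",
    "WAVEFORM_SHAPE_ORDER",
    "build_amplitude_protocol",
    "build_frequency_protocol",
    "build_waveform_protocol",
    "episode_windows",
    "save_protocol",
    "load_protocol",
]

AMPLITUDE_MULTIPLIERS = (1.0, 1.25, 1.5, 1.75, 2.0)
FREQUENCY_LEVELS_HZ = (15.0, 50.0, 100.0, 130.0, 180.0, 250.0, 350.0)
CHARGE_MULTIPLIERS = (1.0, 1.25, 1.5, 1.75, 2.0)
WAVEFORM_SHAPE_ORDER = (PulseShape.RECT, PulseShape.SINE, PulseShape.TRI, PulseShape.LIN_DEC)

OFF_LABEL = "off"


@dataclass(frozen=True)
class StimulationEpisode:
    """One timeline segment; ``train is None`` marks an off period."""

    start_s: float
    duration_s: float
    label: str
    train: PulseTrainSpec | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise DomainError("episode duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def is_on(self) -> bool:
        return self.train is not None


@dataclass
class SessionProtocol:
    """Ordered, non-overlapping ON/OFF timeline for one paradigm."""

    episodes: list[StimulationEpisode]
    paradigm: str
    I0_ua: float | None = None
    Q0_uc: float | None = None

    def __post_init__(self) -> None:
        if not self.episodes:
            raise DomainError("protocol has no episodes")
        if not self.episodes[0].is_on:
            raise DomainError("protocol must begin with an ON episode")
        prev_end = None
        prev_on = None
        for ep in self.episodes:
            if prev_end is not None:
                if ep.start_s < prev_end - 1e-9:
                    raise DomainError("episodes overlap or are unordered")
                if ep.is_on == prev_on:
                    raise DomainError("episodes must alternate ON/OFF")
            prev_end, prev_on = ep.end_s, ep.is_on

    @property
    def end_s(self) -> float:
        return self.episodes[-1].end_s

    def on_episodes(self) -> list[StimulationEpisode]:
        return [ep for ep in self.episodes if ep.is_on]


def _fmt(x: float) -> str:
    return f"{x:g}"


def build_amplitude_protocol(
    I0_ua: float, on_s: float = 30.0, off_s: float = 45.0
) -> SessionProtocol:
    """Amplitude sweep: 5 episodes at (1, 1.25, 1.5, 1.75, 2)·I0.

    Rect pulses, 130 Hz, 65 μs per phase, 100 μs interphase gap; 30-s ON
    episodes separated by 45-s OFF periods.
    """
    if not I0_ua > 0:
        raise DomainError("I0 must be positive")
    episodes: list[StimulationEpisode] = []
    t = 0.0
    for i, m in enumerate(AMPLITUDE_MULTIPLIERS):
        if i:
            episodes.append(StimulationEpisode(t, off_s, OFF_LABEL))
            t += off_s
        train = PulseTrainSpec(
            shape=PulseShape.RECT,
            amplitude_ua=m * I0_ua,
            pulse_width_us=65.0,
            frequency_hz=130.0,
            interphase_us=100.0,
        )
        episodes.append(StimulationEpisode(t, on_s, f"{_fmt(m)}xI0", train))
        t += on_s
    return SessionProtocol(episodes, paradigm="amplitude", I0_ua=I0_ua)


def build_frequency_protocol(
    I0_at_15hz_ua: float, on_s: float = 30.0, off_s: float = 45.0
) -> SessionProtocol:
    """Frequency sweep: 15…350 Hz at fixed amplitude (Rect, 65 μs, 100 μs gap)."""
    if not I0_at_15hz_ua > 0:
        raise DomainError("I0 must be positive")
    episodes: list[StimulationEpisode] = []
    t = 0.0
    for i, f in enumerate(FREQUENCY_LEVELS_HZ):
        if i:
            episodes.append(StimulationEpisode(t, off_s, OFF_LABEL))
            t += off_s
        train = PulseTrainSpec(
            shape=PulseShape.RECT,
            amplitude_ua=I0_at_15hz_ua,
            pulse_width_us=65.0,
            frequency_hz=f,
            interphase_us=100.0,
        )
        episodes.append(StimulationEpisode(t, on_s, f"{_fmt(f)}Hz", train))
        t += on_s
    return SessionProtocol(episodes, paradigm="frequency", I0_ua=I0_at_15hz_ua)


def build_waveform_protocol(
    Q0_uc: float,
    pw_us: float = 100.0,
    on_s: float = 30.0,
    off_s: float = 45.0,
    block_break_s: float = 1200.0,
) -> SessionProtocol:
    """Charge-matched waveform sweep.

    Five charge blocks at (1, 1.25, 1.5, 1.75, 2)·Q0; within each block the
    four shapes run in Rect-Sine-Tri-LinDec order with per-shape amplitudes
    chosen so every episode carries the block charge per phase. 45-s OFF
    within a block, a 20-min break between blocks; 130 Hz, 100 μs interphase.
    """
    if not Q0_uc > 0:
        raise DomainError("Q0 must be positive")
    episodes: list[StimulationEpisode] = []
    t = 0.0
    for bi, m in enumerate(CHARGE_MULTIPLIERS):
        if bi:
            episodes.append(StimulationEpisode(t, block_break_s, OFF_LABEL))
            t += block_break_s
        q = m * Q0_uc
        for si, shape in enumerate(WAVEFORM_SHAPE_ORDER):
            if si:
                episodes.append(StimulationEpisode(t, off_s, OFF_LABEL))
                t += off_s
            train = PulseTrainSpec(
                shape=shape,
                amplitude_ua=equivalent_amplitude(shape, q, pw_us),
                pulse_width_us=pw_us,
                frequency_hz=130.0,
                interphase_us=100.0,
            )
            episodes.append(
                StimulationEpisode(t, on_s, f"{_fmt(m)}xQ0_{shape.display}", train)
            )
            t += on_s
    return SessionProtocol(episodes, paradigm="waveform", Q0_uc=Q0_uc)


def episode_windows(
    protocol: SessionProtocol,
) -> list[tuple[str, float, float, PulseTrainSpec]]:
    """ON episodes as ``(label, start, end, train)`` half-open windows, in order."""
    return [
        (ep.label, ep.start_s, ep.end_s, ep.train)
        for ep in protocol.episodes
        if ep.is_on
    ]


# ---------------------------------------------------------------------------
# config (de)serialization — unit-suffixed keys, YAML container


def _train_to_dict(train: PulseTrainSpec) -> dict:
    return {
        "shape": train.shape.value,
        "amp_ua": float(train.amplitude_ua),
        "pw_us": float(train.pulse_width_us),
        "freq_hz": float(train.frequency_hz),
        "interphase_us": float(train.interphase_us),
        "polarity": train.polarity,
    }


def _train_from_dict(d: dict) -> PulseTrainSpec:
    return PulseTrainSpec(
        shape=PulseShape.coerce(d["shape"]),
        amplitude_ua=d["amp_ua"],
        pulse_width_us=d["pw_us"],
        frequency_hz=d["freq_hz"],
        interphase_us=d.get("interphase_us", 0.0),
        polarity=d.get("polarity", "cathodic_first"),
    )


def protocol_to_dict(protocol: SessionProtocol) -> dict:
    return {
        "paradigm": protocol.paradigm,
        "I0_ua": protocol.I0_ua,
        "Q0_uc": protocol.Q0_uc,
        "episodes": [
            {
                "start_s": float(ep.start_s),
                "duration_s": float(ep.duration_s),
                "label": ep.label,
                "train": _train_to_dict(ep.train) if ep.is_on else None,
            }
            for ep in protocol.episodes
        ],
    }


def protocol_from_dict(d: dict) -> SessionProtocol:
    episodes = [
        StimulationEpisode(
            start_s=ep["start_s"],
            duration_s=ep["duration_s"],
            label=ep["label"],
            train=_train_from_dict(ep["train"]) if ep.get("train") else None,
        )
        for ep in d["episodes"]
    ]
    return SessionProtocol(
        episodes, paradigm=d["paradigm"], I0_ua=d.get("I0_ua"), Q0_uc=d.get("Q0_uc")
    )


def save_protocol(path, protocol: SessionProtocol) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol_to_dict(protocol), fh, sort_keys=False)


def load_protocol(path) -> SessionProtocol:
    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh))
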