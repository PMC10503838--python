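"""Photoperiod regimen schedules.

A regimen is an ordered, contiguous partition of the recording into photo
periods (acclimation, dark1, light1, ..., darkN), each carrying its
illumination state and intensity.  Time is measured in 0-based integer
seconds from the recording origin and every period interval is half-open
``[start_s, end_s)``, so each second belongs to exactly one period.

Intensity presets follow the custom light-box calibration used in the
assays: white light at 20.5 uW/cm2 (~300 lx, "low") or 469.4 uW/cm2
(~8000 lx, "high"); infrared at 116.0 uW/cm2, which registers 0 lx.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence


class LightState(str, Enum):
    """Illumination state of a photo period."""

    IR_ONLY = "IR_only"
    WHITE = "white"


#: (irradiance uW/cm2, illuminance lx) presets from the light-box calibration
WHITE_LOW = (20.5, 300.0)
WHITE_HIGH = (469.4, 8000.0)
IR_HIGH = (116.0, 0.0)

_INTENSITY_PRESETS = {"low": WHITE_LOW, "high": WHITE_HIGH}


class RegimenError(ValueError):
    """Invalid regimen construction or lookup."""


@dataclass(frozen=True)
class PhotoPeriod:
    """One contiguous interval of constant illumination.

    Attributes
    ----------
    label : str
        Period name ("acclimation", "dark1", "light2", ...).
    start_s, end_s : int
        Half-open interval [start_s, end_s) in seconds from recording origin.
    light_state : LightState
        Whether the white light is on or only infrared.
    irradiance_uW_cm2 : float
        Light power per unit area.
    illuminance_lx : float
        Photometric brightness; 0 for IR-only periods.
    """

    label: str
    start_s: int
    end_s: int
    light_state: LightState
    irradiance_uW_cm2: float
    illuminance_lx: float

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise RegimenError(
                f"period {self.label!r}: start_s ({self.start_s}) must be < "
                f"end_s ({self.end_s})"
            )
        if self.irradiance_uW_cm2 < 0:
            raise RegimenError(f"period {self.label!r}: negative irradiance")
        if self.light_state is LightState.IR_ONLY and self.illuminance_lx != 0:
            raise RegimenError(
                f"period {self.label!r}: IR-only periods have 0 lx illuminance"
            )

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s

    @property
    def is_light(self) -> bool:
        return self.light_state is LightState.WHITE

    def contains(self, t_s: int) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass(frozen=True)
class Regimen:
    """Ordered photoperiod schedule of one assay.

    Attributes
    ----------
    periods : tuple of PhotoPeriod
        Contiguous, non-overlapping periods covering [0, total_duration_s).
    analysis_start_s : int
        First second entering the statistical model (default: end of
        acclimation).
    sampling_stride_s : int
        Model sampling stride: 1 s for dark-light repeat assays, 30 s for
        baseline assays.
    """

    periods: tuple[PhotoPeriod, ...]
    analysis_start_s: int
    sampling_stride_s: int = 1

    def __post_init__(self) -> None:
        if not self.periods:
            raise RegimenError("regimen must contain at least one period")
        if self.periods[0].start_s != 0:
            raise RegimenError("first period must start at t=0")
        for prev, cur in zip(self.periods, self.periods[1:]):
            if cur.start_s != prev.end_s:
                raise RegimenError(
                    f"periods {prev.label!r} and {cur.label!r} are not "
                    f"contiguous ({prev.end_s} != {cur.start_s})"
                )
        if not 0 <= self.analysis_start_s < self.total_duration_s:
            raise RegimenError("analysis_start_s outside regimen")
        if self.sampling_stride_s < 1:
            raise RegimenError("sampling_stride_s must be >= 1")

    @property
    def total_duration_s(self) -> int:
        return self.periods[-1].end_s

    def period_of(self, t_s: int) -> PhotoPeriod:
        """Return the unique period whose half-open interval contains t_s."""
        if not 0 <= t_s < self.total_duration_s:
            raise RegimenError(
                f"t={t_s} outside regimen [0, {self.total_duration_s})"
            )
        for p in self.periods:
            if p.contains(t_s):
                return p
        raise AssertionError("unreachable: periods partition the regimen")

    def period(self, label: str) -> PhotoPeriod:
        for p in self.periods:
            if p.label == label:
                return p
        raise RegimenError(f"no period labelled {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.periods)

    def light_state_at(self, t_s: int) -> LightState:
        return self.period_of(t_s).light_state

    def analysis_times(self, start_s: int | None = None) -> "np.ndarray":
        """Analyzed seconds: analysis_start_s to the end, at the stride."""
        import numpy as np

        start = self.analysis_start_s if start_s is None else start_s
        return np.arange(start, self.total_duration_s, self.sampling_stride_s)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "analysis_start_s": self.analysis_start_s,
            "sampling_stride_s": self.sampling_stride_s,
            "periods": [
                {
                    "label": p.label,
                    "start_s": p.start_s,
                    "end_s": p.end_s,
                    "light_state": p.light_state.value,
                    "irradiance_uW_cm2": p.irradiance_uW_cm2,
                    "illuminance_lx": p.illuminance_lx,
                }
                for p in self.periods
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Regimen":
        periods = tuple(
            PhotoPeriod(
                label=p["label"],
                start_s=int(p["start_s"]),
                end_s=int(p["end_s"]),
                light_state=LightState(p["light_state"]),
                irradiance_uW_cm2=float(p["irradiance_uW_cm2"]),
                illuminance_lx=float(p["illuminance_lx"]),
            )
            for p in d["periods"]
        )
        return cls(
            periods=periods,
            analysis_start_s=int(d["analysis_start_s"]),
            sampling_stride_s=int(d.get("sampling_stride_s", 1)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Regimen":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_seconds(minutes: float, what: str) -> int:
    if minutes <= 0:
        raise RegimenError(f"{what} must be positive, got {minutes}")
    s = round(minutes * 60)
    if abs(s - minutes * 60) > 1e-9:
        raise RegimenError(f"{what} must be a whole number of seconds")
    return int(s)


def build_repeat_regimen(
    acclim_min: float = 30,
    n_cycles: int = 4,
    dark_min: float = 7.5,
    light_min: float = 7.5,
    final_dark_min: float = 25,
    intensity: str = "high",
    include_final_dark: bool = True,
) -> Regimen:
    """Construct a dark-light repeat regimen.

    Default layout is the standard assay: 30-min dark acclimation, four
    cycles of 7.5-min dark + light of the chosen duration, and a terminal
    25-min dark period.  Dark periods (including acclimation) run under
    infrared; light periods use the chosen white intensity ("low" ~300 lx
    or "high" ~8000 lx).  Post-acclimation dark periods are numbered
    dark1..darkN with the terminal dark as dark(n_cycles+1); some early
    assays omitted the terminal dark, expressed via ``include_final_dark``.
    """
    if n_cycles < 1:
        raise RegimenError(f"n_cycles must be >= 1, got {n_cycles}")
    if intensity not in _INTENSITY_PRESETS:
        raise RegimenError(f"intensity must be one of {sorted(_INTENSITY_PRESETS)}")
    white_irr, white_lx = _INTENSITY_PRESETS[intensity]
    ir_irr, ir_lx = IR_HIGH

    acclim_s = _as_seconds(acclim_min, "acclim_min")
    dark_s = _as_seconds(dark_min, "dark_min")
    light_s = _as_seconds(light_min, "light_min")

    periods: list[PhotoPeriod] = []
    t = 0

    def add(label: str, dur: int, state: LightState) -> None:
        nonlocal t
        irr, lx = (white_irr, white_lx) if state is LightState.WHITE else (ir_irr, ir_lx)
        periods.append(PhotoPeriod(label, t, t + dur, state, irr, lx))
        t += dur

    add("acclimation", acclim_s, LightState.IR_ONLY)
    for c in range(1, n_cycles + 1):
        add(f"dark{c}", dark_s, LightState.IR_ONLY)
        add(f"light{c}", light_s, LightState.WHITE)
    if include_final_dark:
        add(f"dark{n_cycles + 1}", _as_seconds(final_dark_min, "final_dark_min"),
            LightState.IR_ONLY)

    return Regimen(
        periods=tuple(periods),
        analysis_start_s=acclim_s,
        sampling_stride_s=1,
    )


def build_baseline_regimen(duration_h: float, light_state: LightState | str) -> Regimen:
    """Construct a constant-illumination baseline regimen.

    One analysis period of ``duration_h`` hours in either constant white
    light (high intensity) or constant darkness (infrared only); the
    pre-recording acclimation happens before the recording origin and is
    not part of the schedule.  Baseline data are modeled at one sample per
    30 seconds.
    """
    if isinstance(light_state, str):
        light_state = LightState(light_state)
    if duration_h <= 0:
        raise RegimenError(f"duration_h must be positive, got {duration_h}")
    dur_s = round(duration_h * 3600)
    if light_state is LightState.WHITE:
        irr, lx = WHITE_HIGH
        label = "light"
    else:
        irr, lx = IR_HIGH
        label = "dark"
    period = PhotoPeriod(label, 0, int(dur_s), light_state, irr, lx)
    return Regimen(periods=(period,), analysis_start_s=0, sampling_stride_s=30)


#: Named regimen presets accepted wherever a regimen file is accepted.
def _preset_repeat(light_min: float, intensity: str) -> Regimen:
    return build_repeat_regimen(light_min=light_min, intensity=intensity)


REGIMEN_PRESETS = {
    "repeat-7.5+7.5": lambda: _preset_repeat(7.5, "high"),
    "repeat-7.5+6": lambda: _preset_repeat(6, "high"),
    "repeat-7.5+4": lambda: _preset_repeat(4, "high"),
    "repeat-7.5+2": lambda: _preset_repeat(2, "high"),
    "dim-7.5+7.5": lambda: _preset_repeat(7.5, "low"),
    "dim-7.5+4": lambda: _preset_repeat(4, "low"),
    "dim-7.5+2": lambda: _preset_repeat(2, "low"),
    "baseline-light": lambda: build_baseline_regimen(12, LightState.WHITE),
    "baseline-dark": lambda: build_baseline_regimen(12, LightState.IR_ONLY),
}


def load_regimen(ref: str | Path) -> Regimen:
    """Load a regimen from a preset name or a JSON file path."""
    if isinstance(ref, str) and ref in REGIMEN_PRESETS:
        return REGIMEN_PRESETS[ref]()
    path = Path(ref)
    if not path.exists():
        raise RegimenError(
            f"{ref!r} is neither a preset ({sorted(REGIMEN_PRESETS)}) nor a file"
        )
    return Regimen.from_json(path)
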