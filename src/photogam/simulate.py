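"""Synthetic larval locomotor traces with photoperiod-locked dynamics.

Real multiwell tracking data are severely right-skewed and zero-inflated:
most seconds a larva does not move at all, and positive seconds are short
bursts of a few mm.  The generator reproduces that marginal structure with
a zero-inflated Gamma draw per second, modulated by a deterministic rate
profile that carries the photoperiod physiology:

* a light/dark baseline (larvae move more under white light),
* a brief onset transient after every illumination switch,
* a post-illumination dark *rebound* whose amplitude saturates in the
  duration of the preceding light period (Michaelis-type ``s/(s+1)`` with a
  per-genotype half-saturation), and decays exponentially through the dark
  period,
* a log-normal per-assay random multiplier (between-assay variation).

Genotype enters only through an overall activity multiplier (basal
deficit) and the rebound half-saturation, so parameter-recovery tests have
a well-defined target: wild-type larvae rebound after brief light, mutants
need substantially longer illumination to mount the same rebound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .regimen import LightState, Regimen, build_repeat_regimen
from .traces import WellTrace, rolling_sum, write_well_traces


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GroupParams:
    """Per-genotype mechanism parameters.

    activity_mult scales the whole rate profile (basal deficit when < 1);
    rebound_halfsat_min is the light duration (minutes) at which the dark
    rebound reaches half its ceiling.
    """

    activity_mult: float = 1.0
    rebound_halfsat_min: float = 1.0

    def __post_init__(self) -> None:
        if self.activity_mult <= 0 or self.rebound_halfsat_min <= 0:
            raise SimConfigError("group parameters must be positive")


#: Default genotype mechanism: WT rebounds after ~1 min of light, HM needs
#: ~6 min and carries a basal activity deficit; HT behaves like WT.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "WT": GroupParams(activity_mult=1.0, rebound_halfsat_min=1.0),
    "HT": GroupParams(activity_mult=1.0, rebound_halfsat_min=1.0),
    "HM": GroupParams(activity_mult=0.75, rebound_halfsat_min=6.0),
}


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    All movement scales are mm per active second; probabilities are the
    chance of a zero-movement second in the given illumination state.
    """

    regimen: Regimen = field(default_factory=build_repeat_regimen)
    n_assays: int = 6
    n_fish_per_group: int = 16
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    group_factor: str = "geno"
    zero_inflation_dark: float = 0.80
    zero_inflation_light: float = 0.50
    burst_shape: float = 0.8
    burst_scale: float = 3.0
    base_rate_dark: float = 0.5
    base_rate_light: float = 1.0
    onset_spike_amp: float = 1.5
    onset_spike_decay_s: float = 20.0
    rebound_amp: float = 4.0
    rebound_decay_s: float = 240.0
    assay_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zero_inflation_dark", "zero_inflation_light"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {p}")
        for name in ("burst_shape", "burst_scale", "base_rate_dark",
                     "base_rate_light", "onset_spike_decay_s",
                     "rebound_decay_s"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("onset_spike_amp", "rebound_amp", "assay_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.n_assays < 1 or self.n_fish_per_group < 1:
            raise SimConfigError("n_assays and n_fish_per_group must be >= 1")
        if not self.groups:
            raise SimConfigError("at least one group required")
        self.groups = {
            k: v if isinstance(v, GroupParams) else GroupParams(**v)
            for k, v in self.groups.items()
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regimen"] = self.regimen.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("regimen"), dict):
            d["regimen"] = Regimen.from_dict(d["regimen"])
        if "groups" in d:
            d["groups"] = {
                k: GroupParams(**v) if isinstance(v, dict) else v
                for k, v in d["groups"].items()
            }
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated study (for recovery tests)."""

    expected_rsums: dict[str, np.ndarray]  # group -> mm/min trajectory
    assay_effects: dict[str, float]  # assay_id -> log-multiplier
    group_params: dict[str, GroupParams]

    def to_dict(self) -> dict:
        return {
            "expected_rsums": {k: v.tolist() for k, v in self.expected_rsums.items()},
            "assay_effects": self.assay_effects,
            "group_params": {k: asdict(v) for k, v in self.group_params.items()},
        }


def rebound_saturation(light_duration_min: float, halfsat_min: float) -> float:
    """Fraction of the rebound ceiling reached after a light period.

    Michaelis-type saturation ``s / (s + 1)`` with ``s = duration / halfsat``.
    """
    s = light_duration_min / halfsat_min
    return s / (s + 1.0)


def rate_profile(config: SimConfig, group: str) -> np.ndarray:
    """Deterministic per-second rate multiplier for one group.

    The product of the state baseline, the post-switch onset transient and
    the duration-dependent dark rebound, scaled by the group's activity
    multiplier.  The per-assay random effect is *not* included.
    """
    params = config.groups[group]
    regimen = config.regimen
    n = regimen.total_duration_s
    rate = np.empty(n)
    t_axis = np.arange(n, dtype=float)

    for i, p in enumerate(regimen.periods):
        sl = slice(p.start_s, p.end_s)
        base = config.base_rate_light if p.is_light else config.base_rate_dark
        seg = np.full(p.duration_s, base)
        local = t_axis[sl] - p.start_s
        # onset transient after any illumination switch (not at recording start)
        if i > 0 and config.onset_spike_amp > 0:
            seg *= 1.0 + config.onset_spike_amp * np.exp(
                -local / config.onset_spike_decay_s
            )
        # dark rebound after a light -> dark switch
        if (
            i > 0
            and not p.is_light
            and regimen.periods[i - 1].is_light
            and config.rebound_amp > 0
        ):
            dur_min = regimen.periods[i - 1].duration_s / 60.0
            ceiling = config.rebound_amp * rebound_saturation(
                dur_min, params.rebound_halfsat_min
            )
            seg *= 1.0 + ceiling * np.exp(-local / config.rebound_decay_s)
        rate[sl] = seg
    return params.activity_mult * rate


def _state_mask(regimen: Regimen) -> np.ndarray:
    """Boolean per-second mask, True where the white light is on."""
    mask = np.zeros(regimen.total_duration_s, dtype=bool)
    for p in regimen.periods:
        if p.is_light:
            mask[p.start_s:p.end_s] = True
    return mask


def expected_movement(config: SimConfig, group: str) -> np.ndarray:
    """Expected mm moved per second (assay effect at its median, i.e. 0)."""
    light = _state_mask(config.regimen)
    p_zero = np.where(light, config.zero_inflation_light, config.zero_inflation_dark)
    return (
        (1.0 - p_zero)
        * config.burst_shape
        * config.burst_scale
        * rate_profile(config, group)
    )


def simulate_well(
    config: SimConfig,
    assay_effect: float,
    group: str,
    rng: np.random.Generator,
    assay_id: str = "assay1",
    well_id: str = "w1",
) -> WellTrace:
    """Draw one fish's per-second trace.

    Per second: ``movement = Bernoulli(1 - pi_state) * Gamma(shape, scale)
    * rate(t)`` where ``rate`` is the group's deterministic profile times
    ``exp(assay_effect)``.
    """
    if group not in config.groups:
        raise SimConfigError(f"unknown group {group!r}")
    n = config.regimen.total_duration_s
    light = _state_mask(config.regimen)
    p_zero = np.where(light, config.zero_inflation_light, config.zero_inflation_dark)
    active = rng.random(n) >= p_zero
    bursts = rng.gamma(config.burst_shape, config.burst_scale, size=n)
    rate = rate_profile(config, group) * np.exp(assay_effect)
    return WellTrace(
        assay_id=assay_id,
        well_id=well_id,
        group_labels={config.group_factor: group},
        distance_per_s=np.where(active, bursts * rate, 0.0),
    )


def _well_rng(seed: int, assay_idx: int, well_idx: int) -> np.random.Generator:
    # deterministic substream per (seed, assay, well): parallel-safe
    return np.random.default_rng(np.random.SeedSequence([seed, 1, assay_idx, well_idx]))


def simulate_traces(config: SimConfig) -> tuple[list[WellTrace], SimTruth]:
    """Simulate the whole study in memory.

    Returns all ``n_assays * n_groups * n_fish_per_group`` traces plus the
    ground truth (expected group trajectories and the drawn assay effects).
    Fully determined by ``config`` including its seed.
    """
    effect_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    assay_ids = [f"assay{a + 1}" for a in range(config.n_assays)]
    if config.assay_sd > 0:
        effects = effect_rng.normal(0.0, config.assay_sd, size=config.n_assays)
    else:
        effects = np.zeros(config.n_assays)
    assay_effects = {aid: float(e) for aid, e in zip(assay_ids, effects)}

    traces: list[WellTrace] = []
    for a_idx, aid in enumerate(assay_ids):
        well_idx = 0
        for group in config.groups:
            for _ in range(config.n_fish_per_group):
                rng = _well_rng(config.seed, a_idx, well_idx)
                traces.append(
                    simulate_well(
                        config,
                        assay_effects[aid],
                        group,
                        rng,
                        assay_id=aid,
                        well_id=f"w{well_idx + 1:02d}",
                    )
                )
                well_idx += 1

    window = 60
    expected = {}
    for group in config.groups:
        em = expected_movement(config, group)
        expected[group] = rolling_sum(em, window)
    truth = SimTruth(
        expected_rsums=expected,
        assay_effects=assay_effects,
        group_params=dict(config.groups),
    )
    return traces, truth


def simulate_study(config: SimConfig, outdir: str | Path) -> Path:
    """Simulate a study and write its artifact files.

    Writes ``traces.csv`` + ``metadata.csv`` (the trace I/O dialect),
    ``regimen.json`` and ``truth.json`` under ``outdir``; identical config
    and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces, truth = simulate_traces(config)
    write_well_traces(traces, outdir / "traces.csv", outdir / "metadata.csv")
    config.regimen.to_json(outdir / "regimen.json")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh)
        fh.write("\n")
    return outdir
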