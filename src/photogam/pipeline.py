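"""End-to-end pipeline: simulate/load -> aggregate -> fit -> contrasts ->
proportions -> cross-regimen comparisons.

A run is described by a single :class:`RunConfig` (usually a YAML file):
one or more studies (each simulated from a config or loaded from trace
CSVs), a shared model specification, a comparison plan (which group pairs,
in which direction, over which photo-period sets) and cross-study
proportion tests.  Every stage persists its artifacts under the output
directory so partial reruns and external audit are possible, and the whole
run is reproducible bit-for-bit from the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contrasts import ContrastTrajectory, pairwise_trajectory
from .gam import (
    GamFit,
    ModelSpec,
    SmoothTerm,
    build_design,
    check_basis_dimension,
    fit_gam,
    term_tests,
)
from .proportions import (
    PeriodProportion,
    compare_proportions,
    proportion_significant,
)
from .regimen import Regimen, load_regimen
from .simulate import SimConfig, simulate_traces
from .traces import (
    WellTrace,
    aggregate_group_mean,
    group_series_frame,
    read_well_traces,
    write_well_traces,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class StudySpec:
    """One study: either a simulation config or paths to recorded traces."""

    name: str
    simulate: dict | None = None  # SimConfig fields (regimen as preset/file ok)
    traces: str | None = None
    metadata: str | None = None
    regimen: str | None = None  # preset name or JSON path (input studies)

    def validate(self) -> None:
        if (self.simulate is None) == (self.traces is None):
            raise ConfigError(
                f"study {self.name!r}: exactly one of 'simulate' or "
                "'traces' must be given"
            )
        if self.traces is not None and (self.metadata is None or self.regimen is None):
            raise ConfigError(
                f"study {self.name!r}: input studies need 'metadata' and "
                "'regimen'"
            )


@dataclass
class RunConfig:
    """Full description of a pipeline run."""

    studies: list[StudySpec]
    model: ModelSpec
    contrast_factor: str = "geno"
    pairs: list[dict] = field(default_factory=lambda: [
        {"a": "WT", "b": "HM", "direction": "WT"}
    ])
    period_sets: dict[str, list[str]] = field(default_factory=dict)
    compare: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "photogam_run"
    stride_s: int | None = None  # override regimen sampling stride
    analysis_end_s: int | None = None  # optional truncation of the window

    def __post_init__(self) -> None:
        if not self.studies:
            raise ConfigError("at least one study required")
        names = [s.name for s in self.studies]
        if len(set(names)) != len(names):
            raise ConfigError("study names must be unique")
        for s in self.studies:
            s.validate()
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        for c in self.compare:
            for key in ("study_a", "study_b", "pair", "period_set"):
                if key not in c:
                    raise ConfigError(f"comparison entry missing {key!r}")
            for s in (c["study_a"], c["study_b"]):
                if s not in names:
                    raise ConfigError(f"comparison references unknown study {s!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        studies = [
            StudySpec(name=name, **spec) for name, spec in d.pop("studies").items()
        ]
        model = d.pop("model", None)
        if isinstance(model, dict):
            model = ModelSpec.from_dict(model)
        elif model is None:
            model = ModelSpec(
                parametric_factors=[d.get("contrast_factor", "geno")],
                smooth_terms=[SmoothTerm(var="time_s", k=130,
                                         by=d.get("contrast_factor", "geno"))],
            )
        return cls(studies=studies, model=model, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "studies": {
                s.name: {
                    k: v
                    for k, v in {
                        "simulate": s.simulate,
                        "traces": s.traces,
                        "metadata": s.metadata,
                        "regimen": s.regimen,
                    }.items()
                    if v is not None
                }
                for s in self.studies
            },
            "model": self.model.to_dict(),
            "contrast_factor": self.contrast_factor,
            "pairs": self.pairs,
            "period_sets": self.period_sets,
            "compare": self.compare,
            "alpha": self.alpha,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stride_s": self.stride_s,
            "analysis_end_s": self.analysis_end_s,
        }


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # where artifacts land is not part of the analysis
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Everything computed for one study."""

    name: str
    regimen: Regimen
    fit: GamFit
    trajectory: ContrastTrajectory
    proportions: dict[tuple[str, str], PeriodProportion]  # (pair_key, set) -> prop


def _resolve_regimen(ref: str | dict | Regimen, base: Path | None = None) -> Regimen:
    if isinstance(ref, Regimen):
        return ref
    if isinstance(ref, dict):
        return Regimen.from_dict(ref)
    if base is not None and (base / str(ref)).exists():
        return Regimen.from_json(base / str(ref))
    return load_regimen(ref)


def _study_traces(
    study: StudySpec, seed: int, out: Path
) -> tuple[list[WellTrace], Regimen]:
    if study.simulate is not None:
        sim = dict(study.simulate)
        reg = _resolve_regimen(sim.pop("regimen", "repeat-7.5+7.5"))
        sim.setdefault("seed", seed)
        cfg = SimConfig(regimen=reg, **sim)
        traces, truth = simulate_traces(cfg)
        write_well_traces(traces, out / "traces.csv", out / "metadata.csv")
        reg.to_json(out / "regimen.json")
        _json_dump(truth.to_dict(), out / "truth.json")
        return traces, reg
    traces = read_well_traces(study.traces, study.metadata)
    reg = _resolve_regimen(study.regimen)
    return traces, reg


def run_study(
    config: RunConfig, study: StudySpec, out: Path, seed: int
) -> StudyResult:
    """Execute stages (1)-(4) for one study, persisting artifacts."""
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    traces, regimen = _study_traces(study, seed, out)
    logger.info("study %s: %d traces (%.1fs)", study.name, len(traces), time.time() - t0)

    stride = config.stride_s or regimen.sampling_stride_s
    factors = config.model.parametric_factors
    series = aggregate_group_mean(
        traces,
        factors,
        stride_s=stride,
        start_s=regimen.analysis_start_s,
        end_s=config.analysis_end_s,
    )
    df = group_series_frame(series)
    df.to_csv(out / "group_series.csv", index=False, float_format="%.8g")

    design = build_design(config.model, df)
    fit = fit_gam(design)
    _json_dump(fit.summary_dict(), out / "fit_summary.json")
    tt = term_tests(fit)
    pd.DataFrame([t.__dict__ for t in tt]).to_csv(
        out / "term_tests.csv", index=False, float_format="%.8g"
    )
    checks = check_basis_dimension(
        fit, rng=np.random.default_rng(np.random.SeedSequence([seed, 99]))
    )
    _json_dump([c.__dict__ for c in checks], out / "diagnostics.json")

    traj = pairwise_trajectory(fit, config.contrast_factor, alpha=config.alpha)
    traj.pairs.to_csv(out / "contrasts.csv", index=False, float_format="%.8g")
    traj.emms.to_csv(out / "emms.csv", index=False, float_format="%.8g")

    props: dict[tuple[str, str], PeriodProportion] = {}
    period_sets = config.period_sets or _default_period_sets(regimen)
    for pair_spec in config.pairs:
        a, b = pair_spec["a"], pair_spec["b"]
        direction = pair_spec.get("direction", a)
        for set_name, labels in period_sets.items():
            labels = [l for l in labels if l in regimen.labels]
            if not labels:
                continue
            pp = proportion_significant(
                traj,
                regimen,
                tuple(labels),
                (a, b),
                direction,
                alpha=config.alpha,
                label=f"{study.name}:{a}>{b}:{set_name}",
            )
            props[(f"{a}>{b}", set_name)] = pp
    _json_dump([p.to_dict() for p in props.values()], out / "proportions.json")
    logger.info("study %s done (%.1fs)", study.name, time.time() - t0)
    return StudyResult(study.name, regimen, fit, traj, props)


def _default_period_sets(regimen: Regimen) -> dict[str, list[str]]:
    dark = [l for l in regimen.labels if l.startswith("dark")]
    # post-illumination dark periods (all but the first dark of repeat assays)
    sets = {"dark_all": dark}
    if len(dark) > 2:
        sets["dark_late"] = dark[2:]
    return sets


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write ``report.json``.

    Returns the report dictionary: per-study fit summaries, term tests,
    proportions, diagnostics, the cross-study proportion comparisons, and
    provenance (config hash, seed, version).
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    results: dict[str, StudyResult] = {}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for study in config.studies:
            try:
                results[study.name] = run_study(
                    config, study, out_root / study.name, config.seed
                )
            except Exception as exc:
                raise type(exc)(
                    f"pipeline stage failed for study {study.name!r} "
                    f"(artifacts under {out_root / study.name}): {exc}"
                ) from exc
        caught = sorted({str(w.message) for w in wlist})

    comparisons = []
    for c in config.compare:
        pair = tuple(c["pair"])
        key = (f"{pair[0]}>{pair[1]}", c["period_set"])
        ra, rb = results[c["study_a"]], results[c["study_b"]]
        if key not in ra.proportions or key not in rb.proportions:
            raise ConfigError(
                f"comparison {c}: proportion {key} missing from a study"
            )
        pc = compare_proportions(ra.proportions[key], rb.proportions[key])
        comparisons.append(
            {"study_a": c["study_a"], "study_b": c["study_b"], **pc.to_dict()}
        )
    _json_dump(comparisons, out_root / "comparisons.json")

    report = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
        "studies": {
            name: {
                "n_obs": r.fit.n_obs,
                "deviance_explained": r.fit.deviance_explained,
                "total_edf": r.fit.total_edf,
                "aic": r.fit.aic(),
                "lambdas": r.fit.lambdas,
                "term_tests": [
                    t.__dict__ for t in term_tests(r.fit)
                ],
                "proportions": [p.to_dict() for p in r.proportions.values()],
            }
            for name, r in results.items()
        },
        "comparisons": comparisons,
        "warnings": caught,
    }
    _json_dump(report, out_root / "report.json")
    return report
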