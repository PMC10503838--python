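#!/usr/bin/env python
"""Dark-period proportion-of-significance and cross-regimen tests.

Collapses each study's per-second WT-vs-HM significance trajectory into
the directional proportion of post-illumination dark seconds where wild
type moved significantly more than the homozygous mutant, then compares
the proportions between every pair of illumination durations with the
Yates-corrected two-proportions test.  Writes results/proportions.csv and
results/proportion_comparisons.csv.
"""

import itertools
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from photogam.proportions import (
    PeriodProportion, compare_proportions,
)
from photogam.regimen import Regimen

ROOT = Path(__file__).resolve().parents[1]
TRAJ = ROOT / "scratch" / "analysis" / "contrasts"
STUDIES = ROOT / "scratch" / "analysis" / "studies"
RESULTS = ROOT / "results"
DARK_PERIODS = ("dark2", "dark3")  # post-illumination dark phases
ALPHA = 0.05


def proportion_for(study: str) -> PeriodProportion:
    regimen = Regimen.from_json(STUDIES / study / "regimen.json")
    table = pd.read_csv(TRAJ / f"{study}.csv")
    sub = table[(table["a"] == "WT") & (table["b"] == "HM")]
    t = sub["time_s"].to_numpy()
    mask = np.zeros(len(sub), dtype=bool)
    for lab in DARK_PERIODS:
        p = regimen.period(lab)
        mask |= (t >= p.start_s) & (t < p.end_s)
    picked = sub.loc[mask]
    sig = (picked["p_adj"].to_numpy() < ALPHA) & (
        picked["direction"].to_numpy() == "WT")
    return PeriodProportion(
        pair=("WT", "HM"), direction="WT", period_labels=DARK_PERIODS,
        n_seconds=int(mask.sum()), n_significant=int(sig.sum()),
        alpha=ALPHA, label=study,
    )


def dark_diff_ratio(study: str) -> tuple[float, float]:
    """Mean WT-HM difference (mm/min) and WT/HM-like excess in dark phases."""
    regimen = Regimen.from_json(STUDIES / study / "regimen.json")
    table = pd.read_csv(TRAJ / f"{study}.csv")
    sub = table[(table["a"] == "WT") & (table["b"] == "HM")]
    t = sub["time_s"].to_numpy()
    mask = np.zeros(len(sub), dtype=bool)
    for lab in DARK_PERIODS:
        p = regimen.period(lab)
        mask |= (t >= p.start_s) & (t < p.end_s)
    d = sub.loc[mask, "diff"]
    tr = sub.loc[mask, "t_ratio"]
    return float(d.mean()), float(tr.abs().mean())


def main() -> None:
    studies = sorted(p.stem for p in TRAJ.glob("*.csv"))
    props = {s: proportion_for(s) for s in studies}
    rows = []
    for s, pp in props.items():
        mean_diff, mean_t = dark_diff_ratio(s)
        rows.append({
            "study": s, "periods": "+".join(DARK_PERIODS),
            "n_seconds": pp.n_seconds, "n_significant": pp.n_significant,
            "proportion_pct": pp.proportion_pct,
            "mean_dark_diff_mm_min": round(mean_diff, 2),
            "mean_dark_abs_t": round(mean_t, 2),
        })
    pd.DataFrame(rows).to_csv(RESULTS / "proportions.csv", index=False)
    for r in rows:
        print(f"{r['study']}: WT > HM in {r['proportion_pct']}% of "
              f"post-light dark seconds "
              f"(mean dark difference {r['mean_dark_diff_mm_min']} mm/min)")

    cmp_rows = []
    for sa, sb in itertools.combinations(studies, 2):
        pc = compare_proportions(props[sa], props[sb])
        cmp_rows.append({
            "study_a": sa, "study_b": sb,
            "prop_a_pct": props[sa].proportion_pct,
            "prop_b_pct": props[sb].proportion_pct,
            "chi2": round(pc.chi2, 3), "p": pc.p_value,
        })
    pd.DataFrame(cmp_rows).to_csv(
        RESULTS / "proportion_comparisons.csv", index=False,
        float_format="%.6g",
    )
    print(f"wrote {RESULTS / 'proportions.csv'} and "
          f"{RESULTS / 'proportion_comparisons.csv'}")


if __name__ == "__main__":
    main()
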