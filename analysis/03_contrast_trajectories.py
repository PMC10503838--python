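#!/usr/bin/env python
"""Per-second Tukey-adjusted genotype contrasts for every study.

Refits each study's additive model and computes the estimated marginal
mean of each genotype at every analyzed second, all pairwise differences
with studentized-range (Tukey) adjustment, and the direction of each
difference.  Full trajectories go to scratch/ (one row per second per
pair); a compact per-(study, pair) summary of significant-second counts
lands in results/contrast_summary.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from photogam.contrasts import pairwise_trajectory
from photogam.gam import ModelSpec, SmoothTerm, build_design, fit_gam

ROOT = Path(__file__).resolve().parents[1]
SERIES = ROOT / "scratch" / "analysis" / "series"
TRAJ = ROOT / "scratch" / "analysis" / "contrasts"
RESULTS = ROOT / "results"

MODEL = ModelSpec(
    parametric_factors=["geno"],
    smooth_terms=[SmoothTerm(var="time_s", k=30, by="geno")],
    random_effect="assay_id",
)


def main() -> None:
    TRAJ.mkdir(parents=True, exist_ok=True)
    rows = []
    for series_csv in sorted(SERIES.glob("*.csv")):
        df = pd.read_csv(series_csv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gam(build_design(MODEL, df))
            traj = pairwise_trajectory(fit, "geno", alpha=0.05)
        traj.pairs.to_csv(TRAJ / series_csv.name, index=False,
                          float_format="%.8g")
        for pair, sub in traj.pairs.groupby("pair"):
            sig = sub["significant"]
            rows.append({
                "study": series_csv.stem,
                "pair": pair,
                "n_seconds": len(sub),
                "n_significant": int(sig.sum()),
                "pct_significant": round(100 * sig.mean(), 2),
                "median_abs_diff_mm_min": round(sub["diff"].abs().median(), 2),
            })
            print(f"{series_csv.stem} {pair}: {rows[-1]['pct_significant']}% "
                  f"of seconds significant")
    out = RESULTS / "contrast_summary.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
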