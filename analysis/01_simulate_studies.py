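#!/usr/bin/env python
"""Simulate the dark-light repeat studies analyzed in this project.

Four reduced-scale repeat regimens (2-, 4-, 6- and 7.5-min illumination,
two dark-light cycles, 4 assays x 3 genotypes x 8 fish) are generated with
the default mechanism: wild-type larvae rebound in post-light darkness
after ~1 min of light (half-saturation 1 min), homozygous mutants need
~6 min and carry a basal activity deficit; heterozygotes behave like
wild type.  Raw per-second traces land under scratch/ (they are large and
fully regenerable from the seed); downstream scripts read them from there.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from photogam.regimen import build_repeat_regimen
from photogam.simulate import SimConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "analysis" / "studies"
SEED = 20260929
LIGHT_DURATIONS = (2, 4, 6, 7.5)


def main() -> None:
    for i, light_min in enumerate(LIGHT_DURATIONS):
        tag = f"light{str(light_min).replace('.', 'p')}"
        regimen = build_repeat_regimen(
            acclim_min=5, n_cycles=2, dark_min=7.5,
            light_min=light_min, final_dark_min=7.5,
        )
        cfg = SimConfig(
            regimen=regimen, n_assays=4, n_fish_per_group=8,
            seed=SEED + i,
        )
        out = simulate_study(cfg, OUT / tag)
        n = cfg.n_assays * len(cfg.groups) * cfg.n_fish_per_group
        print(f"{tag}: {n} wells x {regimen.total_duration_s} s -> {out}")


if __name__ == "__main__":
    main()
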