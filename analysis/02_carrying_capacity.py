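"""Estimate the long-term carrying capacity of each site's pasture base.

Reference steers graze a one-hectare paddock down to the species residual on
a daily time step; the run-average steer number divided by the 1.5x cow+calf
conversion gives cows/ha.  Writes results/carrying_capacity.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import cowcalf as cc
from cowcalf.management import CapacityConfig

YEARS = 30
DISCARD = 10


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--met-dir", type=Path, default=Path("results/met"))
    ap.add_argument("--out", type=Path, default=Path("results/carrying_capacity.csv"))
    args = ap.parse_args()

    cfg = CapacityConfig(run_years=YEARS, discard_years=DISCARD)
    rows = []
    for name in cc.BUILTIN_SITES:
        site = cc.builtin_site(name)
        met = cc.read_met(args.met_dir / f"{name}.csv")
        cows = cc.estimate_carrying_capacity(site, met, cfg)
        rows.append({"site": site.name, "pasture": site.pasture,
                     "capacity_cows_ha": cows})
        print(f"{site.name:12s} ({site.pasture:8s}) {cows:.1f} cows/ha")
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    lowest = df.loc[df["capacity_cows_ha"].idxmin(), "site"]
    print(f"\nLowest capacity at {lowest}; all sites within 0.6-0.9 cows/ha: "
          f"{df['capacity_cows_ha'].between(0.6, 0.9).all()}")


if __name__ == "__main__":
    main()
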