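#!/usr/bin/env python
"""Embed species-mean band spectra as PCA trajectories.

Species-mean 101 x 60 band matrices are log transformed, min-max scaled
per band across developmental time, and embedded with a centred PCA;
developmental events are marked at their median relative times along
each trajectory.
"""

import argparse
from pathlib import Path

import pandas as pd

from ept.pipeline import make_config, stage_reduce


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = make_config({"seed": args.seed, "output_dir": str(args.out)})
    stage_reduce(cfg, args.out)

    var = pd.read_csv(args.out / "pca_variance.csv")
    for _, row in var.iterrows():
        print(f"  {row['species']}: PC1 {100*row['PC1']:.1f}%, "
              f"PC2 {100*row['PC2']:.1f}% "
              f"(PC1+PC2 {100*row['PC1_plus_PC2']:.1f}% of variance)")


if __name__ == "__main__":
    main()
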