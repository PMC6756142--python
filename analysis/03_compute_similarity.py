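"""Compute CSCS and Bray-Curtis similarity for every pair of leaf samples.

After blank subtraction, rows are normalised to relative ion intensities and
all C(102, 2) = 5,151 sample pairs are scored with both metrics; total ion
intensity per sample is kept for the quantitative contrasts.  Prints the
within- vs between-species similarity summary that motivates the formal
permutation tests.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from foliarchem.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out, seed=args.seed)
    sims = run_pipeline(cfg, stages=("similarity",))["similarity"]
    meta = pd.read_csv(args.out / "fixture" / "metadata.csv").set_index("sample_id")

    for metric in ("CSCS", "BC"):
        sim = sims[metric]
        sp = meta.loc[sim.index, "species"].to_numpy()
        gen = meta.loc[sim.index, "genus"].to_numpy()
        iu = np.triu_indices(sim.shape[0], 1)
        v = sim.to_numpy()[iu]
        same_sp = sp[iu[0]] == sp[iu[1]]
        same_gen = gen[iu[0]] == gen[iu[1]]
        print(f"{metric}: {iu[0].size} sample pairs")
        print(f"  mean within species:               {v[same_sp].mean():.3f}")
        print(f"  mean between species, same genus:  {v[same_gen & ~same_sp].mean():.3f}")
        print(f"  mean between genera:               {v[~same_gen].mean():.3f}")


if __name__ == "__main__":
    main()
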