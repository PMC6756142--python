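"""Test treatment, leaf-age and species effects on chemical similarity.

Runs the constrained permutation tests (999 permutations, control-discordant
pairs rejected) for each focal species / genus, combines species-level
p-values with the weighted-Z method, and contrasts total ion intensity with
one-sided Wilcoxon tests.  Prints the three report tables: treatment effect
stratified by leaf age, leaf-age effect controlling for treatment, and the
within- vs between-congener species effect per genus.
"""

import argparse
from pathlib import Path

import pandas as pd

from foliarchem.pipeline import PipelineConfig, run_pipeline


def show(df: pd.DataFrame, title: str) -> None:
    cols = ["group", "stratum", "metric", "within", "between", "delta",
            "p_paper", "p"]
    print(f"\n== {title} ==")
    print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=999)
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out, seed=args.seed, n_perm=args.n_perm)
    df = run_pipeline(cfg, stages=("test",))["results"]

    show(df[df.analysis == "treatment"], "jasmonic acid treatment effect (by leaf age)")
    show(df[df.analysis == "leaf_age"], "leaf age effect (controlling treatment)")
    show(df[df.analysis == "species"], "species effect within genera")
    sig = df[(df.analysis == "species") & (df.p <= 0.05)]
    print(f"\nspecies effect significant (p <= 0.05) in {len(sig)}/8 genus x metric rows")


if __name__ == "__main__":
    main()
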