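"""Hourly environmental covariates.

Builds the modeling covariates for every monitored hour: month and season,
diel phase from the sun table, tide covariates (signed time to high water,
phase, range), pooled POD temperature and the per-pod hourly Nall noise
proxy.
"""

import argparse

import pandas as pd

from podcompare import pipeline as P


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--days", type=int, default=444)
    args = ap.parse_args()
    P.run_pipeline(P.demo_scenario(n_days=args.days), args.out, seed=args.seed, stages=["covariates"])
    cov = pd.read_csv(f"{args.out}/covariates/hourly.csv", index_col=0)
    print(f"{len(cov)} hourly covariate rows; diel split: "
          f"{cov['diel_period'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
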