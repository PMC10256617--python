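"""Collate the comparison report.

Brings the per-stage outputs together: per-filter totals and Kendall
agreement, overall and seasonal detection ratios, buzz summaries,
side-by-side effect tables, and the two headline figures.
"""

import argparse
import json

from podcompare import pipeline as P


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--days", type=int, default=444)
    args = ap.parse_args()
    P.run_pipeline(P.demo_scenario(n_days=args.days), args.out, seed=args.seed, stages=["compare"])
    headline = json.loads(open(f"{args.out}/report/headline.json").read())
    for k, v in headline.items():
        print(f"{k}: {v:.3f}")


if __name__ == "__main__":
    main()
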