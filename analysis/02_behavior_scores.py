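"""Score the simulated behavior: per-bin PC/RT/BIS and per-session trends.

Reads results/data, writes results/behavior/{bin_scores.csv, trends.csv}.
"""

import argparse
from pathlib import Path

from vigil.data import read_dataset
from vigil.scoring import score_trials, trends_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/behavior")
    args = ap.parse_args()
    trials, _ = read_dataset(args.data)
    bins = score_trials(trials)
    trends = trends_table(bins)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    bins.to_csv(out / "bin_scores.csv", index=False)
    trends.to_csv(out / "trends.csv", index=False)
    neg = (trends["slope"] < 0).mean()
    print(f"{len(trends)} sessions; {neg:.0%} with negative BIS slope")


if __name__ == "__main__":
    main()
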