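"""Simulate the desk-scale dataset (behavior + labeled EEG epochs).

Writes results/data/{trials.csv, epochs.npy, epochs_meta.csv,
epochs_meta.json}.
"""

import argparse

from vigil.config import desk_scale_config
from vigil.pipeline import RunConfig, write_simulated_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()
    run_cfg = RunConfig(sim=desk_scale_config(seed=args.seed), seed=args.seed)
    path = write_simulated_dataset(run_cfg, args.out)
    print(f"dataset written to {path}")


if __name__ == "__main__":
    main()
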