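"""Extract the 320 spectral band-power features per labeled epoch.

Reads results/data, writes results/features.npy (raw, pre-log power;
per-fold standardization happens inside the cross-validation).
"""

import argparse
from pathlib import Path

import numpy as np

from vigil.data import read_dataset
from vigil.spectral import morlet_band_power


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/features.npy")
    args = ap.parse_args()
    _, epochs = read_dataset(args.data)
    if epochs is None:
        raise SystemExit(f"no epochs stored in {args.data}")
    feats = morlet_band_power(epochs)
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    np.save(out, feats.values.astype(np.float32))
    print(f"{feats.values.shape[0]} epochs x {feats.n_features} features")


if __name__ == "__main__":
    main()
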