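"""Architecture accounting: TCN receptive fields and MLPNN parameter count.

Writes results/architecture.json.
"""

import argparse
import json
from pathlib import Path

from vigil.config import MLPConfig
from vigil.models import build_mlpnn, receptive_field


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/architecture.json")
    args = ap.parse_args()
    table = [
        {"kernel_size": k, "n_blocks": b, "final_dilation": d,
         "receptive_field": receptive_field(k, b, d)}
        for (k, b, d) in [(2, 2, 32), (4, 2, 32), (2, 1, 8), (2, 2, 8)]
    ]
    mlp = build_mlpnn(MLPConfig())
    payload = {
        "tcn_receptive_fields": table,
        "mlpnn_parameters": mlp.n_parameters,
    }
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(payload, indent=1))
    print(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
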