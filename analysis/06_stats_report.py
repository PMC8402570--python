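"""Statistical report over one or two CV runs.

Reads the predictions.csv of each run directory; prints Agresti-Coull
intervals (pooled and per participant) with the strict above-chance call,
and, when two runs are given, the difference-of-proportions interval and
McNemar's test on the shared validation epochs.
"""

import argparse
from pathlib import Path

import pandas as pd

from vigil.stats import (
    agresti_coull_ci,
    discordant_counts,
    format_ci,
    mcnemar,
    report_table,
    significant_vs_chance,
    two_proportion_diff_ci,
)


def _load(run_dir: str) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "predictions.csv")


def _accuracy_rows(name: str, pred: pd.DataFrame) -> list[dict]:
    rows = [dict(model=name, unit="pooled",
                 correct=int((pred.y_true == pred.y_pred).sum()),
                 n=len(pred))]
    for pid, g in pred.groupby("participant_id"):
        rows.append(dict(model=name, unit=pid,
                         correct=int((g.y_true == g.y_pred).sum()), n=len(g)))
    return rows


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("runs", nargs="+",
                    help="One or two run directories holding predictions.csv")
    args = ap.parse_args()
    preds = {Path(r).name: _load(r) for r in args.runs[:2]}

    rows = []
    for name, pred in preds.items():
        rows += _accuracy_rows(name, pred)
    print(report_table(rows).to_string(index=False))

    if len(preds) == 2:
        (na, a), (nb, b) = preds.items()
        xa = int((a.y_true == a.y_pred).sum())
        xb = int((b.y_true == b.y_pred).sum())
        d, lo, hi = two_proportion_diff_ci(xa, len(a), xb, len(b))
        print(f"\naccuracy difference {na} - {nb}: "
              f"{d:.3f} (95% CI {lo:.3f}, {hi:.3f})")
        if len(a) == len(b) and (a.y_true == b.y_true).all():
            bb, cc = discordant_counts(a.y_true, a.y_pred, b.y_pred)
            m = mcnemar(bb, cc)
            print(f"McNemar (b={m.b}, c={m.c}): chi2={m.statistic:.3f}, "
                  f"p={m.p_value:.4f}")
        else:
            print("runs validate on different epochs; McNemar skipped")


if __name__ == "__main__":
    main()
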