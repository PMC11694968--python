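"""Three-step best-model selection and summary tables.

Per (model, learning mode) the feature count maximizing the mean training
GMEAN is chosen; the group winners are then ranked by mean test GMEAN.
Also exports the mean±SD GMEAN curves per model for plotting.
"""

import json
from pathlib import Path

import pandas as pd

from injurypred import experiment

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    agg = pd.read_csv(OUT / "sweep.csv")
    report = experiment.select_best(agg)
    report.to_json(OUT / "best_models.json")
    curves = agg[
        ["model", "cost_sensitive", "p",
         "train_gmean_mean", "train_gmean_std",
         "test_gmean_mean", "test_gmean_std"]
    ]
    curves.to_csv(OUT / "gmean_curves.csv", index=False)
    print("group winners (ranked by test GMEAN):")
    for g in report.groups:
        mode = "cost-sensitive" if g["cost_sensitive"] else "traditional"
        print(
            f"  {g['model']:8s} {mode:14s} p={g['p']:3d}  "
            f"train GMEAN {100 * g['train_gmean']:6.2f}%  "
            f"test GMEAN {100 * g['test_gmean']:6.2f}%  "
            f"test AUC {g['test_auc']:.2f}"
        )
    w = report.overall
    print(
        f"best model: {w['model']} "
        f"({'cost-sensitive' if w['cost_sensitive'] else 'traditional'}, "
        f"p={w['p']})"
    )


if __name__ == "__main__":
    main()
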