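"""Whole-cohort fingerprinting under tangent, non-tangent and geodesic
distances.

Runs the full pipeline on the default synthetic cohort for each method and
tabulates ROC-AUC, PR-AUC, peak accuracy and the Delta separability margin
(smallest between-subject minus largest within-subject distance).
"""

from pathlib import Path

import pandas as pd

from connectofp import CohortConfig, ExperimentConfig, generate_cohort, run_fingerprint

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    recordings = generate_cohort(CohortConfig(seed=0))
    rows = []
    for method in ("tangent", "non_tangent", "geodesic"):
        res = run_fingerprint(recordings, ExperimentConfig(method=method, lam=1.0))
        rows.append(
            {
                "method": method,
                "auc_roc": res.auc_roc,
                "auc_pr": res.auc_pr,
                "max_acc": res.max_acc,
                "argmax_theta": res.argmax_theta,
                "delta": res.delta,
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "fingerprint_summary.csv", index=False)
    print(table.to_string(index=False))
    best = table.loc[table.delta.idxmax()]
    print(
        f"\nAll methods separate this strongly fingerprinted cohort "
        f"(AUC {table.auc_roc.min():.3f}-{table.auc_roc.max():.3f}); the "
        f"largest separability margin is Delta={best.delta:.3f} "
        f"({best.method})."
    )


if __name__ == "__main__":
    main()
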