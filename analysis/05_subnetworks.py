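"""Per-subnetwork fingerprinting.

Splits the parcellation into named subnetworks (one deliberately below the
10-region filter), restricts FCs to each surviving subnetwork, rebuilds
the tangent reference in the restricted space, and compares tangent vs
non-tangent AUC per condition. A moderate-distinctiveness cohort keeps the
comparison off the AUC ceiling.
"""

from pathlib import Path

import pandas as pd

from connectofp import (
    CohortConfig,
    ConditionSpec,
    ExperimentConfig,
    SubnetworkDefinition,
    generate_cohort,
    subnetwork_fingerprint,
)

ROOT = Path(__file__).resolve().parents[1]

ATLAS = [
    SubnetworkDefinition("VIS", tuple(range(0, 12))),
    SubnetworkDefinition("FPN", tuple(range(12, 24))),
    SubnetworkDefinition("SAL", tuple(range(24, 30))),  # < 10 regions: dropped
]


def main() -> None:
    cfg = CohortConfig(
        distinctiveness=0.3,
        session_noise=0.4,
        n_frames=100,
        conditions=(
            ConditionSpec("rest"),
            ConditionSpec("motor", modulation=0.6, regions=tuple(range(0, 12))),
        ),
        seed=0,
    )
    recordings = generate_cohort(cfg)
    table = subnetwork_fingerprint(recordings, ATLAS, ExperimentConfig(seed=0))
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "subnetwork_auc.csv", index=False)
    print(table.to_string(index=False))
    wide = table.pivot_table(index=["subnetwork", "condition"], columns="method", values="auc")
    gain = (wide["tangent"] - wide["non_tangent"]).mean()
    print(
        f"\nThe sub-10-region SAL block was filtered out. Across the "
        f"surviving subnetworks and conditions the tangent method gains "
        f"{gain:+.3f} AUC on average over the non-tangent method."
    )


if __name__ == "__main__":
    main()
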