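"""Temporal stability: drift across sessions and within-session blocks.

First, the distance from each subject's first-session FC to every later
session's FC, with a permutation test on the pooled slope (the generator's
sessions are exchangeable, so no trend is expected). Second, recordings
are split into two blocks each: per-session covariance perturbations make
same-session block pairs measurably closer than different-session pairs.
"""

import json
from pathlib import Path

import pandas as pd

from connectofp import (
    CohortConfig,
    ExperimentConfig,
    drift_analysis,
    generate_cohort,
    session_block_analysis,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    recordings = generate_cohort(CohortConfig(seed=0))
    cfg = ExperimentConfig(method="tangent", seed=0)

    drift = drift_analysis(recordings, cfg)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame({"lag": drift.lags, "mean": drift.mean, "sd": drift.sd}).to_csv(
        out / "drift.csv", index=False
    )
    print(
        f"Drift: slope {drift.slope:+.4f} per session lag, permutation "
        f"p = {drift.p_value:.3f} — "
        + ("no significant trend." if drift.p_value >= 0.05 else "trend detected.")
    )

    blocks = session_block_analysis(recordings, 2, cfg)
    summary = {
        "within_session_mean": blocks.within_mean,
        "between_session_mean": blocks.between_mean,
        "p_value": blocks.p_value,
        "n_within": blocks.n_within,
        "n_between": blocks.n_between,
    }
    (out / "session_blocks.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"Blocks: same-session pairs mean {blocks.within_mean:.3f} vs "
        f"different-session {blocks.between_mean:.3f} "
        f"(Mann-Whitney p = {blocks.p_value:.2e}) — session-level "
        "perturbations leave a detectable within-session signature."
    )


if __name__ == "__main__":
    main()
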