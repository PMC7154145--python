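"""Parameter recovery: the protocol's estimates track the generative truth.

Sweeps the generative criterion with sensitivity held fixed and confirms
that both the estimated criterion c and the measured threshold rise
monotonically — the core mechanism claim: a more conservative observer
yields higher method-of-limits thresholds without any sensory change.  Then
regresses estimated c on true criterion across 500 heterogeneous observers.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from touchlimits.studies import criterion_recovery_regression, criterion_recovery_sweep

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    sweep = criterion_recovery_sweep(sessions_per_level=200, seed=seed)
    tab = pd.DataFrame(
        {
            "lam": sweep.lam_grid,
            "mean_estimated_c": sweep.mean_c,
            "mean_threshold_g": sweep.mean_threshold,
        }
    )
    RESULTS.mkdir(parents=True, exist_ok=True)
    tab.to_csv(RESULTS / "criterion_recovery_sweep.csv", index=False)
    print(tab.round(4).to_string(index=False))
    rho = sps.spearmanr(sweep.lam_grid, sweep.mean_c).statistic
    print(f"\nSpearman(lam, mean c) = {rho:.2f}; "
          f"threshold strictly increasing: {bool(np.all(np.diff(sweep.mean_threshold) > 0))}")
    slope, p, n = criterion_recovery_regression(seed=seed + 1)
    print(f"estimated c on true criterion across {n} observers: "
          f"slope = {slope:.3f}, p = {p:.2e}")


if __name__ == "__main__":
    main()
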