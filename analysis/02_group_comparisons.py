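"""Group comparisons: thresholds, A_z and c by diagnosis and age band.

Reads the session summary written by 01_simulate_cohort.py (regenerating it
if absent) and reports Cliff's delta with 95% CI for each variable, overall
and within the child/adolescent and adult subsamples — the analogue of a
descriptives-and-effect-sizes table for a skewed psychophysical outcome.
"""

from pathlib import Path

import pandas as pd

from touchlimits.stats import group_comparison_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SESSIONS = RESULTS / "study" / "sessions.csv"

VARIABLES = ["age_years", "viq", "piq", "fsiq", "srs_t", "threshold_g", "az", "c"]


def main() -> None:
    if not SESSIONS.exists():
        import importlib

        importlib.import_module("01_simulate_cohort").main()  # pragma: no cover
    df = pd.read_csv(SESSIONS)
    ok = df[~df["excluded"]]
    for label, sub in (
        ("whole sample", ok),
        ("children/adolescents", ok[ok["age_band"] == "child"]),
        ("adults", ok[ok["age_band"] == "adult"]),
    ):
        tab = group_comparison_table(sub, [v for v in VARIABLES if v in sub])
        dest = RESULTS / f"comparisons_{label.split('/')[0].split()[0]}.csv"
        tab.to_csv(dest, index=False)
        print(f"\n== {label} (n = {len(sub)}) ==")
        print(
            tab[["variable", "delta", "ci_low", "ci_high", "p"]]
            .round(3)
            .to_string(index=False)
        )


if __name__ == "__main__":
    main()
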