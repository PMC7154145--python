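"""End-to-end orchestration: simulate -> score -> compare -> regress.

`run_study` drives a full simulated study from a single config and seed and
writes tidy CSV artifacts (participants, trial log, session summaries,
group-comparison tables, regression tables, model-search JSON) plus a run
manifest.  `analyze_external` applies the same statistical battery to an
existing session-summary table, so real exports with the documented columns
take the identical code path as simulated data.

A single master seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence``, so cohort generation, protocol simulation and
any analysis resampling are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cpm import mechanism_scenario, wald_summary
from .observer import (
    CohortSpec,
    cohort_spec_from_yaml,
    cohort_to_frame,
    default_cohort_spec,
    generate_cohort,
)
from .protocol import (
    FilamentSet,
    ProtocolConfig,
    block_threshold,
    simulate_sessions,
    trials_to_frame,
)
from .stats import group_comparison_table, icc_consistency, spearman_corr

__all__ = ["RunConfig", "run_study", "analyze_external", "score_cohort"]

#: session-summary columns the analysis stages require
REQUIRED_ANALYSIS_COLUMNS = (
    "threshold_g",
    "diagnosis",
    "age_years",
    "sex",
    "counterbalance",
    "az",
    "c",
)

COMPARISON_VARIABLES = (
    "age_years", "viq", "piq", "fsiq", "srs_t", "threshold_g", "az", "c",
)


class SchemaError(ValueError):
    """Raised when an external dataset lacks required columns."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort: CohortSpec
    protocol: ProtocolConfig = ProtocolConfig()
    seed: int = 0
    candidate_predictors: tuple[str, ...] = ("az", "c")
    criterion_col: str = "c"
    out_dir: str = "results"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = (
            cohort_spec_from_yaml(raw["cohort_spec"])
            if "cohort_spec" in raw
            else default_cohort_spec()
        )
        prot = raw.get("protocol", {})
        if "filaments" in prot:
            prot["filaments"] = FilamentSet(tuple(prot["filaments"]))
        protocol = ProtocolConfig(**prot)
        return RunConfig(
            cohort=cohort,
            protocol=protocol,
            seed=int(raw.get("seed", 0)),
            candidate_predictors=tuple(raw.get("candidate_predictors", ("az", "c"))),
            criterion_col=str(raw.get("criterion_col", "c")),
            out_dir=str(raw.get("out_dir", "results")),
        )


def _child_seeds(seed: int, n: int = 3) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def score_cohort(config: RunConfig):
    """Simulate the cohort and its sessions; returns (records, sessions, summary)."""
    cohort_seed, protocol_seed, _ = _child_seeds(config.seed)
    spec = dataclasses.replace(config.cohort, seed=cohort_seed)
    records = generate_cohort(spec)
    sessions, summary = simulate_sessions(records, config.protocol, seed=protocol_seed)
    return records, sessions, summary


def _comparison_tables(summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    ok = summary[~summary["excluded"]] if "excluded" in summary else summary
    tables = {}
    variables = [v for v in COMPARISON_VARIABLES if v in ok.columns]
    tables["whole"] = group_comparison_table(ok, variables)
    if "age_band" in ok.columns:
        for band in ("child", "adult"):
            sub = ok[ok["age_band"] == band]
            if sub["diagnosis"].nunique() == 2:
                tables[band] = group_comparison_table(sub, variables)
    return tables


def _regression_tables(summary: pd.DataFrame, config: RunConfig):
    ok = summary.dropna(subset=["threshold_g"])
    candidates = tuple(c for c in config.candidate_predictors if c in ok.columns)
    report = mechanism_scenario(
        ok,
        criterion_col=config.criterion_col,
        candidate_cols=candidates,
    )
    base = report.baseline.table.copy()
    base["model"] = "baseline"
    aug = report.augmented.table.copy()
    aug["model"] = "baseline+c"
    table = pd.concat([base, aug]).rename_axis("predictor").reset_index()
    search = {
        "subsets": [list(s) for s in report.search.subsets],
        "bic": report.search.bics.tolist(),
        "weights": report.search.weights.tolist(),
        "best_subset": list(report.search.best_subset),
        "bf10_vs_baseline": report.search.bf10_vs_baseline,
        "mechanism": {
            "diagnosis_sig_baseline": report.diagnosis_sig_baseline,
            "criterion_selected": report.criterion_selected,
            "diagnosis_sig_augmented": report.diagnosis_sig_augmented,
            "criterion_largest_wald": report.criterion_largest_wald,
            "n": report.n,
        },
        "model_fit": {
            "baseline": {
                "lr_chi2": report.baseline.lr_chi2,
                "df": report.baseline.lr_df,
                "p": report.baseline.lr_p,
                "nagelkerke_r2": report.baseline.nagelkerke_r2,
            },
            "augmented": {
                "lr_chi2": report.augmented.lr_chi2,
                "df": report.augmented.lr_df,
                "p": report.augmented.lr_p,
                "nagelkerke_r2": report.augmented.nagelkerke_r2,
            },
        },
    }
    return table, search, report


def analyze_external(data: pd.DataFrame, config: RunConfig | None = None):
    """Statistical battery on an existing session-summary table.

    The table must carry the documented analysis columns; missing ones raise
    a SchemaError naming every absence.  Returns (comparison tables,
    regression table, model-search dict).
    """
    if config is None:
        config = RunConfig(cohort=default_cohort_spec())
    missing = [c for c in REQUIRED_ANALYSIS_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"dataset is missing required columns: {missing}")
    if "excluded" not in data.columns:
        data = data.assign(excluded=False)
    comparisons = _comparison_tables(data)
    regression, search, _ = _regression_tables(data, config)
    return comparisons, regression, search


def run_study(config: RunConfig, out_dir=None) -> dict:
    """Full simulated study; writes all artifacts and returns the manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, sessions, summary = score_cohort(config)

    participants = cohort_to_frame(records)
    trials = trials_to_frame(sessions)
    comparisons = _comparison_tables(summary)
    regression, search, _ = _regression_tables(summary, config)

    blocks = np.array(
        [
            [block_threshold(b, config.protocol.threshold_rule) for b in s.blocks]
            for s in sessions
            if not s.excluded
        ]
    )
    icc = icc_consistency(blocks) if blocks.shape[0] >= 2 else None

    participants.to_csv(out / "participants.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    summary.to_csv(out / "sessions.csv", index=False)
    for name, tab in comparisons.items():
        tab.to_csv(out / f"group_comparisons_{name}.csv", index=False)
    regression.to_csv(out / "regression_models.csv", index=False)
    with open(out / "model_search.json", "w") as fh:
        json.dump(search, fh, indent=2)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_participants": len(participants),
        "n_excluded": int(summary["excluded"].sum()),
        "icc_3k": None if icc is None else {
            "icc": icc.icc, "ci": [icc.ci_low, icc.ci_high], "k": icc.k,
        },
        "config_hash": hashlib.sha256(
            repr((config.cohort, config.protocol, config.seed,
                  config.candidate_predictors)).encode()
        ).hexdigest(),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
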