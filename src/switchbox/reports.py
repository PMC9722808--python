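"""Report builders tying the analysis stages together.

Every numeric cell produced here is computed by an operation in the core
modules — this layer only arranges results into tables and files, so the
command-line interface stays a thin shell over the library.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .classification import classify_strategy, first_intervention_summary
from .cohort import CohortSpec, generate_cohort, read_trial_log, write_trial_log
from .core import Condition, ParticipantRecord, TaskConfig
from .economics import PayoutRule, expected_policy_payout
from .information import participant_efficiency
from .policies import (
    PolicySpec,
    matched_random_cohort,
    participant_rng,
    run_policy,
)
from .stats import (
    ContingencyTable2x2,
    PowerDesign,
    bootstrap_mean_ci,
    fisher_exact_two_sided,
    fisher_power_simulation,
    proportion_table,
)


def write_manifest(out_dir: Path, seed: Optional[int], **extra) -> Path:
    """Record what produced a report bundle; every bundle names one."""
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "switchbox",
        "version": __version__,
        "seed": seed,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def strategy_table(
    cohort: Sequence[ParticipantRecord],
    config: TaskConfig,
    optimality_mode: str = "rule",
) -> pd.DataFrame:
    """Strategy proportions per cell with info-optimal bracket counts.

    One row per (age_group, condition, label) with the count, the within-
    cell proportion among classifiable sessions, and the bracketed count of
    sessions that were additionally information-optimal.
    """
    rows = []
    for p in cohort:
        cfg = replace(config, condition=Condition(p.condition))
        lab = classify_strategy(p.trials, cfg, optimality_mode=optimality_mode)
        rows.append(
            {
                "age_group": p.age_group,
                "condition": Condition(p.condition).value,
                "label": lab.label,
                "info_optimal": lab.info_optimal,
            }
        )
    df = pd.DataFrame(rows)
    classifiable = df[df["label"] != "unclassifiable"]
    out = (
        classifiable.groupby(["age_group", "condition", "label"])
        .agg(n=("label", "size"), n_info_optimal=("info_optimal", "sum"))
        .reset_index()
    )
    cell_totals = classifiable.groupby(["age_group", "condition"])[
        "label"
    ].size()
    out["proportion"] = out.apply(
        lambda r: r["n"] / cell_totals[(r["age_group"], r["condition"])],
        axis=1,
    )
    out["n_unclassifiable"] = out.apply(
        lambda r: int(
            (
                (df["age_group"] == r["age_group"])
                & (df["condition"] == r["condition"])
                & (df["label"] == "unclassifiable")
            ).sum()
        ),
        axis=1,
    )
    return out


def efficiency_table(
    cohort: Sequence[ParticipantRecord], config: TaskConfig
) -> pd.DataFrame:
    """Per-participant mean intervention efficiency."""
    rows = []
    for p in cohort:
        cfg = replace(config, condition=Condition(p.condition))
        score = participant_efficiency(p.trials, cfg)
        rows.append(
            {
                "participant_id": p.participant_id,
                "age_group": p.age_group,
                "condition": Condition(p.condition).value,
                "n_trials": p.n_trials,
                "mean_efficiency": score.participant_mean,
            }
        )
    return pd.DataFrame(rows)


def baseline_comparison(
    cohort: Sequence[ParticipantRecord],
    config: TaskConfig,
    seed: int,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Participant efficiency vs simulated baselines, per condition.

    Baselines: matched random interveners (yoked trial counts), pure
    test-one learners and pure split-half learners, one simulant per
    participant with the participant's condition and target.
    """

    def summarise(records, who):
        eff = efficiency_table(records, config)
        rows = []
        for cond, sub in eff.groupby("condition"):
            vals = sub["mean_efficiency"].dropna().tolist()
            lo, hi = bootstrap_mean_ci(vals, level=ci_level, seed=seed)
            rows.append(
                {
                    "source": who,
                    "condition": cond,
                    "n": len(vals),
                    "mean_efficiency": sum(vals) / len(vals),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return rows

    rows = summarise(cohort, "participants")
    rows += summarise(
        matched_random_cohort(cohort, config, seed=seed), "random_matched"
    )
    for kind in ("test_one", "split_half"):
        sims = []
        for i, p in enumerate(cohort):
            cfg = replace(config, condition=Condition(p.condition))
            trials = run_policy(
                PolicySpec(kind=kind),
                cfg,
                p.target_switch,
                rng=participant_rng(seed + 1, i),
            )
            sims.append(
                ParticipantRecord(
                    participant_id=f"{kind}_{p.participant_id}",
                    age_group=p.age_group,
                    condition=cfg.condition,
                    target_switch=p.target_switch,
                    trials=tuple(trials),
                    planted_strategy=kind,
                )
            )
        rows += summarise(sims, f"pure_{kind}")
    return pd.DataFrame(rows)


def accuracy_contingency(
    cohort: Sequence[ParticipantRecord],
    config: TaskConfig,
    strategy: str = "test_multiple",
    condition: Optional[Condition] = None,
) -> tuple[ContingencyTable2x2, float]:
    """Age-group x guess-accuracy table within a strategy class + Fisher p."""
    kept, labels = [], []
    for p in cohort:
        if condition is not None and Condition(p.condition) != condition:
            continue
        cfg = replace(config, condition=Condition(p.condition))
        kept.append(p)
        labels.append(classify_strategy(p.trials, cfg).label)
    table = proportion_table(kept, labels, restrict_to=strategy)
    return table, fisher_exact_two_sided(table)


def analyze_cohort(
    cohort: Sequence[ParticipantRecord],
    config: TaskConfig,
    out_dir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Run the full analysis bundle on a cohort and write CSV reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    first = first_intervention_summary(cohort)
    written["first_intervention"] = out_dir / "first_intervention.csv"
    first.to_csv(written["first_intervention"], index=False)

    strat = strategy_table(cohort, config)
    written["strategy_table"] = out_dir / "strategy_table.csv"
    strat.to_csv(written["strategy_table"], index=False)

    eff = efficiency_table(cohort, config)
    written["efficiency"] = out_dir / "efficiency.csv"
    eff.to_csv(written["efficiency"], index=False)

    base = baseline_comparison(cohort, config, seed=seed)
    written["baselines"] = out_dir / "baseline_comparison.csv"
    base.to_csv(written["baselines"], index=False)

    contingency_rows = []
    for cond in (Condition.SPARSE, Condition.DENSE, None):
        try:
            table, p = accuracy_contingency(cohort, config, condition=cond)
        except ValueError:
            continue
        contingency_rows.append(
            {
                "condition": cond.value if cond else "both",
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "fisher_p": round(p, 4),
            }
        )
    written["contingency"] = out_dir / "accuracy_contingency.csv"
    pd.DataFrame(contingency_rows).to_csv(written["contingency"], index=False)

    written["manifest"] = write_manifest(
        out_dir, seed, reports=sorted(k for k in written)
    )
    return written


def generate_and_write(
    spec: CohortSpec,
    config: TaskConfig,
    out_dir: str | Path,
    include_planted: bool = False,
) -> dict[str, Path]:
    """Generate a synthetic cohort and write its trial/guess logs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, config)
    trials_path, guesses_path = write_trial_log(
        cohort,
        out_dir / "trials.csv",
        include_planted=include_planted,
        n_switches=config.n_switches,
    )
    manifest = write_manifest(
        out_dir,
        spec.seed,
        n_participants=len(cohort),
        cells=[asdict(c) for c in spec.cells],
    )
    return {
        "trials": trials_path,
        "guesses": guesses_path,
        "manifest": manifest,
    }


def power_report(design: PowerDesign, target_power: float = 0.80) -> dict:
    """Power estimate with SE and the planning decision vs a target."""
    est = fisher_power_simulation(design)
    return {
        "n_per_group": design.n_per_group,
        "p1": design.p1,
        "p2": design.p2,
        "alpha": design.alpha,
        "replicates": est.replicates,
        "power": est.power,
        "se": est.se,
        "target_power": target_power,
        "meets_target": est.power >= target_power,
    }
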