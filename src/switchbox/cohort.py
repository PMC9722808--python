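"""Synthetic participant cohorts with the statistical structure of the study.

Each simulated participant is assigned a *planted* strategy drawn from a
per-cell mixture over ``test_one`` (single-switch tester),
``test_multiple_split_half`` (half-splitter) and ``other_switcher``
(alternates between the two), runs that policy until at most
``guess_threshold`` candidates remain or the tokens run out, and then
guesses. With probability ``inference_noise`` the participant fails to
integrate the evidence and guesses uniformly over *all* switches (the
candidate set of a non-integrating learner); otherwise the guess is the
deduced answer when certain, or uniform over the remaining candidates.
Wrong guesses are verified for free and eliminate the guessed switch;
guessing repeats until correct, but only a correct *first* guess pays out.

The noise parameter places the younger children's deficit where the study
locates it — in drawing reliable causal inferences from evidence, not in
choosing interventions — so raising it lowers guess accuracy without
touching the intervention sequence.

Default cell sizes and strategy mixtures approximate the study's reported
first-intervention cross-tabulation; they are configuration, not ground
truth.

Log schema (CSV, invented since the original box logs are unpublished):
``trials``: participant_id, age_group, condition, target_switch,
trial_index, s1..sN (0/1), lights_on (0/1) [, planted_strategy];
``guesses``: participant_id, guess_index, guessed_switch, verified_correct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BeliefState,
    Condition,
    GuessRecord,
    ParticipantRecord,
    TaskConfig,
    TrialRecord,
    update_belief,
)
from .economics import PayoutRule, realized_payout
from .policies import PolicySpec, participant_rng, run_policy

PLANTED_STRATEGIES = ("test_one", "test_multiple_split_half", "other_switcher")

_POLICY_FOR_STRATEGY = {
    "test_one": "test_one",
    "test_multiple_split_half": "split_half",
    "other_switcher": "switcher",
}


@dataclass(frozen=True)
class CellSpec:
    """One age-group x condition cell of the cohort design."""

    age_group: str
    condition: Condition
    n_participants: int
    strategy_mixture: tuple[float, float, float]  # over PLANTED_STRATEGIES
    inference_noise: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        mix = tuple(float(p) for p in self.strategy_mixture)
        if len(mix) != 3 or any(p < 0 for p in mix):
            raise ValueError("strategy_mixture needs 3 non-negative weights")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("strategy_mixture must sum to 1")
        if not 0.0 <= self.inference_noise <= 1.0:
            raise ValueError("inference_noise must lie in [0, 1]")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        object.__setattr__(self, "strategy_mixture", mix)


def default_cells() -> tuple[CellSpec, ...]:
    """Study-sized cells with mixtures set from the reported first-test
    one/multiple percentages (scaled to leave a 0.2 switcher share) and an
    inference-noise gap between age groups."""
    table = [
        # age, condition, n, pct test-one on first trial
        ("younger", Condition.SPARSE, 24, 62.5),
        ("younger", Condition.DENSE, 29, 79.3),
        ("older", Condition.SPARSE, 28, 39.3),
        ("older", Condition.DENSE, 23, 60.9),
    ]
    noise = {"younger": 0.65, "older": 0.10}
    cells = []
    for age, cond, n, pct_one in table:
        p1 = 0.8 * pct_one / 100.0
        cells.append(
            CellSpec(
                age_group=age,
                condition=cond,
                n_participants=n,
                strategy_mixture=(p1, 0.8 - p1, 0.2),
                inference_noise=noise[age],
            )
        )
    return tuple(cells)


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort design: cells, guessing rule and the global seed."""

    cells: tuple[CellSpec, ...] = field(default_factory=default_cells)
    guess_threshold: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        if self.guess_threshold < 1:
            raise ValueError("guess_threshold must be >= 1")


def _simulate_guesses(
    belief: BeliefState,
    target: int,
    noise: float,
    config: TaskConfig,
    rng: np.random.Generator,
) -> list[GuessRecord]:
    noisy = bool(rng.random() < noise)
    if noisy:
        pool = set(config.all_switches)
    elif belief.is_certain:
        pool = {belief.sole_candidate}
    else:
        pool = set(belief.candidates)
    guesses: list[GuessRecord] = []
    while True:
        guess = int(rng.choice(sorted(pool)))
        correct = guess == target
        guesses.append(GuessRecord(guess, correct))
        if correct:
            return guesses
        pool.discard(guess)  # free verification eliminates the guess


def generate_cohort(
    spec: CohortSpec, config: TaskConfig
) -> list[ParticipantRecord]:
    """Generate a fully reproducible synthetic cohort.

    ``config`` supplies the box and token parameters; its condition field
    is overridden per cell.
    """
    rule = PayoutRule(n_tokens=config.n_tokens, token_value=config.token_value)
    cohort: list[ParticipantRecord] = []
    idx = 0
    for cell in spec.cells:
        cfg = replace(config, condition=cell.condition)
        for _ in range(cell.n_participants):
            rng = participant_rng(spec.seed, idx)
            strategy = PLANTED_STRATEGIES[
                int(rng.choice(3, p=cell.strategy_mixture))
            ]
            target = int(rng.integers(1, cfg.n_switches + 1))
            policy = PolicySpec(kind=_POLICY_FOR_STRATEGY[strategy])
            trials = run_policy(
                policy, cfg, target, rng=rng,
                stop_at_candidates=spec.guess_threshold,
            )
            belief = BeliefState.full(cfg)
            for t in trials:
                belief = update_belief(belief, t.on_set, t.lights_on, cfg)
            guesses = _simulate_guesses(
                belief, target, cell.inference_noise, cfg, rng
            )
            payout = realized_payout(len(trials), guesses[0].correct, rule)
            cohort.append(
                ParticipantRecord(
                    participant_id=f"p{idx:03d}",
                    age_group=cell.age_group,
                    condition=cell.condition,
                    target_switch=target,
                    trials=tuple(trials),
                    guesses=tuple(guesses),
                    payout=payout,
                    planted_strategy=strategy,
                )
            )
            idx += 1
    return cohort


# ---------------------------------------------------------------------------
# CSV round-trip


class TrialLogError(ValueError):
    """A trial/guess log failed to parse; the message names row and field."""


def guesses_path_for(trials_path: str | Path) -> Path:
    p = Path(trials_path)
    return p.with_name(p.stem + "_guesses" + (p.suffix or ".csv"))


def write_trial_log(
    cohort: Sequence[ParticipantRecord],
    trials_path: str | Path,
    guesses_path: Optional[str | Path] = None,
    include_planted: bool = False,
    n_switches: int = 6,
) -> tuple[Path, Path]:
    """Write a cohort to the trials + guesses CSV pair; returns both paths."""
    trials_path = Path(trials_path)
    guesses_path = (
        Path(guesses_path) if guesses_path else guesses_path_for(trials_path)
    )
    trial_rows, guess_rows = [], []
    for p in cohort:
        for i, t in enumerate(p.trials, start=1):
            row = {
                "participant_id": p.participant_id,
                "age_group": p.age_group,
                "condition": Condition(p.condition).value,
                "target_switch": p.target_switch,
                "trial_index": i,
                **{
                    f"s{s}": int(s in t.on_set)
                    for s in range(1, n_switches + 1)
                },
                "lights_on": int(t.lights_on),
            }
            if include_planted:
                row["planted_strategy"] = p.planted_strategy or ""
            trial_rows.append(row)
        for j, g in enumerate(p.guesses, start=1):
            guess_rows.append(
                {
                    "participant_id": p.participant_id,
                    "guess_index": j,
                    "guessed_switch": g.guessed_switch,
                    "verified_correct": int(g.correct),
                }
            )
    pd.DataFrame(trial_rows).to_csv(trials_path, index=False)
    cols = ["participant_id", "guess_index", "guessed_switch",
            "verified_correct"]
    pd.DataFrame(guess_rows, columns=cols).to_csv(guesses_path, index=False)
    return trials_path, guesses_path


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise TrialLogError(f"{what} log is missing column {c!r}")


def read_trial_log(
    trials_path: str | Path,
    config: TaskConfig,
    guesses_path: Optional[str | Path] = None,
    rule: Optional[PayoutRule] = None,
) -> list[ParticipantRecord]:
    """Read a trials + guesses CSV pair back into participant records.

    Payout is recomputed from the payment rule (default: derived from
    ``config``), so the round-trip is lossless for cohorts written by this
    package. The planted-strategy column is restored when present.
    """
    trials_path = Path(trials_path)
    guesses_path = (
        Path(guesses_path) if guesses_path else guesses_path_for(trials_path)
    )
    rule = rule or PayoutRule(
        n_tokens=config.n_tokens, token_value=config.token_value
    )
    df = pd.read_csv(trials_path)
    _require_columns(
        df,
        ["participant_id", "age_group", "condition", "target_switch",
         "trial_index", "lights_on"],
        "trial",
    )
    switch_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"s\d+", c)),
        key=lambda c: int(c[1:]),
    )
    if [int(c[1:]) for c in switch_cols] != list(
        range(1, config.n_switches + 1)
    ):
        raise TrialLogError(
            f"expected switch columns s1..s{config.n_switches}, "
            f"found {switch_cols}"
        )
    has_planted = "planted_strategy" in df.columns
    gdf = pd.read_csv(guesses_path) if Path(guesses_path).exists() else None
    if gdf is not None and len(gdf):
        _require_columns(
            gdf,
            ["participant_id", "guess_index", "guessed_switch",
             "verified_correct"],
            "guess",
        )
    cohort: list[ParticipantRecord] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index")
        if list(grp["trial_index"]) != list(range(1, len(grp) + 1)):
            raise TrialLogError(
                f"participant {pid}: trial_index not consecutive from 1"
            )
        trials = []
        for row_pos, row in enumerate(grp.itertuples(index=True)):
            line = row.Index + 2  # header + 1-based
            try:
                on = frozenset(
                    s for s in range(1, config.n_switches + 1)
                    if int(getattr(row, f"s{s}")) == 1
                )
                for s in range(1, config.n_switches + 1):
                    if int(getattr(row, f"s{s}")) not in (0, 1):
                        raise ValueError(f"s{s} not 0/1")
                lights = int(row.lights_on)
                if lights not in (0, 1):
                    raise ValueError("lights_on not 0/1")
            except (ValueError, TypeError) as exc:
                raise TrialLogError(
                    f"line {line}: malformed trial row ({exc})"
                ) from exc
            trials.append(TrialRecord(on, bool(lights)))
        first = grp.iloc[0]
        target = int(first["target_switch"])
        config.validate_switch(target)
        guesses: tuple[GuessRecord, ...] = ()
        if gdf is not None and len(gdf):
            sub = gdf[gdf["participant_id"] == pid].sort_values("guess_index")
            guesses = tuple(
                GuessRecord(int(r.guessed_switch), bool(r.verified_correct))
                for r in sub.itertuples(index=False)
            )
        payout = (
            realized_payout(len(trials), guesses[0].correct, rule)
            if guesses else 0.0
        )
        cohort.append(
            ParticipantRecord(
                participant_id=str(pid),
                age_group=str(first["age_group"]),
                condition=Condition(str(first["condition"])),
                target_switch=target,
                trials=tuple(trials),
                guesses=guesses,
                payout=payout,
                planted_strategy=(
                    str(first["planted_strategy"])
                    if has_planted and pd.notna(first["planted_strategy"])
                    and str(first["planted_strategy"])
                    else None
                ),
            )
        )
    return cohort
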