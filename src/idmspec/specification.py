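"""The systematic step-down specification procedure.

Starting from the unrestricted illness-death model (transition-specific
effects and baselines), the procedure

1. tests the Markov assumption by the significance of the healthy-state
   sojourn time ``t010`` on the progression-to-death hazard
   (:func:`markov_test`);
2. assesses proportionality of the baseline hazards pairwise, by stacking
   two transitions in one stratum with a transition indicator and applying
   the Schoenfeld test to that indicator (:func:`baseline_tests`), plus
   log-log curves for the graphical check;
3. restricts the two death baselines to proportionality, adding the
   exp(gamma) term (:func:`apply_proportional_baselines`);
4. reduces the model greedily (:func:`reduce`): equality of a covariate's
   effects across transitions, then pruning of insignificant main effects,
   each move accepted only when the likelihood-ratio test against the
   current model is non-significant and the AIC does not increase.

``t010`` is exempt from reduction: once the Markov assumption is rejected
it is the structural justification of the semi-Markov model, not an
ordinary covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from . import cox_engine
from .cox_engine import CoxError, FittedModel
from .structures import (
    DEATH_TRANSITIONS,
    DEFAULT_COVARIATES,
    Effect,
    EffectStructure,
    ProportionalTerm,
    StructureError,
    T010,
    full_structure,
)

__all__ = [
    "MarkovTestResult",
    "BaselineTestResult",
    "Move",
    "ReductionStep",
    "markov_test",
    "baseline_tests",
    "apply_proportional_baselines",
    "evaluate_move",
    "reduce",
]


@dataclass
class MarkovTestResult:
    """Effect of the healthy-state sojourn time on the 1->2 hazard."""

    coef: float
    se: float
    hr: float
    wald_p: float
    lr_stat: float
    lr_p: float
    with_t010: FittedModel
    without_t010: FittedModel

    @property
    def reject_markov(self) -> bool:
        return self.wald_p < 0.05


def markov_test(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ties: str = "breslow",
) -> MarkovTestResult:
    """Test whether survival after progression depends on time to progression.

    Fits the full transition-specific model with and without ``t010`` on the
    1->2 hazard.  A significant coefficient rejects the Markov assumption in
    favour of the (non-homogeneous) semi-Markov model.
    """
    sub12 = table[table["transition"] == "12"]
    if len(sub12) == 0 or sub12["status"].sum() == 0:
        raise CoxError("no progression-to-death events; the Markov test is undefined")
    with_ = cox_engine.fit(table, full_structure(covariates, include_t010=True), ties=ties)
    without = cox_engine.fit(table, full_structure(covariates, include_t010=False), ties=ties)
    label = f"{T010}.12"
    _, _, lr_p = cox_engine.lr_test(without, with_)
    return MarkovTestResult(
        coef=with_.coef(label),
        se=with_.se_of(label),
        hr=float(with_.summary().loc[label, "hr"]),
        wald_p=with_.wald_p(label),
        lr_stat=2.0 * (with_.loglik - without.loglik),
        lr_p=lr_p,
        with_t010=with_,
        without_t010=without,
    )


_ALL_STRATA_ONE = (frozenset({"01", "02", "12"}),)


@dataclass
class BaselineTestResult:
    """Pairwise baseline-proportionality tests plus log-log curve data."""

    pairwise: dict[tuple[str, str], tuple[float, float]]
    loglog: dict[str, "object"]
    full_model: FittedModel

    def p_value(self, a: str, b: str) -> float:
        return self.pairwise[tuple(sorted((a, b)))][1]


def baseline_tests(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    ties: str = "breslow",
    transform: str = "identity",
) -> BaselineTestResult:
    """Schoenfeld proportionality test for each pair of baseline hazards.

    For a pair of transitions the rows are stacked in a single stratum with
    all transition-specific covariate effects plus an indicator of the
    second transition; a time trend in the indicator's Schoenfeld residuals
    signals non-proportional baselines.  Log-log curves of the full model
    accompany the tests for the graphical check.
    """
    results: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(("01", "02", "12"), 2):
        sub = table[table["transition"].isin([a, b])].reset_index(drop=True)
        effects = [Effect(c, frozenset({t})) for t in (a, b) for c in covariates]
        if "12" in (a, b) and T010 in table.columns and table[T010].notna().any():
            effects.append(Effect(T010, frozenset({"12"})))
        structure = EffectStructure(
            effects=tuple(effects),
            baseline_strata=_ALL_STRATA_ONE,
            proportional_terms=(ProportionalTerm("pair", frozenset({b})),),
        )
        fitted = cox_engine.fit(sub, structure, ties=ties)
        results[(a, b)] = cox_engine.schoenfeld_ph_test(
            fitted, sub, "pair.gamma", transform=transform
        )
    full = cox_engine.fit(table, full_structure(covariates, include_t010=True), ties=ties)
    return BaselineTestResult(
        pairwise=results, loglog=cox_engine.loglog_curves(full), full_model=full
    )


def apply_proportional_baselines(
    structure: EffectStructure,
    transitions: tuple[str, str] = DEATH_TRANSITIONS,
    proportional_name: str = "progression",
) -> EffectStructure:
    """Restrict the named transitions to a shared baseline up to exp(gamma).

    For the death transitions this yields the PH model: one mortality
    baseline, with gamma the log change in the death hazard after
    progression.  Degrees of freedom rise by one relative to merging the
    strata outright (10 -> 11 from the full model).
    """
    return structure.share_baseline(transitions, proportional_name)


# ---------------------------------------------------------------------------
# greedy step-down reduction


@dataclass(frozen=True)
class Move:
    """One candidate restriction: merge effects across transitions or drop one."""

    kind: str  # "merge" | "drop"
    covariate: str
    transitions: frozenset[str]

    def apply(self, structure: EffectStructure) -> EffectStructure:
        if self.kind == "merge":
            return structure.merge(self.covariate, self.transitions)
        if self.kind == "drop":
            return structure.drop(self.covariate, self.transitions)
        raise StructureError(f"unknown move kind {self.kind!r}")

    def describe(self) -> str:
        ts = "+".join(sorted(self.transitions))
        verb = "share" if self.kind == "merge" else "drop"
        return f"{verb} {self.covariate} on {ts}"


@dataclass
class ReductionStep:
    """One accepted (or evaluated) restriction with its test results."""

    name: str
    move: Move
    fitted: FittedModel
    lr_stat: float
    lr_df: int
    lr_p: float
    aic_delta: float
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "move": self.move.describe(),
            "df": self.fitted.df,
            "loglik": self.fitted.loglik,
            "aic": self.fitted.aic,
            "lr_stat": self.lr_stat,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "aic_delta": self.aic_delta,
            "accepted": self.accepted,
        }


def evaluate_move(
    table: pd.DataFrame,
    current: FittedModel,
    move: Move,
    alpha: float = 0.05,
    ties: str = "breslow",
) -> tuple[FittedModel, float, int, float, float, bool]:
    """Fit one candidate restriction and judge it.

    Returns the restricted fit, the LR statistic/df/p against the current
    model, the AIC change, and whether the move is acceptable (LR p >= alpha
    and the AIC does not increase).
    """
    restricted = cox_engine.fit(table, move.apply(current.structure), ties=ties)
    stat, df, p = cox_engine.lr_test(restricted, current)
    aic_delta = restricted.aic - current.aic
    ok = (p >= alpha) and (aic_delta <= 0.0)
    return restricted, stat, df, p, aic_delta, ok


def _merge_candidates(structure: EffectStructure) -> list[Move]:
    moves: list[Move] = []
    for cov in sorted({e.covariate for e in structure.effects} - {T010}):
        effs = structure.effects_for(cov)
        covered = frozenset(t for e in effs for t in e.transitions)
        if len(effs) == 3:
            moves.append(Move("merge", cov, covered))
        death = frozenset(DEATH_TRANSITIONS)
        death_effs = [e for e in effs if e.transitions <= death]
        if len(death_effs) == 2:
            moves.append(Move("merge", cov, death))
    return moves


def _drop_candidates(structure: EffectStructure, fitted: FittedModel, alpha: float) -> list[Move]:
    moves = []
    for eff in structure.effects:
        if eff.covariate == T010:
            continue
        if fitted.wald_p(eff.label) > alpha:
            moves.append(Move("drop", eff.covariate, eff.transitions))
    return sorted(moves, key=lambda m: (m.covariate, sorted(m.transitions)))


def reduce(
    table: pd.DataFrame,
    start: EffectStructure,
    alpha: float = 0.05,
    moves: list[Move] | None = None,
    ties: str = "breslow",
    start_name: str = "A",
) -> tuple[list[ReductionStep], FittedModel]:
    """Greedy step-down reduction from ``start``.

    In auto mode (``moves`` is None) every iteration first screens equality
    moves (sharing a covariate's coefficients across all transitions, or
    across the two death transitions), then drops of main effects whose
    Wald p exceeds ``alpha``.  A move is accepted only when the LR test
    against the current model is non-significant (p >= alpha) and the AIC
    does not increase; among acceptable moves the lowest resulting AIC wins,
    ties broken by the larger df reduction, then covariate order.  With an
    explicit ``moves`` list, the moves are evaluated in the given order
    under the same acceptance rule (rejected moves are recorded and the
    model is left unchanged by them).

    Returns the step trace and the final fitted model.
    """
    current = cox_engine.fit(table, start, ties=ties)
    steps: list[ReductionStep] = []
    names = (chr(c) for c in itertools.count(ord(start_name) + 1))

    if moves is not None:
        for move in moves:
            fitted, stat, df, p, dA, ok = evaluate_move(table, current, move, alpha, ties)
            steps.append(ReductionStep(next(names), move, fitted, stat, df, p, dA, ok))
            if ok:
                current = fitted
        return steps, current

    while True:
        progressed = False
        for candidates in (
            _merge_candidates(current.structure),
            _drop_candidates(current.structure, current, alpha),
        ):
            evaluated = []
            for move in candidates:
                try:
                    res = evaluate_move(table, current, move, alpha, ties)
                except CoxError:
                    continue
                evaluated.append((move, res))
            acceptable = [(m, r) for m, r in evaluated if r[5]]
            if not acceptable:
                continue
            acceptable.sort(
                key=lambda mr: (
                    mr[1][0].aic,
                    -(current.df - mr[1][0].df),
                    mr[0].covariate,
                    sorted(mr[0].transitions),
                )
            )
            move, (fitted, stat, df, p, dA, ok) = acceptable[0]
            steps.append(ReductionStep(next(names), move, fitted, stat, df, p, dA, True))
            current = fitted
            progressed = True
            break
        if not progressed:
            return steps, current
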