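"""Declarative description of an illness-death regression structure.

The three-state illness-death model without recovery has states
0 ("healthy"), 1 ("progression") and 2 ("death", absorbing) and the three
transitions 0->1, 0->2 and 1->2.  On each transition a Cox-type hazard

    alpha_ij(t) = alpha_ij0(t) * exp(beta_ij' z)

acts on that transition's own clock (clock-reset: time since entering the
source state).  An :class:`EffectStructure` records, for such a model,

* which regression coefficients exist and across which transitions each one
  is shared (an equality restriction ``beta_ij,c = beta_kl,c`` is expressed
  by a single :class:`Effect` listing several transitions),
* how the three nonparametric baselines are partitioned into strata
  (transitions in one stratum share a baseline hazard), and
* optional proportionality terms: an indicator covariate whose coefficient
  gamma makes two baselines within one stratum differ by the constant
  factor exp(gamma).

The sojourn time in the healthy state (``t010``) is an ordinary covariate
restricted to the 1->2 transition; its presence makes the model a
non-homogeneous semi-Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

#: canonical transition codes of the illness-death model without recovery
TRANSITIONS: tuple[str, ...] = ("01", "02", "12")

#: the two transitions that end in the absorbing death state
DEATH_TRANSITIONS: tuple[str, str] = ("02", "12")

#: name of the sojourn-time covariate on the 1->2 hazard
T010 = "t010"

#: default subject-level covariates of the ovarian-cancer style cohort
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "residual_tumor", "figo_high")


class StructureError(ValueError):
    """Raised for an inconsistent or unsupported effect structure."""


def _check_transitions(transitions: Iterable[str]) -> frozenset[str]:
    ts = frozenset(transitions)
    unknown = ts - set(TRANSITIONS)
    if unknown:
        raise StructureError(f"unknown transitions: {sorted(unknown)}")
    if not ts:
        raise StructureError("empty transition set")
    return ts


def _trans_label(transitions: frozenset[str]) -> str:
    return "+".join(sorted(transitions))


@dataclass(frozen=True)
class Effect:
    """One free regression coefficient.

    ``transitions`` lists every transition on which the coefficient acts;
    more than one transition expresses an equality (shared-effect)
    restriction.
    """

    covariate: str
    transitions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", _check_transitions(self.transitions))

    @property
    def label(self) -> str:
        if len(self.transitions) == 1:
            return f"{self.covariate}.{next(iter(self.transitions))}"
        return f"{self.covariate}.shared:{_trans_label(self.transitions)}"

    def applies_to(self, transition: str) -> bool:
        return transition in self.transitions


@dataclass(frozen=True)
class ProportionalTerm:
    """Indicator covariate exp(gamma) separating transitions within a stratum.

    ``indicator_transitions`` are the transitions on which the indicator is 1;
    for the illness-death model this is {"12"}: gamma is the log change of the
    death hazard caused by progression.
    """

    name: str
    indicator_transitions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indicator_transitions", _check_transitions(self.indicator_transitions)
        )

    @property
    def label(self) -> str:
        return f"{self.name}.gamma"


@dataclass(frozen=True)
class EffectStructure:
    """Coefficient layout, baseline strata and proportional terms of a model."""

    effects: tuple[Effect, ...]
    baseline_strata: tuple[frozenset[str], ...] = (
        frozenset({"01"}),
        frozenset({"02"}),
        frozenset({"12"}),
    )
    proportional_terms: tuple[ProportionalTerm, ...] = ()

    def __post_init__(self) -> None:
        covered = [t for s in self.baseline_strata for t in s]
        if sorted(covered) != sorted(TRANSITIONS):
            raise StructureError(
                "baseline_strata must partition the three transitions, got "
                f"{[sorted(s) for s in self.baseline_strata]}"
            )
        seen: dict[tuple[str, str], str] = {}
        for eff in self.effects:
            for t in eff.transitions:
                key = (eff.covariate, t)
                if key in seen:
                    raise StructureError(
                        f"covariate {eff.covariate!r} appears twice on transition {t}"
                    )
                seen[key] = eff.label
        for term in self.proportional_terms:
            stratum = self.stratum_of(next(iter(term.indicator_transitions)))
            if not term.indicator_transitions < stratum:
                raise StructureError(
                    f"proportional term {term.name!r} must distinguish transitions "
                    "within a single shared stratum"
                )

    # -- bookkeeping ---------------------------------------------------------

    @property
    def df(self) -> int:
        """Number of free coefficients (effects plus proportional terms)."""
        return len(self.effects) + len(self.proportional_terms)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.effects) + tuple(
            t.label for t in self.proportional_terms
        )

    @property
    def covariates(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.effects:
            if e.covariate not in out:
                out.append(e.covariate)
        return tuple(out)

    @property
    def includes_t010(self) -> bool:
        return any(e.covariate == T010 for e in self.effects)

    def stratum_of(self, transition: str) -> frozenset[str]:
        for s in self.baseline_strata:
            if transition in s:
                return s
        raise StructureError(f"transition {transition!r} not in any stratum")

    def stratum_label(self, stratum: frozenset[str]) -> str:
        return _trans_label(stratum)

    def effects_for(self, covariate: str) -> tuple[Effect, ...]:
        return tuple(e for e in self.effects if e.covariate == covariate)

    # -- editing moves -------------------------------------------------------

    def merge(self, covariate: str, transitions: Iterable[str]) -> "EffectStructure":
        """Share one coefficient for ``covariate`` across ``transitions``.

        The named transitions must currently carry separate coefficients for
        the covariate; they are replaced by a single shared effect.
        """
        ts = _check_transitions(transitions)
        current = [e for e in self.effects if e.covariate == covariate and e.transitions <= ts]
        covered = frozenset(t for e in current for t in e.transitions)
        if covered != ts or len(current) < 2:
            raise StructureError(
                f"cannot merge {covariate!r} over {sorted(ts)}: transitions do not "
                "carry separate coefficients for it"
            )
        effects = tuple(e for e in self.effects if e not in current)
        return replace(self, effects=effects + (Effect(covariate, ts),))

    def drop(self, covariate: str, transitions: Iterable[str]) -> "EffectStructure":
        """Remove the coefficient of ``covariate`` on exactly ``transitions``."""
        ts = _check_transitions(transitions)
        match = [e for e in self.effects if e.covariate == covariate and e.transitions == ts]
        if not match:
            raise StructureError(
                f"no coefficient for {covariate!r} on exactly {sorted(ts)} to drop"
            )
        return replace(self, effects=tuple(e for e in self.effects if e not in match))

    def share_baseline(
        self, transitions: Iterable[str], proportional_name: str | None = "progression"
    ) -> "EffectStructure":
        """Merge the strata of ``transitions`` into one shared baseline.

        With ``proportional_name`` set, an indicator term exp(gamma) marking
        arrival from the progression state is added, so the merged baselines
        are restricted to proportionality rather than equality.
        """
        ts = _check_transitions(transitions)
        merged = frozenset().union(*(self.stratum_of(t) for t in ts))
        if merged in self.baseline_strata and len(ts) > 1:
            raise StructureError(f"transitions {sorted(ts)} already share a stratum")
        strata = tuple(s for s in self.baseline_strata if not s & merged) + (merged,)
        terms = self.proportional_terms
        if proportional_name is not None:
            if "12" not in ts:
                raise StructureError("the proportional indicator marks arrival from state 1")
            terms = terms + (ProportionalTerm(proportional_name, frozenset({"12"})),)
        return replace(self, baseline_strata=strata, proportional_terms=terms)

    def is_restriction_of(self, other: "EffectStructure") -> bool:
        """True if this structure is nested in ``other``.

        Checked by coefficient containment: every (covariate, transition)
        pair carrying a coefficient here also carries one in ``other``, and
        every shared effect here covers transitions that are a union of
        effect groups of ``other``.
        """
        if self.df > other.df:
            return False
        other_pairs = {(e.covariate, t) for e in other.effects for t in e.transitions}
        for eff in self.effects:
            for t in eff.transitions:
                if (eff.covariate, t) not in other_pairs:
                    return False
        if self.baseline_strata != other.baseline_strata:
            # a finer baseline partition is not expressible as a restriction
            other_strata = {frozenset(s) for s in other.baseline_strata}
            for s in other_strata:
                if not any(s <= m for m in self.baseline_strata):
                    return False
        return True


def structure_to_dict(structure: EffectStructure) -> dict:
    """Plain-dict form of a structure (YAML/JSON friendly)."""
    return {
        "effects": [[e.covariate, sorted(e.transitions)] for e in structure.effects],
        "baseline_strata": [sorted(s) for s in structure.baseline_strata],
        "proportional_terms": [
            [t.name, sorted(t.indicator_transitions)] for t in structure.proportional_terms
        ],
    }


def structure_from_dict(d: dict) -> EffectStructure:
    effects = tuple(Effect(c, frozenset(ts)) for c, ts in d["effects"])
    kwargs = {}
    if "baseline_strata" in d:
        kwargs["baseline_strata"] = tuple(frozenset(s) for s in d["baseline_strata"])
    if "proportional_terms" in d:
        kwargs["proportional_terms"] = tuple(
            ProportionalTerm(n, frozenset(ts)) for n, ts in d["proportional_terms"]
        )
    return EffectStructure(effects=effects, **kwargs)


def full_structure(
    covariates: Sequence[str] = DEFAULT_COVARIATES, include_t010: bool = True
) -> EffectStructure:
    """The unrestricted model: transition-specific effects and baselines.

    With the three default covariates and the sojourn-time covariate this has
    ten coefficients: three per transition plus one for ``t010`` on 1->2.
    """
    effects = [Effect(c, frozenset({t})) for t in TRANSITIONS for c in covariates]
    if include_t010:
        effects.append(Effect(T010, frozenset({"12"})))
    return EffectStructure(effects=tuple(effects))


def ph_structure(
    covariates: Sequence[str] = DEFAULT_COVARIATES, include_t010: bool = True
) -> EffectStructure:
    """The proportional-baselines model: one shared death baseline.

    Identical to :func:`full_structure` except that the two transitions into
    death share one baseline up to the factor exp(gamma); the gamma term
    raises the degrees of freedom by one (10 -> 11 with the defaults).
    """
    return full_structure(covariates, include_t010).share_baseline(DEATH_TRANSITIONS)
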