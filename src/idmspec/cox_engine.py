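"""Stratified Cox partial likelihood for transition-structured data.

Fits the stacked counting-process table of an illness-death model under an
:class:`~idmspec.structures.EffectStructure`: one Newton--Raphson
maximization of the stratified partial likelihood, where strata are the
baseline groups of the structure and the design matrix encodes
transition-specific, shared and proportional-term coefficients.  Also
provides Breslow cumulative baseline hazards, likelihood-ratio tests, a
Schoenfeld-residual test of proportional hazards, and log-log curve data
for graphical proportionality checks.

Tie handling is configurable (Breslow or Efron); Breslow is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .structures import EffectStructure, structure_from_dict, structure_to_dict

__all__ = [
    "CoxError",
    "ConvergenceError",
    "StepHazard",
    "FittedModel",
    "fit",
    "breslow_baseline",
    "lr_test",
    "schoenfeld_residuals",
    "schoenfeld_ph_test",
    "loglog_curves",
]


class CoxError(ValueError):
    pass


class ConvergenceError(CoxError):
    pass


# ---------------------------------------------------------------------------
# step functions


@dataclass(frozen=True)
class StepHazard:
    """Nondecreasing cumulative hazard as jump times + increments."""

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        dl = np.asarray(self.increments, float)
        if t.shape != dl.shape:
            raise ValueError("times and increments must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(dl < 0):
            raise ValueError("increments must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "increments", dl)
        object.__setattr__(self, "_cum", np.cumsum(dl))

    def cumhaz(self, t) -> np.ndarray:
        """Cumulative hazard at t (right-continuous, flat beyond last jump)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        cum = np.concatenate([[0.0], self._cum])
        return cum[idx]

    def cumhaz_left(self, t) -> np.ndarray:
        """Left limit of the cumulative hazard at t."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="left")
        cum = np.concatenate([[0.0], self._cum])
        return cum[idx]

    @property
    def total(self) -> float:
        return float(self._cum[-1]) if len(self.times) else 0.0


# ---------------------------------------------------------------------------
# design matrix and per-stratum layout


def design_matrix(table: pd.DataFrame, structure: EffectStructure) -> tuple[np.ndarray, list[str]]:
    """Design columns of the stacked table under ``structure``.

    A coefficient's column holds the covariate value on the transitions the
    coefficient acts on and 0 elsewhere; a proportional term contributes its
    transition indicator.
    """
    trans = table["transition"].to_numpy()
    cols, names = [], []
    for eff in structure.effects:
        if eff.covariate not in table.columns:
            raise CoxError(f"covariate {eff.covariate!r} not in table")
        mask = np.isin(trans, list(eff.transitions))
        vals = np.nan_to_num(table[eff.covariate].to_numpy(float))
        cols.append(np.where(mask, vals, 0.0))
        names.append(eff.label)
    for term in structure.proportional_terms:
        cols.append(np.isin(trans, list(term.indicator_transitions)).astype(float))
        names.append(term.label)
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, names


@dataclass
class _Stratum:
    label: str
    tstop: np.ndarray          # sorted descending
    status: np.ndarray
    X: np.ndarray
    event_order: np.ndarray    # indices into the original table, events only


def _split_strata(table: pd.DataFrame, structure: EffectStructure, X: np.ndarray) -> list[_Stratum]:
    if np.any(table["tstart"].to_numpy(float) != 0.0):
        raise CoxError("risk intervals must start at 0 on the reset clock")
    trans = table["transition"].to_numpy()
    out = []
    for stratum in structure.baseline_strata:
        mask = np.isin(trans, list(stratum))
        if not mask.any():
            raise CoxError(f"stratum {sorted(stratum)} has no rows")
        t = table.loc[mask, "tstop"].to_numpy(float)
        d = table.loc[mask, "status"].to_numpy(int)
        if d.sum() == 0:
            raise CoxError(f"stratum {sorted(stratum)} has no events")
        order = np.argsort(-t, kind="stable")
        out.append(
            _Stratum(
                label=structure.stratum_label(stratum),
                tstop=t[order],
                status=d[order],
                X=X[mask][order],
                event_order=np.flatnonzero(mask)[order],
            )
        )
    return out


def _stratum_quantities(s: _Stratum, beta: np.ndarray, ties: str):
    """Log partial likelihood, score and information contribution of one stratum.

    Rows are sorted by descending stop time, so the risk set at an event
    time u is a prefix of the arrays; prefix sums give the weighted moments
    S0, S1, S2 over each risk set.
    """
    t, d, X = s.tstop, s.status, s.X
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta = eta - eta.max() if n else eta  # common factor cancels in the PL
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    cw = np.cumsum(w)
    cwX = np.cumsum(wX, axis=0)
    cwXX = np.cumsum(wXX, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev = d.astype(bool)
    # distinct event times, with the prefix index of the last row still at risk
    et, inv = np.unique(-t[ev], return_inverse=True)
    et = -et  # descending distinct event times
    for g in range(len(et)):
        u = et[g]
        last = np.searchsorted(-t, -u, side="right") - 1  # prefix end: t >= u
        S0 = cw[last]
        S1 = cwX[last]
        S2 = cwXX[last]
        egrp = np.flatnonzero(ev)[inv == g]
        dcount = len(egrp)
        sx = X[egrp].sum(axis=0)
        ll += eta[egrp].sum()
        if ties == "breslow" or dcount == 1:
            ll -= dcount * np.log(S0)
            xbar = S1 / S0
            grad += sx - dcount * xbar
            hess -= dcount * (S2 / S0 - np.outer(xbar, xbar))
        elif ties == "efron":
            wD = w[egrp].sum()
            wDX = wX[egrp].sum(axis=0)
            wDXX = wXX[egrp].sum(axis=0)
            for k in range(dcount):
                f = k / dcount
                S0k = S0 - f * wD
                S1k = S1 - f * wDX
                S2k = S2 - f * wDXX
                ll -= np.log(S0k)
                xbar = S1k / S0k
                grad += sx / dcount - xbar
                hess -= S2k / S0k - np.outer(xbar, xbar)
        else:
            raise CoxError(f"unknown tie method {ties!r}")
    return ll, grad, hess


def _loglik_parts(strata: list[_Stratum], beta: np.ndarray, ties: str):
    p = len(beta)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for s in strata:
        l, g, h = _stratum_quantities(s, beta, ties)
        ll += l
        grad += g
        hess += h
    return ll, grad, hess


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedModel:
    """Result of a stratified partial-likelihood fit."""

    structure: EffectStructure
    names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    loglik_null: float
    df: int
    ties: str
    baselines: dict[str, StepHazard]
    n: int
    n_events: dict[str, int] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def wald_p(self, name: str) -> float:
        i = self.names.index(name)
        z = self.beta[i] / self.se[i]
        return float(2.0 * stats.norm.sf(abs(z)))

    def summary(self) -> pd.DataFrame:
        """Hazard ratios with Wald 95% intervals and two-sided p-values."""
        se = self.se
        z = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "hr": np.exp(self.beta),
                "hr_lower95": np.exp(self.beta - 1.959963984540054 * se),
                "hr_upper95": np.exp(self.beta + 1.959963984540054 * se),
                "p": 2.0 * stats.norm.sf(np.abs(z)),
            },
            index=self.names,
        )

    def baseline_for(self, transition: str) -> StepHazard:
        stratum = self.structure.stratum_of(transition)
        return self.baselines[self.structure.stratum_label(stratum)]

    def linear_predictor(self, profile: dict, transition: str) -> float:
        """Profile linear predictor on one transition, t010 term excluded."""
        lp = 0.0
        for eff, b in zip(self.structure.effects, self.beta):
            if transition in eff.transitions and eff.covariate != "t010":
                if eff.covariate not in profile:
                    raise CoxError(f"profile is missing covariate {eff.covariate!r}")
                lp += b * float(profile[eff.covariate])
        off = len(self.structure.effects)
        for term, b in zip(self.structure.proportional_terms, self.beta[off:]):
            if transition in term.indicator_transitions:
                lp += b
        return lp

    @property
    def t010_coef(self) -> float:
        for eff, b in zip(self.structure.effects, self.beta):
            if eff.covariate == "t010":
                return float(b)
        return 0.0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": structure_to_dict(self.structure),
            "names": self.names,
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "df": self.df,
            "aic": self.aic,
            "ties": self.ties,
            "n": self.n,
            "n_events": self.n_events,
            "baselines": {
                k: {"times": v.times.tolist(), "increments": v.increments.tolist()}
                for k, v in self.baselines.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        structure = structure_from_dict(d["structure"])
        return cls(
            structure=structure,
            names=list(d["names"]),
            beta=np.asarray(d["beta"], float),
            vcov=np.asarray(d["vcov"], float).reshape(len(d["names"]), len(d["names"]))
            if d["names"]
            else np.empty((0, 0)),
            loglik=d["loglik"],
            loglik_null=d["loglik_null"],
            df=d["df"],
            ties=d["ties"],
            baselines={
                k: StepHazard(np.asarray(v["times"]), np.asarray(v["increments"]))
                for k, v in d["baselines"].items()
            },
            n=d["n"],
            n_events={k: int(v) for k, v in d.get("n_events", {}).items()},
        )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting


_BETA_BOUND = 15.0


def fit(
    table: pd.DataFrame,
    structure: EffectStructure,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
) -> FittedModel:
    """Maximize the stratified Cox partial likelihood.

    Newton--Raphson with step-halving on a likelihood decrease; convergence
    when the relative change in the log partial likelihood falls below
    ``tol`` and the score max-norm falls below ``grad_tol`` (the score
    criterion is waived after ``max_iter`` if the likelihood has
    stabilized, which happens near monotone-likelihood configurations).
    Raises :class:`ConvergenceError` when a coefficient diverges or the
    likelihood itself fails to stabilize.
    """
    if len(table) == 0:
        raise CoxError("empty table")
    X, names = design_matrix(table, structure)
    strata = _split_strata(table, structure, X)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_parts(strata, beta, ties)
    loglik_null = ll
    if p:
        ll_stable = False
        stable_runs = 0
        # decreases below numerical noise are not treated as overshoot
        noise = 64.0 * np.finfo(float).eps
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_parts(strata, new_beta, ties)
            halvings = 0
            while (
                not np.isfinite(new_ll) or new_ll < ll - noise * (abs(ll) + 1.0)
            ) and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_ll, new_grad, new_hess = _loglik_parts(strata, new_beta, ties)
                halvings += 1
            ll_stable = abs(new_ll - ll) < tol * (abs(ll) + 1.0)
            stable_runs = stable_runs + 1 if ll_stable else 0
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            if np.any(np.abs(beta) > _BETA_BOUND) and np.max(np.abs(grad)) > np.sqrt(tol):
                bad = names[int(np.argmax(np.abs(beta)))]
                raise ConvergenceError(
                    f"coefficient {bad!r} diverges (monotone likelihood)"
                )
            if ll_stable and (np.max(np.abs(grad)) < grad_tol or stable_runs >= 5):
                break
        else:
            if not ll_stable:
                raise ConvergenceError(f"no convergence in {max_iter} iterations")
        if np.any(np.abs(beta) > _BETA_BOUND):
            bad = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(f"coefficient {bad!r} diverges (monotone likelihood)")
        vcov = np.linalg.inv(-hess)
    else:
        vcov = np.empty((0, 0))
    model = FittedModel(
        structure=structure,
        names=names,
        beta=beta,
        vcov=vcov,
        loglik=float(ll),
        loglik_null=float(loglik_null),
        df=p,
        ties=ties,
        baselines={},
        n=len(table),
        n_events={s.label: int(s.status.sum()) for s in strata},
    )
    model.baselines = breslow_baseline(model, table)
    return model


def breslow_baseline(fitted: FittedModel, table: pd.DataFrame) -> dict[str, StepHazard]:
    """Breslow cumulative baseline hazard per stratum.

    The increment at an event time u is (number of events at u) divided by
    the sum of exp(linear predictor) over the stratum's risk set at u.
    """
    X, _ = design_matrix(table, fitted.structure)
    strata = _split_strata(table, fitted.structure, X)
    out: dict[str, StepHazard] = {}
    for s in strata:
        w = np.exp(s.X @ fitted.beta) if fitted.df else np.ones(len(s.tstop))
        cw = np.cumsum(w)
        ev = s.status.astype(bool)
        et = np.unique(s.tstop[ev])
        inc = np.empty_like(et)
        for i, u in enumerate(et):
            last = np.searchsorted(-s.tstop, -u, side="right") - 1
            dcount = int(((s.tstop == u) & ev).sum())
            inc[i] = dcount / cw[last]
        out[s.label] = StepHazard(et, inc)
    return out


def lr_test(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one."""
    if not nested.structure.is_restriction_of(full.structure):
        raise CoxError("models are not nested")
    stat = 2.0 * (full.loglik - nested.loglik)
    stat = max(stat, 0.0)
    df = full.df - nested.df
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return float(stat), df, p


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics


def schoenfeld_residuals(fitted: FittedModel, table: pd.DataFrame):
    """Schoenfeld residuals per event, pooled over strata.

    Returns event times (each on its stratum's clock), the residual matrix
    (events x coefficients) and the per-event risk-set covariance matrices.
    """
    X, _ = design_matrix(table, fitted.structure)
    strata = _split_strata(table, fitted.structure, X)
    times, resid, vmats = [], [], []
    for s in strata:
        w = np.exp(s.X @ fitted.beta) if fitted.df else np.ones(len(s.tstop))
        cw = np.cumsum(w)
        cwX = np.cumsum(w[:, None] * s.X, axis=0)
        cwXX = np.cumsum(np.einsum("i,ij,ik->ijk", w, s.X, s.X), axis=0)
        ev_idx = np.flatnonzero(s.status)
        for i in ev_idx:
            u = s.tstop[i]
            last = np.searchsorted(-s.tstop, -u, side="right") - 1
            S0 = cw[last]
            xbar = cwX[last] / S0
            V = cwXX[last] / S0 - np.outer(xbar, xbar)
            times.append(u)
            resid.append(s.X[i] - xbar)
            vmats.append(V)
    order = np.argsort(times, kind="stable")
    return (
        np.asarray(times)[order],
        np.asarray(resid)[order],
        np.asarray(vmats)[order],
    )


def schoenfeld_ph_test(
    fitted: FittedModel,
    table: pd.DataFrame,
    coefficient: str,
    transform: str = "identity",
) -> tuple[float, float]:
    """Score test for a time trend in a coefficient's Schoenfeld residuals.

    Tests H0: the coefficient is constant in time, against a drift linear in
    ``g(t)`` (identity, rank, or Kaplan-Meier transform of the event time).
    One-degree-of-freedom chi-square.
    """
    if coefficient not in fitted.names:
        raise CoxError(f"coefficient {coefficient!r} not in the fitted model")
    k = fitted.names.index(coefficient)
    times, resid, vmats = schoenfeld_residuals(fitted, table)
    if len(times) < 2:
        raise CoxError("need at least two events for the proportionality test")
    if transform == "identity":
        g = times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(times).astype(float)
    elif transform == "km":
        # pooled Kaplan-Meier of the event-time distribution, left-continuous
        n = len(times)
        g = 1.0 - (stats.rankdata(times, method="min") - 1.0) / n
    else:
        raise CoxError(f"unknown time transform {transform!r}")
    vkk = vmats[:, k, k]
    gbar = float(np.sum(g * vkk) / np.sum(vkk))
    num = float(np.sum((g - gbar) * resid[:, k]))
    den = float(np.sum((g - gbar) ** 2 * vkk))
    if den <= 0:
        raise CoxError("degenerate time transform (no variation)")
    statistic = num * num / den
    return statistic, float(stats.chi2.sf(statistic, 1))


def loglog_curves(fitted: FittedModel) -> dict[str, np.ndarray]:
    """(ln t, ln cumulative baseline hazard) polylines per stratum.

    Parallel curves across strata support proportional baseline hazards;
    points exist only where the cumulative hazard is positive.
    """
    out = {}
    for label, bh in fitted.baselines.items():
        cum = np.cumsum(bh.increments)
        keep = (bh.times > 0) & (cum > 0)
        out[label] = np.column_stack([np.log(bh.times[keep]), np.log(cum[keep])])
    return out
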