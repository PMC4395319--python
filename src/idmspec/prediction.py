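"""Clock-reset semi-Markov state-occupation probabilities.

For a covariate profile z, a fitted illness-death model supplies
subject-specific cumulative transition hazards built from the Breslow
baselines times exp(linear predictor).  Starting healthy at time 0,

    P00(t) = exp(-L01(t) - L02(t))
    P01(t) = sum over progression times u <= t of
             [mass of progressing at u] * S12(t - u | t010 = u)
    P02(t) = 1 - P00(t) - P01(t)

where S12(s | u) = exp(-L12,0(s) * exp(eta12(z) + beta_t010 * u)) is the
post-progression survival on the reset clock, which through ``t010 = u``
depends on when progression happened (the non-homogeneous semi-Markov
feature), and under a proportional-baseline structure L12,0 includes the
factor exp(gamma).  Starting from the progression state with known sojourn
time, P11(s) = S12(s | t010) and P12 = 1 - P11.

The progression mass at a Breslow jump u defaults to the
discrete-hazard form P00(u-) * (1 - exp(-dL(u))) * dL01(u)/dL(u), which is
exactly the law sampled by :func:`microsimulate`; the first-order form
P00(u-) * dL01(u) is available as ``mass="hazard"`` (the two agree to
O(dL^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox_engine import CoxError, FittedModel, StepHazard
from .structures import EffectStructure, T010

__all__ = [
    "StateProbabilities",
    "predict_from_healthy",
    "predict_from_progression",
    "overall_survival",
    "microsimulate",
    "model_from_step_hazards",
    "constant_hazard_model",
]


@dataclass
class StateProbabilities:
    """State-occupation probability curves for one profile."""

    times: np.ndarray
    from_state: int
    probs: dict[str, np.ndarray]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.probs[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.probs})


# ---------------------------------------------------------------------------
# subject-specific hazard assembly


@dataclass
class _SubjectHazards:
    """Merged 0->1/0->2 jump grid and the 1->2 ingredients for one profile."""

    u: np.ndarray        # merged jump times of the two healthy-state hazards
    d01: np.ndarray      # subject-specific increments of L01 at u
    d02: np.ndarray      # increments of L02 at u
    b12: StepHazard      # baseline cumulative hazard of 1->2 (stratum baseline)
    scale12: float       # exp(eta12), gamma included, t010 term excluded
    t010_coef: float

    @property
    def cum(self) -> np.ndarray:
        return np.cumsum(self.d01 + self.d02)

    def s12(self, s, u) -> np.ndarray:
        """Post-progression survival at residual time s given progression at u."""
        return np.exp(
            -self.b12.cumhaz(np.maximum(s, 0.0)) * self.scale12 * np.exp(self.t010_coef * u)
        )


def _subject_hazards(fitted: FittedModel, profile: dict) -> _SubjectHazards:
    b01 = fitted.baseline_for("01")
    b02 = fitted.baseline_for("02")
    e01 = np.exp(fitted.linear_predictor(profile, "01"))
    e02 = np.exp(fitted.linear_predictor(profile, "02"))
    u = np.union1d(b01.times, b02.times)
    d01 = np.zeros_like(u)
    d02 = np.zeros_like(u)
    d01[np.searchsorted(u, b01.times)] = b01.increments * e01
    d02[np.searchsorted(u, b02.times)] = b02.increments * e02
    return _SubjectHazards(
        u=u,
        d01=d01,
        d02=d02,
        b12=fitted.baseline_for("12"),
        scale12=np.exp(fitted.linear_predictor(profile, "12")),
        t010_coef=fitted.t010_coef,
    )


# ---------------------------------------------------------------------------
# analytic prediction


def predict_from_healthy(
    fitted: FittedModel,
    profile: dict,
    tgrid: np.ndarray,
    mass: str = "discrete",
) -> StateProbabilities:
    """P00/P01/P02 on ``tgrid`` for a profile starting healthy at time 0.

    ``mass`` selects the progression-mass convention at each Breslow jump
    (see module docstring).  Beyond the last observed event time the
    baselines are carried forward flat.
    """
    tgrid = np.asarray(tgrid, float)
    if np.any(tgrid < 0):
        raise ValueError("tgrid must be nonnegative")
    h = _subject_hazards(fitted, profile)
    cum = h.cum
    p00_right = np.exp(-cum)
    p00_left = np.exp(-np.concatenate([[0.0], cum[:-1]]))
    dtot = h.d01 + h.d02
    with np.errstate(invalid="ignore", divide="ignore"):
        frac01 = np.where(dtot > 0, h.d01 / np.where(dtot > 0, dtot, 1.0), 0.0)
    if mass == "discrete":
        m01 = p00_left * (1.0 - np.exp(-dtot)) * frac01
    elif mass == "hazard":
        m01 = p00_left * h.d01
    else:
        raise ValueError(f"unknown mass convention {mass!r}")

    idx = np.searchsorted(h.u, tgrid, side="right")
    cum0 = np.concatenate([[0.0], cum])
    p00 = np.exp(-cum0[idx])

    # convolution: for each grid time, sum progression masses at u <= t
    # weighted by post-progression survival over the remaining time
    s = tgrid[:, None] - h.u[None, :]
    active = s >= 0
    surv12 = np.where(
        active,
        np.exp(
            -h.b12.cumhaz(np.clip(s, 0.0, None))
            * h.scale12
            * np.exp(h.t010_coef * h.u)[None, :]
        ),
        0.0,
    )
    p01 = surv12 @ m01 if len(h.u) else np.zeros_like(tgrid)
    p01 = np.clip(p01, 0.0, 1.0)
    p02 = np.clip(1.0 - p00 - p01, 0.0, 1.0)
    return StateProbabilities(
        times=tgrid, from_state=0, probs={"P00": p00, "P01": p01, "P02": p02}
    )


def predict_from_progression(
    fitted: FittedModel, profile: dict, sgrid: np.ndarray
) -> StateProbabilities:
    """P11/P12 on the reset clock for a profile with known sojourn time.

    The profile must carry ``t010`` (months spent healthy before
    progression); a longer healthy sojourn lowers the subsequent death
    hazard when the fitted ``t010`` coefficient is negative.
    """
    if T010 not in profile:
        raise CoxError("prediction from the progression state requires t010 in the profile")
    sgrid = np.asarray(sgrid, float)
    b12 = fitted.baseline_for("12")
    scale = np.exp(
        fitted.linear_predictor(profile, "12") + fitted.t010_coef * float(profile[T010])
    )
    p11 = np.exp(-b12.cumhaz(sgrid) * scale)
    return StateProbabilities(
        times=sgrid, from_state=1, probs={"P11": p11, "P12": 1.0 - p11}
    )


def overall_survival(
    fitted: FittedModel, profile: dict, tgrid: np.ndarray, mass: str = "discrete"
) -> np.ndarray:
    """Model-based survival from time 0: S(t) = P00(t) + P01(t)."""
    sp = predict_from_healthy(fitted, profile, tgrid, mass=mass)
    return sp["P00"] + sp["P01"]


# ---------------------------------------------------------------------------
# microsimulation oracle


def microsimulate(
    fitted: FittedModel,
    profile: dict,
    tgrid: np.ndarray,
    n_paths: int = 200_000,
    seed: int | np.random.Generator = 0,
) -> StateProbabilities:
    """Empirical state probabilities from sampled illness-death paths.

    Each path draws the first-event time by inversion of the subject's
    combined 0->1/0->2 cumulative hazard over the Breslow jump grid, picks
    the destination in proportion to the two increments, and on progression
    at u draws residual survival from S12(. | u).  With a fixed seed the
    output is deterministic; it estimates the same law as
    :func:`predict_from_healthy` with the default mass convention.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tgrid = np.asarray(tgrid, float)
    h = _subject_hazards(fitted, profile)
    cum = h.cum
    dtot = h.d01 + h.d02
    with np.errstate(invalid="ignore"):
        frac01 = np.where(dtot > 0, h.d01 / np.where(dtot > 0, dtot, 1.0), 0.0)

    e1 = rng.exponential(size=n_paths)
    k = np.searchsorted(cum, e1, side="left")
    has_event = k < len(cum)
    u_event = np.where(has_event, h.u[np.minimum(k, len(cum) - 1)], np.inf)
    progressed = has_event & (rng.random(n_paths) < frac01[np.minimum(k, len(cum) - 1)])

    # residual post-progression survival by inversion of the 1->2 hazard
    scale = h.scale12 * np.exp(h.t010_coef * np.where(np.isfinite(u_event), u_event, 0.0))
    e2 = rng.exponential(size=n_paths)
    cum12 = np.cumsum(h.b12.increments)
    t_death = np.where(has_event & ~progressed, u_event, np.inf)
    if progressed.any() and len(cum12):
        k2 = np.searchsorted(cum12, e2[progressed] / scale[progressed], side="left")
        resid = np.where(k2 < len(cum12), h.b12.times[np.minimum(k2, len(cum12) - 1)], np.inf)
        t_death[progressed] = u_event[progressed] + resid

    t = tgrid[:, None]
    in0 = t < u_event[None, :]
    dead = t >= t_death[None, :]
    in1 = progressed[None, :] & ~in0 & ~dead
    return StateProbabilities(
        times=tgrid,
        from_state=0,
        probs={
            "P00": in0.mean(axis=1),
            "P01": in1.mean(axis=1),
            "P02": dead.mean(axis=1),
        },
    )


# ---------------------------------------------------------------------------
# parametric convenience constructors (tests, closed-form checks)


def model_from_step_hazards(
    b01: StepHazard,
    b02: StepHazard,
    b12: StepHazard,
    t010_coef: float = 0.0,
) -> FittedModel:
    """A covariate-free fitted-model shell around given baseline hazards.

    Useful for evaluating the prediction machinery at known (e.g. constant
    or Weibull) hazards: the linear predictor is zero, so the baselines are
    the subject-specific hazards themselves.
    """
    effects = ()
    if t010_coef != 0.0:
        from .structures import Effect

        effects = (Effect(T010, frozenset({"12"})),)
    structure = EffectStructure(effects=effects)
    beta = np.array([t010_coef]) if effects else np.empty(0)
    p = len(beta)
    return FittedModel(
        structure=structure,
        names=[e.label for e in effects],
        beta=beta,
        vcov=np.zeros((p, p)),
        loglik=0.0,
        loglik_null=0.0,
        df=p,
        ties="breslow",
        baselines={"01": b01, "02": b02, "12": b12},
        n=0,
    )


def constant_hazard_model(
    lam01: float, lam02: float, lam12: float, horizon: float, dt: float = 0.01
) -> FittedModel:
    """Discretized constant-hazard illness-death model on a fine grid."""
    times = np.arange(dt, horizon + dt, dt)
    return model_from_step_hazards(
        StepHazard(times, np.full_like(times, lam01 * dt)),
        StepHazard(times, np.full_like(times, lam02 * dt)),
        StepHazard(times, np.full_like(times, lam12 * dt)),
    )
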