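"""Time-dependent prediction error: IPCW Brier score and 0.632+ bootstrap.

The Brier score at t is the mean squared difference between the survival
status at t (1 alive, 0 dead) and the model's prediction from time 0 of
surviving t.  Right censoring is handled by inverse-probability-of-
censoring weights from the Kaplan-Meier estimator G of the censoring
distribution: subjects dead by t are weighted by 1/G(T-), subjects still
under observation at t by 1/G(t), subjects censored before t contribute
nothing.

The 0.632+ estimator combines the downward-biased apparent (resubstitution)
error with the upward-biased bootstrap cross-validation error, the weight
being driven by the relative overfit against the all-pairs no-information
error.  The bootstrap component repeatedly refits the entire modelling
pipeline on training subsamples drawn without replacement and scores the
held-out subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import cox_engine, msdata, prediction, specification
from .structures import DEFAULT_COVARIATES, EffectStructure

__all__ = [
    "StepCurve",
    "ErrorComponents",
    "censoring_km",
    "ipcw_brier",
    "noinformation_error",
    "km_null",
    "bootstrap_cv",
    "err632plus",
    "default_grid",
    "model_pipeline",
    "km_pipeline",
    "prediction_error",
]

log = logging.getLogger(__name__)

#: a pipeline maps training records to a predictor:
#: predictor(records, tgrid) -> (n_subjects, n_times) survival matrix
Pipeline = Callable[[pd.DataFrame], Callable[[pd.DataFrame, np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function with left limits (e.g. a KM curve)."""

    times: np.ndarray
    values: np.ndarray  # value on [times[i], times[i+1])

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]

    def left(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, float), side="left")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


def censoring_km(records: pd.DataFrame) -> StepCurve:
    """Kaplan-Meier estimator of the censoring survival function G.

    Computed on the follow-up times with the event indicator reversed
    (a "censoring event" is the end of observation without death).  With no
    censored subject, G is identically 1.
    """
    t = records["t_death"].to_numpy(float)
    cens = 1 - records["s_death"].to_numpy(int)
    if cens.sum() == 0:
        return StepCurve(np.empty(0), np.empty(0))
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=cens)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(float)
    keep = times > 0
    return StepCurve(times[keep], sf.to_numpy(float)[keep])


def ipcw_brier(
    surv: np.ndarray,
    records: pd.DataFrame,
    tgrid: np.ndarray,
    G: StepCurve | None = None,
) -> np.ndarray:
    """IPCW Brier score curve.

    ``surv`` holds each subject's predicted survival on ``tgrid`` (one row
    per record).  The curve is

        BS(t) = n^-1 sum_i [ 1{T_i <= t, died} S_i(t)^2 / G(T_i-)
                             + 1{T_i > t} (1 - S_i(t))^2 / G(t) ].

    Raises when a required weight 1/G is infinite; choose a grid ending
    before the censoring support is exhausted.
    """
    tgrid = np.asarray(tgrid, float)
    surv = np.atleast_2d(np.asarray(surv, float))
    n = len(records)
    if surv.shape != (n, len(tgrid)):
        raise ValueError(f"surv must be (n={n}, n_times={len(tgrid)})")
    if G is None:
        G = censoring_km(records)
    T = records["t_death"].to_numpy(float)
    died = records["s_death"].to_numpy(int).astype(bool)
    g_left = G.left(T)
    g_grid = G.at(tgrid)

    dead_mask = died[:, None] & (T[:, None] <= tgrid[None, :])
    alive_mask = T[:, None] > tgrid[None, :]
    if np.any(dead_mask & (g_left[:, None] <= 0)) or np.any(alive_mask.any(axis=0) & (g_grid <= 0)):
        raise ValueError("censoring KM reaches 0 inside the grid; shorten the grid")
    w_dead = np.where(dead_mask, 1.0 / np.where(g_left[:, None] > 0, g_left[:, None], 1.0), 0.0)
    w_alive = np.where(alive_mask, 1.0 / np.where(g_grid[None, :] > 0, g_grid[None, :], 1.0), 0.0)
    return (w_dead * surv**2 + w_alive * (1.0 - surv) ** 2).mean(axis=0)


def noinformation_error(
    surv: np.ndarray,
    records: pd.DataFrame,
    tgrid: np.ndarray,
    G: StepCurve | None = None,
) -> np.ndarray:
    """All-pairs no-information error: every prediction against every status."""
    tgrid = np.asarray(tgrid, float)
    surv = np.atleast_2d(np.asarray(surv, float))
    if G is None:
        G = censoring_km(records)
    T = records["t_death"].to_numpy(float)
    died = records["s_death"].to_numpy(int).astype(bool)
    g_left = G.left(T)
    g_grid = G.at(tgrid)
    dead_mask = died[:, None] & (T[:, None] <= tgrid[None, :])
    alive_mask = T[:, None] > tgrid[None, :]
    w_dead = np.where(dead_mask, 1.0 / np.where(g_left[:, None] > 0, g_left[:, None], 1.0), 0.0)
    w_alive = np.where(alive_mask, 1.0 / np.where(g_grid[None, :] > 0, g_grid[None, :], 1.0), 0.0)
    mean_s2 = (surv**2).mean(axis=0)
    mean_1ms2 = ((1.0 - surv) ** 2).mean(axis=0)
    return w_dead.mean(axis=0) * mean_s2 + w_alive.mean(axis=0) * mean_1ms2


def km_null(records: pd.DataFrame, tgrid: np.ndarray) -> np.ndarray:
    """Kaplan-Meier overall survival, the covariate-free null prediction."""
    kmf = KaplanMeierFitter()
    kmf.fit(records["t_death"].to_numpy(float), records["s_death"].to_numpy(int))
    return (
        kmf.survival_function_at_times(np.asarray(tgrid, float)).to_numpy(float)
    )


def default_grid(
    records: pd.DataFrame, quantile: float = 0.95, max_points: int = 100
) -> np.ndarray:
    """Event times up to the given follow-up quantile, thinned if needed.

    Stopping short of the longest follow-up keeps the censoring KM bounded
    away from zero, which the IPCW weights require.
    """
    died = records["s_death"].to_numpy(int).astype(bool)
    times = np.unique(records.loc[died, "t_death"].to_numpy(float))
    cutoff = np.quantile(records["t_death"].to_numpy(float), quantile)
    times = times[times <= cutoff]
    if len(times) > max_points:
        times = times[np.linspace(0, len(times) - 1, max_points).astype(int)]
    return times


def bootstrap_cv(
    pipeline: Pipeline,
    records: pd.DataFrame,
    tgrid: np.ndarray,
    B: int = 300,
    train_n: int = 300,
    seed: int | np.random.Generator = 0,
    min_validation: int = 10,
) -> np.ndarray:
    """Bootstrap cross-validated error by repeated training subsamples.

    ``B`` subsamples of ``train_n`` subjects are drawn without replacement;
    the pipeline refits on each training set and its predictions are scored
    on the held-out subjects with the IPCW Brier curve.  Replicates whose
    training fit fails are dropped (and counted in the log).
    """
    n = len(records)
    if not train_n < n:
        raise ValueError("train_n must be smaller than the number of subjects")
    if n - train_n < min_validation:
        raise ValueError(
            f"only {n - train_n} validation subjects; need >= {min_validation}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curves = []
    failed = 0
    for _ in range(B):
        idx = rng.choice(n, size=train_n, replace=False)
        mask = np.zeros(n, bool)
        mask[idx] = True
        train = records.iloc[mask].reset_index(drop=True)
        valid = records.iloc[~mask].reset_index(drop=True)
        try:
            predictor = pipeline(train)
            surv = predictor(valid, tgrid)
            curves.append(ipcw_brier(surv, valid, tgrid))
        except (cox_engine.CoxError, msdata.DataError, ValueError) as exc:
            failed += 1
            log.warning("bootstrap replicate dropped: %s", exc)
    if not curves:
        raise RuntimeError("every bootstrap replicate failed")
    if failed:
        log.info("bootstrap_cv: %d of %d replicates dropped", failed, B)
    return np.mean(curves, axis=0)


@dataclass
class ErrorComponents:
    """Apparent, cross-validated, no-information and 0.632+ error curves."""

    tgrid: np.ndarray
    err_app: np.ndarray
    err_cv: np.ndarray
    err_noinf: np.ndarray
    relative_overfit: np.ndarray
    weight: np.ndarray
    err632plus: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.tgrid,
                "apparent": self.err_app,
                "cv": self.err_cv,
                "noinf": self.err_noinf,
                "R": self.relative_overfit,
                "weight": self.weight,
                "err632plus": self.err632plus,
            }
        )


def err632plus(
    err_app: np.ndarray, err_cv: np.ndarray, err_noinf: np.ndarray, tgrid: np.ndarray | None = None
) -> ErrorComponents:
    """The 0.632+ combination of apparent and cross-validated error.

    R(t) = (err_cv - err_app)/(err_noinf - err_app) clipped to [0, 1]
    (R = 0 where the no-information error does not exceed the apparent one),
    w(t) = 0.632/(1 - 0.368 R(t)), and the estimate is
    (1 - w) err_app + w err_cv.
    """
    err_app = np.asarray(err_app, float)
    err_cv = np.asarray(err_cv, float)
    err_noinf = np.asarray(err_noinf, float)
    denom = err_noinf - err_app
    bad = denom <= 0
    if bad.any():
        log.warning("no-information error <= apparent error at %d points; R set to 0", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(bad, 0.0, (err_cv - err_app) / np.where(bad, 1.0, denom))
    R = np.clip(R, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    combined = (1.0 - w) * err_app + w * err_cv
    if tgrid is None:
        tgrid = np.arange(len(err_app), dtype=float)
    return ErrorComponents(np.asarray(tgrid, float), err_app, err_cv, err_noinf, R, w, combined)


# ---------------------------------------------------------------------------
# fit-and-predict pipelines


def model_pipeline(
    structure: EffectStructure | None = None,
    reduce_from: EffectStructure | None = None,
    alpha: float = 0.05,
    ties: str = "breslow",
    delta: float = 0.5,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    mass: str = "discrete",
) -> Pipeline:
    """Pipeline fitting a fixed structure, or re-running the reduction.

    With ``reduce_from`` set, every training set goes through the full
    greedy step-down procedure starting from that structure, so model
    selection is honestly refitted inside the bootstrap.
    """
    if (structure is None) == (reduce_from is None):
        raise ValueError("give exactly one of structure / reduce_from")

    def fit_train(train: pd.DataFrame):
        table = msdata.prepare(train, delta=delta, covariates=covariates)
        if reduce_from is not None:
            _, fitted = specification.reduce(table, reduce_from, alpha=alpha, ties=ties)
        else:
            fitted = cox_engine.fit(table, structure, ties=ties)

        def predict(recs: pd.DataFrame, tgrid: np.ndarray) -> np.ndarray:
            out = np.empty((len(recs), len(tgrid)))
            for i, row in enumerate(recs.itertuples(index=False)):
                profile = {c: getattr(row, c) for c in covariates}
                out[i] = prediction.overall_survival(fitted, profile, tgrid, mass=mass)
            return out

        return predict

    return fit_train


def km_pipeline() -> Pipeline:
    """Null-model pipeline: the training Kaplan-Meier curve for everyone."""

    def fit_train(train: pd.DataFrame):
        def predict(recs: pd.DataFrame, tgrid: np.ndarray) -> np.ndarray:
            return np.tile(km_null(train, tgrid), (len(recs), 1))

        return predict

    return fit_train


def prediction_error(
    records: pd.DataFrame,
    pipelines: dict[str, Pipeline],
    tgrid: np.ndarray | None = None,
    B: int = 300,
    train_n: int = 300,
    seed: int = 0,
) -> dict[str, ErrorComponents]:
    """0.632+ prediction error curves for several modelling pipelines.

    Every pipeline is scored on the same training subsamples (the subsample
    generator is re-seeded identically per pipeline), so the curves are
    directly comparable.
    """
    if tgrid is None:
        tgrid = default_grid(records)
    G = censoring_km(records)
    out: dict[str, ErrorComponents] = {}
    for name, pipe in sorted(pipelines.items()):
        predictor = pipe(records)
        surv = predictor(records, tgrid)
        app = ipcw_brier(surv, records, tgrid, G)
        noinf = noinformation_error(surv, records, tgrid, G)
        cv = bootstrap_cv(pipe, records, tgrid, B=B, train_n=train_n, seed=seed)
        out[name] = err632plus(app, cv, noinf, tgrid)
    return out
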