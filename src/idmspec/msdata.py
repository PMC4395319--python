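"""Wide-format subject data: validation, tie adjustment, stacking.

A cohort is a table with one row per subject:

    id, t_prog, s_prog, t_death, s_death, age, residual_tumor, figo_high

``t_prog`` is months from origin (surgery) to progression or to censoring on
that endpoint, ``t_death`` months to death or censoring.  For model fitting
the cohort is expanded to the stacked counting-process ("long") format with
one row per subject and at-risk transition, on each transition's reset
clock: every subject contributes a 0->1 and a 0->2 row over
(0, min(t_prog, t_death)], and progressors additionally a 1->2 row over
(0, t_death - t_prog] carrying the sojourn time ``t010 = t_prog`` as a
covariate.

Progression and death recorded at the same time would give the 1->2 row
zero length; such ties are resolved before stacking by moving the
progression time half a month earlier (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import DEFAULT_COVARIATES, EffectStructure, T010, TRANSITIONS

WIDE_COLUMNS = ("id", "t_prog", "s_prog", "t_death", "s_death")
STACKED_COLUMNS = ("id", "transition", "tstart", "tstop", "status", T010)


class DataError(ValueError):
    """Raised for subject data violating the illness-death layout."""


@dataclass
class ValidationReport:
    """Per-record outcome of :func:`validate`."""

    n: int
    issues: dict[object, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def failed_ids(self) -> list[object]:
        return list(self.issues)

    def raise_if_failed(self) -> None:
        if not self.ok:
            lines = [f"  {i}: {'; '.join(msgs)}" for i, msgs in self.issues.items()]
            raise DataError("invalid subject records:\n" + "\n".join(lines))


def read_wide(path, covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Read a wide-format cohort CSV and check the header."""
    df = pd.read_csv(path)
    missing = [c for c in (*WIDE_COLUMNS, *covariates) if c not in df.columns]
    if missing:
        raise DataError(f"input is missing columns {missing}")
    return df


def validate(records: pd.DataFrame, covariates: tuple[str, ...] | None = None) -> ValidationReport:
    """Check the wide-format invariants record by record.

    Flags duplicate ids, negative or missing times, non-binary status codes,
    progression recorded after death, and (when ``covariates`` is given)
    missing covariate values.  Nothing is modified; callers decide how to
    handle flagged records.
    """
    missing = [c for c in WIDE_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"records are missing columns {missing}")
    report = ValidationReport(n=len(records))

    def flag(rid, msg):
        report.issues.setdefault(rid, []).append(msg)

    dup = records["id"][records["id"].duplicated()]
    for rid in dup.unique():
        flag(rid, "duplicate id")
    cols = list(WIDE_COLUMNS[1:]) + [c for c in (covariates or ()) if c in records.columns]
    for row in records.itertuples(index=False):
        rid = row.id
        if any(pd.isna(getattr(row, c)) for c in cols):
            flag(rid, "missing value")
            continue
        if row.t_prog < 0 or row.t_death < 0:
            flag(rid, "negative time")
        if row.s_prog not in (0, 1) or row.s_death not in (0, 1):
            flag(rid, "non-binary status")
            continue
        if row.s_prog == 1 and row.t_prog > row.t_death:
            flag(rid, "progression after death/last contact")
        if row.s_prog == 0 and row.t_prog > row.t_death:
            flag(rid, "censoring for progression after last contact")
    return report


def adjust_ties(records: pd.DataFrame, delta: float = 0.5) -> pd.DataFrame:
    """Break exact progression/death ties by shifting progression earlier.

    For every subject with both events at the same time, ``t_prog`` is
    replaced by ``t_prog - delta`` (months) so the post-progression survival
    time is positive.  A tie too close to the origin for the shift cannot be
    repaired silently and raises.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    out = records.copy()
    tied = (out["s_prog"] == 1) & (out["s_death"] == 1) & (out["t_prog"] == out["t_death"])
    bad = tied & (out["t_prog"] <= delta)
    if bad.any():
        raise DataError(
            "tie adjustment would produce non-positive progression times for ids "
            f"{out.loc[bad, 'id'].tolist()}"
        )
    out.loc[tied, "t_prog"] = out.loc[tied, "t_prog"] - delta
    return out


def to_stacked(
    records: pd.DataFrame,
    structure: EffectStructure | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Expand validated, tie-adjusted wide records to the stacked long format.

    Every subject gets a 0->1 and a 0->2 row spanning (0, min(t_prog,
    t_death)] with statuses ``s_prog`` and ``s_death and not s_prog``; a
    progressor additionally gets a 1->2 row spanning (0, t_death - t_prog]
    on the reset clock, with ``t010`` set to the healthy sojourn time.  Raw
    covariate columns are carried on every row; when ``structure`` is given,
    one design column per free coefficient is appended (the covariate's
    value on that coefficient's transitions, 0 elsewhere).
    """
    for c in covariates:
        if c not in records.columns:
            raise DataError(f"covariate {c!r} not in records")
    if structure is not None:
        unknown = [
            c for c in structure.covariates if c != T010 and c not in records.columns
        ]
        if unknown:
            raise DataError(f"structure references unknown covariates {unknown}")

    rec = records
    t0_stop = np.minimum(rec["t_prog"].to_numpy(float), rec["t_death"].to_numpy(float))
    if (t0_stop <= 0).any():
        raise DataError("zero-length observation in state 0; adjust or drop these records")
    s_prog = rec["s_prog"].to_numpy(int)
    s_death = rec["s_death"].to_numpy(int)

    blocks = []
    base = {c: rec[c].to_numpy() for c in covariates}
    blocks.append(
        pd.DataFrame(
            {
                "id": rec["id"],
                "transition": "01",
                "tstart": 0.0,
                "tstop": t0_stop,
                "status": s_prog,
                T010: np.nan,
                **base,
            }
        )
    )
    blocks.append(
        pd.DataFrame(
            {
                "id": rec["id"],
                "transition": "02",
                "tstart": 0.0,
                "tstop": t0_stop,
                "status": s_death * (1 - s_prog),
                T010: np.nan,
                **base,
            }
        )
    )
    prog = rec[rec["s_prog"] == 1]
    if len(prog):
        dur = prog["t_death"].to_numpy(float) - prog["t_prog"].to_numpy(float)
        if (dur <= 0).any():
            raise DataError(
                "non-positive 1->2 duration; progression/death ties must be adjusted first"
            )
        blocks.append(
            pd.DataFrame(
                {
                    "id": prog["id"],
                    "transition": "12",
                    "tstart": 0.0,
                    "tstop": dur,
                    "status": prog["s_death"].to_numpy(int),
                    T010: prog["t_prog"].to_numpy(float),
                    **{c: prog[c].to_numpy() for c in covariates},
                }
            )
        )
    stacked = pd.concat(blocks, ignore_index=True)
    stacked = stacked.sort_values(["id", "transition"], kind="stable").reset_index(drop=True)
    if structure is not None:
        stacked = add_design_columns(stacked, structure)
    return stacked


def add_design_columns(stacked: pd.DataFrame, structure: EffectStructure) -> pd.DataFrame:
    """Append one 0-padded design column per coefficient of ``structure``."""
    out = stacked.copy()
    trans = stacked["transition"].to_numpy()
    for eff in structure.effects:
        vals = stacked[eff.covariate].to_numpy(float)
        mask = np.isin(trans, list(eff.transitions))
        out[eff.label] = np.where(mask, np.nan_to_num(vals), 0.0)
    for term in structure.proportional_terms:
        out[term.label] = np.isin(trans, list(term.indicator_transitions)).astype(float)
    return out


def collapse_stacked(
    stacked: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Rebuild the wide format from a stacked table (round-trip inverse)."""
    rows = []
    for rid, grp in stacked.groupby("id", sort=False):
        by_t = {t: grp[grp["transition"] == t] for t in TRANSITIONS}
        if len(by_t["01"]) != 1 or len(by_t["02"]) != 1:
            raise DataError(f"subject {rid}: expected exactly one 01 and one 02 row")
        r01 = by_t["01"].iloc[0]
        r02 = by_t["02"].iloc[0]
        s_prog = int(r01["status"])
        has12 = len(by_t["12"]) == 1
        if has12 != bool(s_prog):
            raise DataError(f"subject {rid}: 1->2 row must exist iff progression observed")
        if s_prog:
            r12 = by_t["12"].iloc[0]
            t_prog = float(r01["tstop"])
            t_death = t_prog + float(r12["tstop"])
            s_death = int(r12["status"])
        else:
            t_prog = t_death = float(r01["tstop"])
            s_death = int(r02["status"])
        rows.append(
            {
                "id": rid,
                "t_prog": t_prog,
                "s_prog": s_prog,
                "t_death": t_death,
                "s_death": s_death,
                **{c: r01[c] for c in covariates if c in stacked.columns},
            }
        )
    return pd.DataFrame(rows)


def prepare(
    records: pd.DataFrame,
    structure: EffectStructure | None = None,
    delta: float = 0.5,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Validate, adjust ties, and stack in one call."""
    validate(records, covariates).raise_if_failed()
    return to_stacked(adjust_ties(records, delta), structure, covariates)
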