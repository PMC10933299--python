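"""Proportional-hazards analysis of single-cell death and puncta formation.

Longitudinal automated microscopy yields, per cell, a time to death or to
puncta formation, possibly right-censored. Risk differences between
genotypes (or between expression/CV quintiles, or between cells that were
diffuse vs punctate on day 1) are quantified with the Cox proportional
hazards model: the hazard of cell ``i`` in group ``g`` is
``h_i(t) = h_0(t) * exp(beta_g)``, with ``exp(beta_g)`` the hazard ratio
relative to a reference group. Pooled replicate experiments enter as
strata, i.e. each experiment keeps its own baseline hazard ``h_0`` while
the group effects are shared.

Fitting is delegated to :class:`lifelines.CoxPHFitter`, which maximizes the
partial likelihood with Efron's tie correction — appropriate here because
imaging on a daily grid produces heavily tied event times. Confidence
intervals and p-values are Wald statistics on the log-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "CoxResult",
    "SurvivalError",
    "SeparationError",
    "fit_cox",
    "quintile_bin",
    "hazard_by_quintile",
    "diffuse_vs_punctate_analysis",
    "risk_table_report",
]

#: |beta| beyond which a monotone partial likelihood (complete separation)
#: is assumed; on this data scale true log-hazards are O(1).
_SEPARATION_BETA = 15.0


class SurvivalError(ValueError):
    """Invalid input to a survival analysis."""


class SeparationError(SurvivalError):
    """Monotone partial likelihood: a group separates the risk sets."""


@dataclass
class CoxResult:
    """One contrast of a proportional-hazards fit (one table row)."""

    term: str
    reference: str
    n: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    strata: str | None = None


def fit_cox(
    records: pd.DataFrame,
    *,
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
    reference: str | None = None,
    strata_col: str | None = None,
) -> list[CoxResult]:
    """Cox regression of group membership against a reference group.

    Each non-reference group contributes one dummy covariate; the returned
    list holds one :class:`CoxResult` per non-reference group with
    ``HR = exp(beta_hat)``, Wald 95% CI and Wald p. ``strata_col`` (e.g. the
    experiment date) fits separate baseline hazards per stratum.

    Raises :class:`SurvivalError` when no events are observed or fewer than
    two groups are present, and :class:`SeparationError` when the partial
    likelihood is monotone (e.g. one group's events all precede the
    other's), rather than silently returning a divergent estimate.
    """
    _check_records(records, duration_col, event_col)
    groups = list(pd.unique(records[group_col]))
    if len(groups) < 2:
        raise SurvivalError("need at least 2 groups for a contrast")
    if reference is None:
        reference = sorted(groups)[0]
    if reference not in groups:
        raise SurvivalError(f"reference group {reference!r} not present")

    others = [g for g in groups if g != reference]
    model = pd.DataFrame(
        {
            duration_col: records[duration_col].to_numpy(dtype=float),
            event_col: records[event_col].to_numpy(dtype=int),
        }
    )
    colnames = {}
    for i, g in enumerate(others):
        col = f"_g{i}"
        colnames[col] = g
        model[col] = (records[group_col] == g).to_numpy(dtype=float)
    if strata_col is not None:
        model["_stratum"] = records[strata_col].to_numpy()

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                model,
                duration_col=duration_col,
                event_col=event_col,
                strata=["_stratum"] if strata_col is not None else None,
            )
    except ConvergenceError as exc:
        raise SeparationError(f"Cox fit did not converge: {exc}") from exc

    summary = cph.summary
    if np.any(np.abs(summary["coef"].to_numpy()) > _SEPARATION_BETA):
        raise SeparationError(
            "divergent log-hazard estimate: likely complete separation"
        )

    counts = records[group_col].value_counts()
    strata_desc = f"stratified by {strata_col}" if strata_col else None
    results = []
    for col, g in colnames.items():
        row = summary.loc[col]
        results.append(
            CoxResult(
                term=str(g),
                reference=str(reference),
                n=int(counts[g]),
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
                beta=float(row["coef"]),
                se=float(row["se(coef)"]),
                strata=strata_desc,
            )
        )
    return results


def _check_records(records: pd.DataFrame, duration_col: str, event_col: str) -> None:
    if records.empty:
        raise SurvivalError("empty event table")
    if np.any(records[duration_col].to_numpy(dtype=float) <= 0):
        raise SurvivalError("event times must be positive")
    events = records[event_col].to_numpy()
    if not np.isin(events, [0, 1]).all():
        raise SurvivalError("event indicator must be 0 or 1")
    if int(events.sum()) == 0:
        raise SurvivalError("no observed events")


def quintile_bin(values) -> np.ndarray:
    """Rank-based assignment into 5 near-equal bins (1 = lowest values).

    Ties are resolved by stable rank order (original row order among equal
    values), so bin sizes differ by at most one regardless of ties.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5:
        raise SurvivalError("need at least 5 values for quintile binning")
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    for q, idx in enumerate(np.array_split(order, 5)):
        bins[idx] = q + 1
    return bins


def hazard_by_quintile(
    records: pd.DataFrame,
    *,
    value_col: str,
    duration_col: str = "time",
    event_col: str = "event",
    within_col: str | None = "group",
    strata_col: str | None = None,
) -> pd.DataFrame:
    """Hazard of quintiles 2-5 vs quintile 1 of a day-1 measurement.

    Quintiles of ``value_col`` (day-1 expression or day-1 CV) are assigned
    within each population given by ``within_col`` (or over the whole table
    when None); the lowest quintile is always the reference. Returns a tidy
    frame with one row per population x quintile contrast.
    """
    records = records.copy()
    populations = (
        [(g, sub) for g, sub in records.groupby(within_col, sort=True)]
        if within_col is not None
        else [("all", records)]
    )
    rows = []
    for pop, sub in populations:
        sub = sub.copy()
        sub["_quintile"] = [f"Q{q}" for q in quintile_bin(sub[value_col])]
        results = fit_cox(
            sub,
            duration_col=duration_col,
            event_col=event_col,
            group_col="_quintile",
            reference="Q1",
            strata_col=strata_col,
        )
        for r in results:
            rows.append(
                {
                    "population": pop,
                    "quintile": r.term,
                    "n": r.n,
                    "hazard_ratio": r.hazard_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                    "beta": r.beta,
                    "se": r.se,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["population", "quintile"]).reset_index(drop=True)


def diffuse_vs_punctate_analysis(
    records: pd.DataFrame,
    *,
    control_group: str,
    flag_col: str = "day1_punctate",
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
    strata_col: str | None = None,
    min_events: int = 1,
) -> tuple[list[CoxResult], list[CoxResult]]:
    """Risk contrasts splitting each genotype by its day-1 reporter pattern.

    Two families are returned:

    * vs-control — every genotype x {diffuse, punctate} subgroup against the
      (unsplit) control group;
    * within-genotype — punctate vs diffuse of the same genotype.

    Subgroups with no members — or with fewer than ``min_events`` observed
    events, which would make the partial likelihood monotone in that
    subgroup's coefficient — are omitted with a warning; an empty control
    group is an error.
    """
    if flag_col not in records.columns:
        raise SurvivalError(f"missing {flag_col!r} column")
    control = records[records[group_col] == control_group]
    if control.empty:
        raise SurvivalError(f"control group {control_group!r} is empty")

    labeled = records.copy()
    suffix = np.where(labeled[flag_col].astype(bool), "_punctate", "_diffuse")
    labeled["_subgroup"] = np.where(
        labeled[group_col] == control_group,
        control_group,
        labeled[group_col].astype(str) + suffix,
    )
    events_per = labeled.groupby("_subgroup")[event_col].sum()
    thin = [
        g for g, n in events_per.items() if g != control_group and n < min_events
    ]
    if thin:
        warnings.warn(
            f"subgroups omitted from the vs-control family (fewer than "
            f"{min_events} events): {sorted(thin)}",
            stacklevel=2,
        )
    kept = labeled[~labeled["_subgroup"].isin(thin)]
    vs_control = fit_cox(
        kept,
        duration_col=duration_col,
        event_col=event_col,
        group_col="_subgroup",
        reference=control_group,
        strata_col=strata_col,
    )

    within: list[CoxResult] = []
    for g, sub in labeled[labeled[group_col] != control_group].groupby(
        group_col, sort=True
    ):
        flags = sub[flag_col].astype(bool)
        events_d = int(sub.loc[~flags, event_col].sum())
        events_p = int(sub.loc[flags, event_col].sum())
        if flags.all() or (~flags).all() or min(events_d, events_p) < min_events:
            warnings.warn(
                f"group {g!r} has an empty or event-free diffuse/punctate "
                "subgroup; within-genotype contrast omitted",
                stacklevel=2,
            )
            continue
        sub = sub.copy()
        sub["_state"] = np.where(flags, f"{g}_punctate", f"{g}_diffuse")
        within.extend(
            fit_cox(
                sub,
                duration_col=duration_col,
                event_col=event_col,
                group_col="_state",
                reference=f"{g}_diffuse",
                strata_col=strata_col,
            )
        )
    return vs_control, within


def risk_table_report(
    results: list[CoxResult], *, include_reference: bool = True
) -> pd.DataFrame:
    """Format Cox contrasts as a risk table.

    Columns ``group, n, hazard_ratio, ci_low, ci_high, p``; hazard ratios
    and CI bounds are rounded to 4 decimals, the reference group (HR exactly
    1) heads the table when all results share one reference. p-values are
    kept as floats; serialization renders values below 1e-3 in scientific
    notation automatically.
    """
    if not results:
        raise SurvivalError("no results to tabulate")
    rows = []
    references = {r.reference for r in results}
    if include_reference and len(references) == 1:
        ref = results[0].reference
        rows.append(
            {
                "group": ref,
                "n": np.nan,
                "hazard_ratio": 1.0,
                "ci_low": 1.0,
                "ci_high": 1.0,
                "p": np.nan,
            }
        )
    for r in results:
        rows.append(
            {
                "group": r.term,
                "n": r.n,
                "hazard_ratio": round(r.hazard_ratio, 4),
                "ci_low": round(r.ci_low, 4),
                "ci_high": round(r.ci_high, 4),
                "p": r.p,
            }
        )
    return pd.DataFrame(rows)
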