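"""Cohort synchronization index (SIg) and period statistics.

In a sequential-seeding experiment, cohorts of plants are sown at fixed
intervals, so germination timing is staggered by design.  Whether a later
phenological event (bolting, flowering initiation, flowering termination,
whole-plant senescence) is *synchronized* is judged relative to that
stagger: take the cohort means of the event day, and compare their
variance with the variance of the cohort mean germination days,

    SIg = log2( Var(germination cohort means) / Var(event cohort means) ).

SIg > 0 means the event's spread across cohorts shrank relative to the
germination stagger (synchrony; SIg = 1 and 2 correspond to halved and
quartered variance), SIg < 0 means it grew (desynchrony; -1 and -2
correspond to doubled and quadrupled variance).

Both variances are sample variances (denominator n-1) over the same set
of cohorts; the estimator choice cancels in the ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVENT_COLUMNS",
    "SIgResult",
    "CorrelationResult",
    "cohort_event_means",
    "sig_index",
    "classify_all_events",
    "period_lengths",
    "correlate",
]

#: Ordered phenological event columns of a phenology table.
EVENT_COLUMNS = ["germination", "bolting", "flowering_init", "flowering_term", "senescence"]

#: Events for which synchrony is reported (germination is the reference).
REPORTED_EVENTS = ["bolting", "flowering_init", "flowering_term", "senescence"]


@dataclass(frozen=True)
class SIgResult:
    """SIg for one event within one accession x regime group."""

    event: str
    var_germination: float
    var_event: float
    sig: float  # log2 units; +inf when var_event == 0; nan when undefined
    classification: str  # synchronized | desynchronized | neutral | undefined
    exact: bool = False  # var_event == 0: synchrony is exact, sig is +inf
    strong: bool = False  # |sig| beyond the strong-band threshold


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float  # nan when undefined (constant input)
    n: int
    p_value: float
    defined: bool


def cohort_event_means(
    records: pd.DataFrame,
    event: str,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-cohort mean event day within each accession x regime group.

    A cohort contributes only if at least ``min_fraction`` of its plants
    have the event recorded, guarding against means driven by a lone
    survivor.  Returns a tidy frame with columns accession, regime,
    cohort, mean_day, n.
    """
    if event not in records.columns:
        raise KeyError(f"unknown event column {event!r}")
    rows = []
    for (accession, regime, cohort), grp in records.groupby(
        ["accession", "regime", "cohort"], sort=True
    ):
        values = grp[event].dropna()
        if len(grp) == 0 or len(values) / len(grp) < min_fraction or len(values) == 0:
            warnings.warn(
                f"cohort {cohort} ({accession}/{regime}) dropped for event {event!r}: "
                f"{len(values)}/{len(grp)} recorded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "accession": accession,
                "regime": regime,
                "cohort": cohort,
                "mean_day": float(values.mean()),
                "n": int(len(values)),
            }
        )
    return pd.DataFrame(rows, columns=["accession", "regime", "cohort", "mean_day", "n"])


def sig_index(
    germination_means: np.ndarray,
    event_means: np.ndarray,
    event: str = "",
    strong_band: float = 4.0,
) -> SIgResult:
    """SIg = log2(Var(germination means) / Var(event means)).

    Inputs are the per-cohort mean days for germination and for the event,
    over the *same* cohorts in the same order.  Classification is by sign;
    ``strong`` flags |SIg| above ``strong_band`` (default 4, i.e. a 16-fold
    variance change).  Zero event variance yields +inf with ``exact=True``;
    zero germination variance makes the index undefined.
    """
    g = np.asarray(germination_means, dtype=float)
    e = np.asarray(event_means, dtype=float)
    if g.shape != e.shape:
        raise ValueError(f"cohort sets differ: {g.shape} germination vs {e.shape} event means")
    if g.size < 2:
        return SIgResult(event, np.nan, np.nan, np.nan, "undefined")
    var_g = float(np.var(g, ddof=1))
    var_e = float(np.var(e, ddof=1))
    if var_g == 0.0:
        return SIgResult(event, var_g, var_e, np.nan, "undefined")
    if var_e == 0.0:
        return SIgResult(event, var_g, var_e, math.inf, "synchronized", exact=True, strong=True)
    sig = math.log2(var_g / var_e)
    if sig > 0:
        cls = "synchronized"
    elif sig < 0:
        cls = "desynchronized"
    else:
        cls = "neutral"
    return SIgResult(event, var_g, var_e, sig, cls, strong=abs(sig) > strong_band)


def classify_all_events(
    records: pd.DataFrame,
    events: list[str] = REPORTED_EVENTS,
    min_fraction: float = 0.5,
    strong_band: float = 4.0,
) -> pd.DataFrame:
    """SIg table: one row per event x accession x regime, deterministically sorted.

    Cohorts enter an event's SIg only if they pass the missing-data policy
    for both germination and that event; groups with fewer than two usable
    cohorts are reported as undefined.
    """
    rows = []
    germ = cohort_event_means(records, "germination", min_fraction)
    for event in events:
        ev = cohort_event_means(records, event, min_fraction)
        for (accession, regime), _ in records.groupby(["accession", "regime"], sort=True):
            g_grp = germ[(germ["accession"] == accession) & (germ["regime"] == regime)]
            e_grp = ev[(ev["accession"] == accession) & (ev["regime"] == regime)]
            shared = sorted(set(g_grp["cohort"]) & set(e_grp["cohort"]))
            if len(shared) < 2:
                res = SIgResult(event, np.nan, np.nan, np.nan, "undefined")
            else:
                g_means = g_grp.set_index("cohort").loc[shared, "mean_day"].to_numpy()
                e_means = e_grp.set_index("cohort").loc[shared, "mean_day"].to_numpy()
                res = sig_index(g_means, e_means, event, strong_band)
            rows.append(
                {
                    "accession": accession,
                    "regime": regime,
                    "event": event,
                    "var_germination": res.var_germination,
                    "var_event": res.var_event,
                    "sig": res.sig,
                    "classification": res.classification,
                    "exact": res.exact,
                    "strong": res.strong,
                    "n_cohorts": len(shared),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["accession", "regime", "event"], kind="stable").reset_index(drop=True)


def period_lengths(records: pd.DataFrame) -> pd.DataFrame:
    """Vegetative (fi - g) and flowering (ft - fi) period lengths in days.

    Missing events propagate to missing periods; a zero-length flowering
    period (termination on the initiation day) is allowed.
    """
    out = records[["plant_id"]].copy() if "plant_id" in records.columns else pd.DataFrame(index=records.index)
    out["vegetative_period"] = records["flowering_init"] - records["germination"]
    out["flowering_period"] = records["flowering_term"] - records["flowering_init"]
    return out


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation with an explicit undefined flag for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 paired finite values, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_name, y_name, np.nan, int(x.size), np.nan, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(r), int(x.size), float(p), defined=True)
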