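"""Comparison analytics between the dynamic bed count and P/N capacity.

Per-unit descriptive summaries (mean and sample SD of census, authorized
capacity and both capacity calculations, plus a pooled all-units row), the
paired two-tailed Student t test on aligned unit-hours, the per-hour delta
series, selection of the unit whose dynamic bed count varies most, and
seeded random sampling of hours for snapshot tables.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import WardTrace

__all__ = [
    "UnitSummary",
    "SampledRow",
    "TTestResult",
    "DegenerateTTestError",
    "POOLED_UNIT_ID",
    "trace_frame",
    "summarize_units",
    "paired_t_test",
    "delta_series",
    "max_variance_unit",
    "sample_rows",
]

logger = logging.getLogger("wardcap.analytics")

#: unit_id used for the pooled summary row concatenating all unit-hours
POOLED_UNIT_ID = "All units"


class DegenerateTTestError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class UnitSummary:
    """One summary row: means and sample SDs plus the paired-t comparison."""

    unit_id: str
    n_hours: int
    census_mean: float
    census_sd: float
    authorized_capacity_mean: float
    authorized_capacity_sd: float
    dbc_mean: float
    dbc_sd: float
    pn_mean: float
    pn_sd: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class SampledRow:
    """One randomly sampled unit-hour in snapshot-table shape."""

    unit_id: str
    date: str
    time: str
    census: int
    pn_capacity: float
    dbc: float
    difference: float

    def __post_init__(self) -> None:
        if abs(self.difference - (self.dbc - self.pn_capacity)) > 0.05 + 1e-9:
            raise ValueError("difference inconsistent with dbc - pn_capacity")


def trace_frame(trace: WardTrace) -> pd.DataFrame:
    """Flatten a computed trace into a tidy hourly DataFrame."""
    if trace.results is None:
        raise ValueError("trace has no computed results")
    records = []
    for snap, res in trace.rows():
        records.append(
            {
                "unit_id": trace.unit_id,
                "timestamp": snap.timestamp,
                "census": snap.census,
                "authorized_capacity": trace.authorized_capacity,
                "dbc": res.dbc,
                "pn_capacity": res.pn_capacity,
                "difference": res.difference,
                "status": res.status.value,
            }
        )
    return pd.DataFrame.from_records(records)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed paired Student t test on aligned series.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with sample SD (n-1 denominator) of
    the differences ``d = x - y``; ``df = n-1``; p is the two-tailed tail
    probability under Student's t (no normal approximation at any n).
    Zero-variance differences raise :class:`DegenerateTTestError`: with a
    nonzero mean the message states "p -> 0", with zero mean "no
    difference".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError(f"paired t test needs n >= 2, got n={n}")
    d = x - y
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            raise DegenerateTTestError("degenerate: no difference")
        raise DegenerateTTestError("degenerate: p -> 0")
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)


def _summary_from_arrays(
    unit_id: str,
    census: np.ndarray,
    cap: np.ndarray,
    dbc: np.ndarray,
    pn: np.ndarray,
) -> UnitSummary:
    def sd(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0

    try:
        t, _, p = paired_t_test(dbc, pn)
    except DegenerateTTestError as exc:
        # keep the summary total: identical series carry no evidence (p=1),
        # a constant nonzero offset is unambiguous (p=0)
        t, p = 0.0, (1.0 if "no difference" in str(exc) else 0.0)
    return UnitSummary(
        unit_id=unit_id,
        n_hours=int(census.size),
        census_mean=float(census.mean()),
        census_sd=sd(census),
        authorized_capacity_mean=float(cap.mean()),
        authorized_capacity_sd=sd(cap),
        dbc_mean=float(dbc.mean()),
        dbc_sd=sd(dbc),
        pn_mean=float(pn.mean()),
        pn_sd=sd(pn),
        t_statistic=t,
        p_value=p,
    )


def summarize_units(traces: Sequence[WardTrace]) -> list[UnitSummary]:
    """Per-unit summary rows plus a pooled row over all unit-hours.

    Means are arithmetic; SDs use the n-1 denominator.  The pooled row
    concatenates unit-hours across units (it does not average unit means),
    so every pooled statistic is computed over the combined hourly series.
    """
    if not traces:
        raise ValueError("no traces to summarize")
    frames = []
    out: list[UnitSummary] = []
    for trace in traces:
        if len(trace) == 0:
            raise ValueError(f"trace for unit {trace.unit_id!r} is empty")
        df = trace_frame(trace)
        frames.append(df)
        out.append(
            _summary_from_arrays(
                trace.unit_id,
                df["census"].to_numpy(dtype=float),
                df["authorized_capacity"].to_numpy(dtype=float),
                df["dbc"].to_numpy(dtype=float),
                df["pn_capacity"].to_numpy(dtype=float),
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    out.append(
        _summary_from_arrays(
            POOLED_UNIT_ID,
            pooled["census"].to_numpy(dtype=float),
            pooled["authorized_capacity"].to_numpy(dtype=float),
            pooled["dbc"].to_numpy(dtype=float),
            pooled["pn_capacity"].to_numpy(dtype=float),
        )
    )
    return out


def delta_series(trace: WardTrace) -> np.ndarray:
    """Per-hour difference dbc - pn, in trace order."""
    if trace.results is None or len(trace) == 0:
        raise ValueError("trace must be nonempty with computed results")
    return np.array([r.difference for r in trace.results], dtype=float)


def max_variance_unit(traces: Sequence[WardTrace]) -> str:
    """Unit whose dynamic bed count series has the largest sample SD.

    Ties break to the lexicographically first unit_id and are logged.
    """
    if not traces:
        raise ValueError("no traces given")
    sds: dict[str, float] = {}
    for trace in traces:
        if trace.results is None or len(trace) < 2:
            raise ValueError(f"trace for {trace.unit_id!r} has fewer than 2 hours")
        sds[trace.unit_id] = float(
            np.std([r.dbc for r in trace.results], ddof=1)
        )
    best = max(sds.values())
    winners = sorted(u for u, s in sds.items() if s == best)
    if len(winners) > 1:
        logger.info(
            "event=sd_tie units=%s chosen=%s sd=%.6f", ",".join(winners), winners[0], best
        )
    return winners[0]


def sample_rows(trace: WardTrace, k: int, seed: int) -> list[SampledRow]:
    """``k`` distinct hours drawn uniformly without replacement, chronological.

    Uses the standard-library ``random`` generator seeded with ``seed`` to
    draw row indices, then sorts the selection by timestamp.  Identical
    (trace, k, seed) yield identical rows.
    """
    if trace.results is None:
        raise ValueError("trace has no computed results")
    n = len(trace)
    if k > n:
        raise ValueError(f"cannot sample {k} rows from a {n}-hour trace")
    idx = sorted(random.Random(seed).sample(range(n), k))
    out = []
    for i in idx:
        snap, res = trace.snapshots[i], trace.results[i]
        out.append(
            SampledRow(
                unit_id=trace.unit_id,
                date=snap.timestamp.date().isoformat(),
                time=f"{snap.timestamp.hour:02d}:00",
                census=snap.census,
                pn_capacity=res.pn_capacity,
                dbc=res.dbc,
                difference=res.difference,
            )
        )
    return out
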