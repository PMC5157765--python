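"""Monthly report-count series and monthly PRR series.

The lead-lag analysis operates on zero-filled calendar-month counts of
reports per stream, optionally restricted to a named specific AE. The
proportional reporting ratio (PRR) series is a within-drug
disproportionality measure: for each month the 2x2 table contrasts the
target-AE reporting fraction in that month against the fraction in all
other months of the study window.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class CountSeries:
    """Zero-filled monthly report counts over an inclusive calendar span."""

    values: pd.Series  # int counts indexed by a monthly PeriodIndex
    stream: str
    ae_filter: str = "all"

    def __post_init__(self):
        idx = self.values.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise TypeError("CountSeries requires a monthly PeriodIndex")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("month index must be sorted and unique")
        full = pd.period_range(idx[0], idx[-1], freq="M")
        if len(full) != len(idx):
            raise ValueError("month index has gaps; zero-fill before constructing")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def start(self) -> pd.Period:
        return self.values.index[0]

    @property
    def end(self) -> pd.Period:
        return self.values.index[-1]

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def align_to(self, start: pd.Period, end: pd.Period) -> "CountSeries":
        """Restrict or zero-extend to the span [start, end]."""
        full = pd.period_range(start, end, freq="M")
        vals = self.values.reindex(full, fill_value=0)
        return replace(self, values=vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.values.index.astype(str),
                "stream": self.stream,
                "ae_filter": self.ae_filter,
                "count": np.asarray(self.values),
            }
        )


def _record_months(records: pd.DataFrame) -> pd.PeriodIndex:
    return pd.PeriodIndex(records["event_month"], freq="M")


def _filter_mask(records: pd.DataFrame, ae_filter: str) -> pd.Series:
    if ae_filter == "all":
        return pd.Series(True, index=records.index)
    col = f"has_{ae_filter}"
    if col not in records.columns:
        raise KeyError(
            f"records carry no specific-AE flag {col!r}; classify the dataset first"
        )
    return records[col].astype(bool)


def monthly_counts(
    dataset,
    ae_filter: str = "all",
    span: tuple | None = None,
    clip: bool = False,
) -> CountSeries:
    """Zero-filled monthly counts of records matching ``ae_filter``.

    ``dataset`` is a classified CleanDataset (or its records frame). The
    span defaults to [first record month, last record month]; a span that
    would drop existing matching records raises unless ``clip=True``.
    """
    records = getattr(dataset, "records", dataset)
    stream = getattr(dataset, "stream", "unknown")
    mask = _filter_mask(records, ae_filter)
    months = _record_months(records[mask])
    if span is not None:
        start, end = (pd.Period(span[0], freq="M"), pd.Period(span[1], freq="M"))
    elif len(months):
        start, end = months.min(), months.max()
    else:
        raise ValueError("empty dataset needs an explicit span")
    if len(months) and ((months < start).any() or (months > end).any()) and not clip:
        raise ValueError(
            "span excludes existing records; pass clip=True to drop them"
        )
    full = pd.period_range(start, end, freq="M")
    counts = (
        pd.Series(1, index=months).groupby(level=0).sum().reindex(full, fill_value=0)
    )
    return CountSeries(values=counts.astype(int), stream=stream, ae_filter=ae_filter)


@dataclass
class PRRSeries:
    """Monthly PRR with the underlying 2x2 margins.

    ``table`` columns: month, a, b, c, d, prr, defined. For month t,
    a = target-AE reports in t, b = other reports in t, c = target reports
    in all other months, d = other reports in all other months;
    PRR_t = (a/(a+b)) / (c/(c+d)). Months where a+b = 0 or c = 0 are
    flagged undefined rather than dropped.
    """

    table: pd.DataFrame
    target_ae: str

    @property
    def values(self) -> pd.Series:
        return self.table.set_index("month")["prr"]


def prr_series(
    dataset, target_ae: str, continuity: bool = False
) -> PRRSeries:
    """Month-versus-rest PRR for one named specific AE.

    ``continuity=True`` adds 0.5 to all four cells when exactly one cell
    is zero (Haldane-style correction), otherwise zero margins leave the
    month undefined (NaN).
    """
    records = getattr(dataset, "records", dataset)
    mask = _filter_mask(records, target_ae)
    months = _record_months(records)
    full = pd.period_range(months.min(), months.max(), freq="M")
    tgt = pd.Series(1, index=months[mask]).groupby(level=0).sum().reindex(full, fill_value=0)
    tot = pd.Series(1, index=months).groupby(level=0).sum().reindex(full, fill_value=0)
    a = tgt.to_numpy(float)
    b = (tot - tgt).to_numpy(float)
    c = a.sum() - a
    d = b.sum() - b
    if continuity:
        one_zero = (np.stack([a, b, c, d]) == 0).sum(axis=0) == 1
        a = a + 0.5 * one_zero
        b = b + 0.5 * one_zero
        c = c + 0.5 * one_zero
        d = d + 0.5 * one_zero
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / (c / (c + d))
    defined = ((a + b) > 0) & (c > 0) & ((c + d) > 0)
    prr = np.where(defined, prr, np.nan)
    table = pd.DataFrame(
        {"month": full, "a": a, "b": b, "c": c, "d": d, "prr": prr, "defined": defined}
    )
    return PRRSeries(table=table, target_ae=target_ae)


def prr_count_series(prr: PRRSeries, stream: str = "regulatory"):
    """PRR values as an aligned float series for VAR input (undefined -> NaN)."""
    s = pd.Series(prr.table["prr"].to_numpy(), index=pd.PeriodIndex(prr.table["month"], freq="M"))
    return s


def plot_series(sm: CountSeries, reg: CountSeries, path) -> None:
    """Two-panel monthly time-series plot of both streams."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for ax, series, title in ((axes[0], reg, "Regulatory reports"), (axes[1], sm, "Social media postings")):
        ax.plot(series.values.index.to_timestamp(), series.to_numpy(), lw=1.2)
        ax.set_ylabel("reports / month")
        ax.set_title(f"{title} ({series.ae_filter})")
    axes[1].set_xlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
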