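"""Weekly quantization of irregular HbA1c series and instance construction.

Irregular measurements are organized into Monday-to-Sunday weeks and
quantized to one value per week: multiple measurements in a week are
averaged, weeks without a measurement stay missing (NaN in files, an
explicit boolean mask in memory).  No interpolation, normalization, or
outlier handling is applied; the model consumes missingness directly
through its attention mask.

A labeled instance is anchored at a *reference date* (a day the patient was
actually tested): the input is the N-year weekly grid ending at that date,
the label is whether any measurement in the following 365 days is at or
above the poor-control threshold (8.0% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "WeeklySeries",
    "LabeledInstance",
    "TemporalSplit",
    "n_week_slots",
    "quantize_weekly",
    "build_instances",
    "make_rolling_splits",
    "instances_to_frame",
    "frame_to_instances",
    "instances_to_xy",
]

DAYS_PER_YEAR = 365  # windows/horizons use 365-day years, matching ceil(N*365/7)
POOR_CONTROL_THRESHOLD = 8.0


def n_week_slots(history_years: int) -> int:
    """Grid width: ceil(N*365/7) weekly slots (53 for one year)."""
    if history_years < 1:
        raise ValueError("history_years must be >= 1")
    return -(-history_years * DAYS_PER_YEAR // 7)


def _monday(d: date) -> date:
    return d - timedelta(days=d.weekday())


@dataclass
class WeeklySeries:
    """A fixed-width Monday-to-Sunday weekly grid ending at a reference date.

    Slot ``W-1`` is the week containing the reference date; slot ``W-1-k``
    is k weeks earlier.  ``values`` carries NaN at unobserved slots; the
    model reads only slots with ``observed_mask`` set, so the sentinel value
    itself is never consumed.
    """

    reference_date: date
    history_years: int
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        w = n_week_slots(self.history_years)
        if len(self.values) != w or len(self.observed_mask) != w:
            raise ValueError(f"grid must have {w} slots for history_years={self.history_years}")

    @property
    def n_slots(self) -> int:
        return len(self.values)


@dataclass
class LabeledInstance:
    series: WeeklySeries
    label: bool
    patient_id: str = ""
    horizon_days: int = DAYS_PER_YEAR
    threshold: float = POOR_CONTROL_THRESHOLD


@dataclass
class TemporalSplit:
    """One rolling-origin fold: train on year-y-1 references, test on year y."""

    train_reference_year: int
    test_reference_year: int


def quantize_weekly(
    dates,
    values,
    window_end: date,
    history_years: int = 1,
    include_reference_week: bool = True,
) -> WeeklySeries:
    """Quantize one patient's measurements onto the weekly grid ending at ``window_end``.

    Measurements after ``window_end`` or before the grid's first week are
    ignored.  Rows with a missing date or a NaN value are rejected with the
    offending row index.
    """
    w = n_week_slots(history_years)
    vals = np.full(w, np.nan)
    counts = np.zeros(w)
    sums = np.zeros(w)
    ref_monday = _monday(window_end)
    for i, (d, v) in enumerate(zip(dates, values)):
        if d is None or pd.isna(d):
            raise ValueError(f"row {i}: measurement date is missing")
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"row {i}: HbA1c value is NaN")
        d = d.date() if isinstance(d, pd.Timestamp) else d
        if d > window_end:
            continue
        idx = w - 1 - (ref_monday - _monday(d)).days // 7
        if not 0 <= idx < w:
            continue
        sums[idx] += float(v)
        counts[idx] += 1
    observed = counts > 0
    vals[observed] = sums[observed] / counts[observed]
    if not include_reference_week:
        vals[w - 1] = np.nan
        observed = observed.copy()
        observed[w - 1] = False
    return WeeklySeries(window_end, history_years, vals, observed)


def build_instances(
    cohort: pd.DataFrame,
    reference_year: int,
    history_years: int = 1,
    horizon_days: int = DAYS_PER_YEAR,
    threshold: float = POOR_CONTROL_THRESHOLD,
    include_reference_week: bool = True,
    last_date: date | None = None,
) -> list[LabeledInstance]:
    """One labeled instance per HbA1c test date inside ``reference_year``.

    The label is positive iff any measurement in ``(ref, ref + horizon]``
    reaches ``threshold`` (the boundary value 8.0 counts as poor control).
    Instances whose outcome horizon extends past the last recorded date of
    the cohort, and degenerate instances with no observed input slot, are
    dropped.  A patient contributes one instance per in-year test date.
    """
    df = cohort.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if last_date is None:
        last_date = df["date"].max()
    years = pd.DatetimeIndex(pd.to_datetime(df["date"])).year
    if reference_year < years.min() or reference_year > years.max():
        warnings.warn(
            f"reference_year {reference_year} outside data range "
            f"[{years.min()}, {years.max()}]; no instances built",
            stacklevel=2,
        )
        return []

    instances: list[LabeledInstance] = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("date", kind="mergesort")
        dates = g["date"].to_list()
        vals = g["hba1c"].to_numpy(dtype=float)
        darr = np.array([d.toordinal() for d in dates])
        for ref in [d for d in dates if d.year == reference_year]:
            if ref + timedelta(days=horizon_days) > last_date:
                continue
            series = quantize_weekly(dates, vals, ref, history_years, include_reference_week)
            if not series.observed_mask.any():
                continue
            lo, hi = ref.toordinal(), ref.toordinal() + horizon_days
            future = vals[(darr > lo) & (darr <= hi)]
            label = bool(future.size and np.nanmax(future) >= threshold)
            instances.append(
                LabeledInstance(series, label, patient_id=str(pid), horizon_days=horizon_days, threshold=threshold)
            )
    return instances


def make_rolling_splits(first_test_year: int, last_test_year: int) -> list[TemporalSplit]:
    """Rolling-origin folds: for each test year y, train on references in y-1."""
    return [TemporalSplit(y - 1, y) for y in range(first_test_year, last_test_year + 1)]


# ---------------------------------------------------------------------------
# instance file round trip and array views


def instances_to_frame(instances: list[LabeledInstance]) -> pd.DataFrame:
    if not instances:
        raise ValueError("no instances to serialize")
    w = instances[0].series.n_slots
    rows = {}
    rows["patient_id"] = [ins.patient_id for ins in instances]
    rows["reference_date"] = [ins.series.reference_date.isoformat() for ins in instances]
    rows["history_years"] = [ins.series.history_years for ins in instances]
    rows["label"] = [int(ins.label) for ins in instances]
    vals = np.stack([ins.series.values for ins in instances])
    mask = np.stack([ins.series.observed_mask for ins in instances])
    for j in range(w):
        rows[f"values_{j}"] = vals[:, j]
    for j in range(w):
        rows[f"mask_{j}"] = mask[:, j].astype(int)
    return pd.DataFrame(rows)


def frame_to_instances(frame: pd.DataFrame) -> list[LabeledInstance]:
    w = sum(c.startswith("values_") for c in frame.columns)
    out = []
    vals = frame[[f"values_{j}" for j in range(w)]].to_numpy(dtype=float)
    mask = frame[[f"mask_{j}" for j in range(w)]].to_numpy(dtype=bool)
    for i, row in enumerate(frame.itertuples(index=False)):
        series = WeeklySeries(
            date.fromisoformat(row.reference_date), int(row.history_years), vals[i], mask[i]
        )
        out.append(LabeledInstance(series, bool(row.label), patient_id=str(row.patient_id)))
    return out


def instances_to_xy(instances: list[LabeledInstance]) -> tuple[np.ndarray, np.ndarray]:
    """Model-ready arrays: X (n, W) with NaN at missing slots, y (n,) in {0,1}."""
    if not instances:
        raise ValueError("no instances")
    X = np.stack([ins.series.values for ins in instances]).astype(float)
    mask = np.stack([ins.series.observed_mask for ins in instances])
    X[~mask] = np.nan
    y = np.array([int(ins.label) for ins in instances])
    return X, y
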