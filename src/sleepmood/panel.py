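"""Daily EMA panels: reading, aggregation, lag pairing and within-person scaling.

The unit of analysis is the subject-day.  Each morning a subject rates the
quality of the night that just ended (``sleep_quality``, 0-8 Likert) and up
to three times during the day rates mood, stress, energy and focus (0-8
Likert each).  The three within-day ratings are averaged into one daily
value per construct.  Two directional "lagged datasets" are derived from a
cohort of panels:

* ``sleep_to_mood`` — treatment is the sleep quality reported on the
  morning of day *t* (the night *t-1* to *t*), outcome is the mean mood of
  day *t*.
* ``mood_to_sleep`` — treatment is the mean mood of day *t*, outcome is the
  sleep quality reported on the morning of day *t+1* (the night that
  follows day *t*).

Confounders attached to each row are taken from the day preceding the
outcome day; optional history lags 1..T add the mood and sleep values of
the T days preceding the treatment day and require those calendar days to
be consecutive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LIKERT_MAX",
    "CSV_COLUMNS",
    "CONSTRUCTS",
    "SubjectPanel",
    "LaggedDataset",
    "SchemaError",
    "PanelValidationError",
    "read_panel_csv",
    "write_panel_csv",
    "panels_to_frame",
    "aggregate_daily",
    "build_lagged_dataset",
    "znormalize_within_subject",
    "znormalize_dataset",
    "filter_low_variance",
]

LIKERT_MAX = 8
CONSTRUCTS = ("mood", "stress", "energy", "focus")
DAY_TYPES = ("normal", "partial", "off")

#: long-format cohort CSV schema, one row per subject-day
CSV_COLUMNS = (
    ["subject_id", "group", "day_index", "day_of_week", "day_type", "sleep_quality"]
    + [f"{c}_{j}" for c in CONSTRUCTS for j in (1, 2, 3)]
    + ["activity_minutes", "mean_temp", "clear_sky_minutes", "phq9", "gad7"]
)

#: daily covariates used as matching confounders, lagged one day before the outcome
BASE_CONFOUNDERS = (
    "stress",
    "energy",
    "focus",
    "activity_minutes",
    "mean_temp",
    "clear_sky_minutes",
)


class SchemaError(ValueError):
    """The input table does not conform to the cohort CSV schema."""


class PanelValidationError(ValueError):
    """A value in the input table violates its declared range."""


@dataclass
class SubjectPanel:
    """One subject's ordered daily records plus screening information.

    ``records`` is indexed by ``day_index`` (strictly increasing integers;
    gaps encode missing days) and carries both the raw within-day ratings
    (``mood_1`` .. ``focus_3``) and their daily aggregates (``mood`` ..
    ``focus``).
    """

    subject_id: str
    group: str
    phq9: int
    gad7: int
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise PanelValidationError(f"subject {self.subject_id}: empty panel")
        days = self.records["day_index"].to_numpy()
        if not np.all(np.diff(days) > 0):
            raise PanelValidationError(
                f"subject {self.subject_id}: day_index must be strictly increasing"
            )

    @property
    def n_days(self) -> int:
        return len(self.records)

    def copy(self) -> "SubjectPanel":
        return SubjectPanel(
            self.subject_id, self.group, self.phq9, self.gad7,
            self.records.copy(), dict(self.meta),
        )


@dataclass
class LaggedDataset:
    """Per-subject rows pairing a treatment, an outcome and confounders.

    ``data`` columns: ``subject_id``, ``group``, ``outcome_day``,
    ``treatment``, ``outcome``, then the confounder columns listed in
    ``confounder_columns`` (empty when built with ``confounders=False``).
    """

    direction: str
    history_depth: int
    data: pd.DataFrame
    confounder_columns: list[str]

    def __post_init__(self) -> None:
        if self.direction not in ("sleep_to_mood", "mood_to_sleep"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.history_depth not in (0, 1, 2, 3):
            raise ValueError("history_depth must be in {0,1,2,3}")

    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"].unique())

    def rows_for(self, subject_id: str) -> pd.DataFrame:
        return self.data[self.data["subject_id"] == subject_id]


def aggregate_daily(ratings) -> float:
    """Daily value of a construct: mean of the available within-day ratings.

    Returns NaN when all three ratings are absent.
    """
    arr = np.asarray(ratings, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def _validate_likert(frame: pd.DataFrame, column: str) -> None:
    vals = frame[column]
    bad = vals.notna() & ((vals < 0) | (vals > LIKERT_MAX))
    if bad.any():
        row = int(frame.index[bad][0])
        raise PanelValidationError(
            f"column {column!r}, row {row}: value {vals[bad].iloc[0]!r} "
            f"outside [0, {LIKERT_MAX}]"
        )


def read_panel_csv(path) -> list[SubjectPanel]:
    """Read a long-format cohort CSV into typed subject panels.

    Empty fields become NaN ("absent").  Likert-scale columns are validated
    against the 0-8 range; violations raise :class:`PanelValidationError`
    with the offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    likert_cols = ["sleep_quality"] + [f"{c}_{j}" for c in CONSTRUCTS for j in (1, 2, 3)]
    for col in likert_cols:
        _validate_likert(df, col)
    bad_type = df["day_type"].notna() & ~df["day_type"].isin(DAY_TYPES)
    if bad_type.any():
        row = int(df.index[bad_type][0])
        raise PanelValidationError(
            f"column 'day_type', row {row}: value {df['day_type'][bad_type].iloc[0]!r} "
            f"not one of {DAY_TYPES}"
        )

    panels = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("day_index").reset_index(drop=True)
        rec = sub.drop(columns=["subject_id", "group", "phq9", "gad7"]).copy()
        for c in CONSTRUCTS:
            rec[c] = [
                aggregate_daily(row) for row in rec[[f"{c}_{j}" for j in (1, 2, 3)]].to_numpy()
            ]
        panels.append(
            SubjectPanel(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                phq9=int(sub["phq9"].iloc[0]),
                gad7=int(sub["gad7"].iloc[0]),
                records=rec,
            )
        )
    return panels


def panels_to_frame(panels: list[SubjectPanel]) -> pd.DataFrame:
    """Flatten panels back to the long-format CSV schema (one row per day)."""
    parts = []
    for p in panels:
        sub = p.records[[c for c in p.records.columns if c in CSV_COLUMNS]].copy()
        sub.insert(0, "subject_id", p.subject_id)
        sub.insert(1, "group", p.group)
        sub["phq9"] = p.phq9
        sub["gad7"] = p.gad7
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    return out[CSV_COLUMNS]


def write_panel_csv(panels: list[SubjectPanel], path) -> None:
    """Write panels as the long-format cohort CSV (empty fields for NaN)."""
    frame = panels_to_frame(panels)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.6g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# lag pairing


def build_lagged_dataset(
    panels: list[SubjectPanel],
    direction: str,
    T: int = 0,
    confounders: bool = True,
    confounder_timing: str = "before_outcome",
) -> LaggedDataset:
    """Pair each day's treatment with the directional outcome and confounders.

    Parameters
    ----------
    direction
        ``"sleep_to_mood"``: treatment = sleep quality reported on the
        morning of day *t*, outcome = mean mood of day *t*.
        ``"mood_to_sleep"``: treatment = mean mood of day *t*, outcome =
        sleep quality reported on the morning of day *t+1*.
    T
        History depth: mood and sleep quality of the 1..T days before the
        treatment day are added as confounders; those days must be
        consecutive calendar days or the row is dropped (no imputation).
    confounders
        When False, only the treatment/outcome pairing is built (the form
        used by the mixed-effects models); no confounder availability is
        required.
    confounder_timing
        ``"before_outcome"`` (default): daily covariates are taken from the
        day preceding the outcome day.  ``"before_treatment"``: from the
        day preceding the treatment day.

    Rows with any required component absent are excluded; an empty dataset
    is allowed.
    """
    if T not in (0, 1, 2, 3):
        raise ValueError("T must be in {0,1,2,3}")
    if direction not in ("sleep_to_mood", "mood_to_sleep"):
        raise ValueError(f"unknown direction {direction!r}")
    if confounder_timing not in ("before_outcome", "before_treatment"):
        raise ValueError(f"unknown confounder_timing {confounder_timing!r}")

    conf_cols: list[str] = []
    if confounders:
        conf_cols = [f"{c}_prev" for c in BASE_CONFOUNDERS] + ["day_of_week", "day_type"]
        for k in range(1, T + 1):
            conf_cols += [f"mood_lag{k}", f"sleep_quality_lag{k}"]

    out_rows = []
    for p in panels:
        rec = p.records.set_index("day_index")
        days = set(rec.index)
        for t in rec.index:
            if direction == "sleep_to_mood":
                treat_day, outcome_day = t, t
                treatment = rec.at[t, "sleep_quality"]
                outcome = rec.at[t, "mood"]
            else:
                treat_day, outcome_day = t, t + 1
                if t + 1 not in days:
                    continue
                treatment = rec.at[t, "mood"]
                outcome = rec.at[t + 1, "sleep_quality"]
            if pd.isna(treatment) or pd.isna(outcome):
                continue

            row = {
                "subject_id": p.subject_id,
                "group": p.group,
                "outcome_day": outcome_day,
                "treatment": float(treatment),
                "outcome": float(outcome),
            }
            if confounders:
                conf_day = (outcome_day if confounder_timing == "before_outcome"
                            else treat_day) - 1
                if conf_day not in days:
                    continue
                vals = rec.loc[conf_day, list(BASE_CONFOUNDERS)]
                if vals.isna().any():
                    continue
                for c in BASE_CONFOUNDERS:
                    row[f"{c}_prev"] = float(vals[c])
                # day context of the treatment day (precedes the outcome in
                # both directions)
                row["day_of_week"] = int(rec.at[treat_day, "day_of_week"])
                row["day_type"] = rec.at[treat_day, "day_type"]
                ok = True
                for k in range(1, T + 1):
                    lag_day = treat_day - k
                    if lag_day not in days:
                        ok = False
                        break
                    mv = rec.at[lag_day, "mood"]
                    sv = rec.at[lag_day, "sleep_quality"]
                    if pd.isna(mv) or pd.isna(sv):
                        ok = False
                        break
                    row[f"mood_lag{k}"] = float(mv)
                    row[f"sleep_quality_lag{k}"] = float(sv)
                if not ok:
                    continue
            out_rows.append(row)

    cols = ["subject_id", "group", "outcome_day", "treatment", "outcome"] + conf_cols
    data = pd.DataFrame(out_rows, columns=cols)
    return LaggedDataset(direction=direction, history_depth=T, data=data,
                         confounder_columns=conf_cols)


# ---------------------------------------------------------------------------
# within-person scaling and the variance exclusion rule


def znormalize_within_subject(
    panels: list[SubjectPanel],
    variables: tuple[str, ...] = ("sleep_quality", "mood"),
) -> tuple[list[SubjectPanel], dict[str, list[str]]]:
    """Replace each variable with its within-person z-score.

    For each subject and variable: ``(x - subject mean) / subject SD`` with
    the n-1 (sample) SD, computed over that subject's non-missing days.
    Subjects with zero SD (or fewer than two observations) for a variable
    are flagged in the returned mapping and that variable is set to NaN for
    them, excluding them from analyses of that variable without dropping
    the subject silently.
    """
    flagged: dict[str, list[str]] = {v: [] for v in variables}
    out = []
    for p in panels:
        q = p.copy()
        for v in variables:
            x = q.records[v].astype(float)
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0.0:
                flagged[v].append(p.subject_id)
                q.records[v] = np.nan
            else:
                q.records[v] = (x - x.mean()) / sd
        out.append(q)
    return out, flagged


def znormalize_dataset(
    dataset: LaggedDataset,
    panels: list[SubjectPanel],
    variables: tuple[str, ...] = ("treatment", "outcome"),
) -> LaggedDataset:
    """Z-score dataset columns using each subject's full-panel statistics.

    The scaling parameters come from the subject's complete daily series
    (as in panel-level normalization), so normalizing the panel and then
    building the dataset gives the same rows as building first and then
    normalizing here.
    """
    var_map = {"treatment": _treatment_variable(dataset.direction),
               "outcome": _outcome_variable(dataset.direction)}
    stats = {}
    for p in panels:
        row = {}
        for col in variables:
            x = p.records[var_map[col]].astype(float)
            row[col] = (x.mean(), x.std(ddof=1))
        stats[p.subject_id] = row
    data = dataset.data.copy()
    for col in variables:
        mu = data["subject_id"].map(lambda s: stats[s][col][0])
        sd = data["subject_id"].map(lambda s: stats[s][col][1])
        data[col] = np.where(sd > 0, (data[col] - mu) / sd, np.nan)
    data = data.dropna(subset=list(variables)).reset_index(drop=True)
    return LaggedDataset(dataset.direction, dataset.history_depth, data,
                         dataset.confounder_columns)


def _treatment_variable(direction: str) -> str:
    return "sleep_quality" if direction == "sleep_to_mood" else "mood"


def _outcome_variable(direction: str) -> str:
    return "mood" if direction == "sleep_to_mood" else "sleep_quality"


def filter_low_variance(
    panels: list[SubjectPanel],
    variable: str,
    threshold: float = 0.5,
    ddof: int = 1,
) -> tuple[list[SubjectPanel], list[str]]:
    """Exclude subjects whose raw daily treatment variance is below threshold.

    Subjects with near-constant treatment do not admit a reliable
    above/below-mean discretization, so they are removed from the matching
    analyses.  The rule is a strict ``<`` comparison on the raw
    (pre-normalization, pre-binarization) series; sample (n-1) variance by
    default.
    """
    kept, excluded = [], []
    for p in panels:
        x = p.records[variable].astype(float).dropna()
        var = x.var(ddof=ddof) if len(x) > ddof else 0.0
        if len(x) >= 2 and var >= threshold:
            kept.append(p)
        else:
            excluded.append(p.subject_id)
    return kept, excluded
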