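"""Tabular input/output and monthly aggregation of admission line-lists.

The package works on three kinds of tables:

* a *line-list* with one row per emergency-department admission for a
  suicide attempt (SA), carrying the attempt date and a handful of
  clinical covariates;
* per-country *monthly series* of SA episode counts;
* per-country monthly *indicator panels* derived from the OxCGRT
  (Oxford COVID-19 Government Response Tracker) daily policy CSV.

Admissions are reduced to *episodes*: attempts occurring within the
7 days preceding an admission collapse to a single episode dated at the
first attempt, and attempts more than 7 days before their admission are
excluded.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
METHODS = ("self_poisoning", "other")
YESNO = ("yes", "no")

#: canonical line-list column order used by :func:`write_linelist`
LINELIST_COLUMNS = (
    "country",
    "patient_id",
    "admission_date",
    "sa_date",
    "age",
    "sex",
    "method",
    "family_history",
    "previous_er_visit",
)

#: default raw-value maps applied by :func:`read_linelist`
DEFAULT_VALUE_MAPS: dict[str, dict[str, str]] = {
    "sex": {"f": "female", "female": "female", "m": "male", "male": "male"},
    "method": {
        "self_poisoning": "self_poisoning",
        "self-poisoning": "self_poisoning",
        "poisoning": "self_poisoning",
        "other": "other",
    },
    "family_history": {"yes": "yes", "y": "yes", "no": "no", "n": "no"},
    "previous_er_visit": {"yes": "yes", "y": "yes", "no": "no", "n": "no"},
}

#: maximum ordinal level per OxCGRT policy indicator (codebook ranges)
ORDINAL_CODEBOOK: dict[str, int] = {
    "school_closing": 3,
    "workplace_closing": 3,
    "cancel_public_events": 2,
    "restrictions_on_gatherings": 4,
    "close_public_transport": 2,
    "stay_at_home_requirements": 3,
    "restrictions_on_internal_movement": 2,
    "international_travel_controls": 4,
    "public_information_campaigns": 2,
    "testing_policy": 3,
    "contact_tracing": 2,
    "facial_coverings": 4,
    "vaccination_policy": 5,
}

#: raw OxCGRT wide-CSV headers -> canonical names
OXCGRT_NAME_MAP: dict[str, str] = {
    "C1_School closing": "school_closing",
    "C2_Workplace closing": "workplace_closing",
    "C3_Cancel public events": "cancel_public_events",
    "C4_Restrictions on gatherings": "restrictions_on_gatherings",
    "C5_Close public transport": "close_public_transport",
    "C6_Stay at home requirements": "stay_at_home_requirements",
    "C7_Restrictions on internal movement": "restrictions_on_internal_movement",
    "C8_International travel controls": "international_travel_controls",
    "H1_Public information campaigns": "public_information_campaigns",
    "H2_Testing policy": "testing_policy",
    "H3_Contact tracing": "contact_tracing",
    "H6_Facial Coverings": "facial_coverings",
    "H7_Vaccination policy": "vaccination_policy",
    "ConfirmedCases": "confirmed_cases",
    "ConfirmedDeaths": "confirmed_deaths",
}


@dataclass(frozen=True)
class PatientRecord:
    """One SA admission row.

    ``sa_date`` is the date of the attempt itself; when absent it is
    taken to be the admission date.  ``age`` is in whole years and, for
    this pediatric setting, must lie in [0, 17] when present.
    """

    country: str
    admission_date: _dt.date
    sa_date: _dt.date | None = None
    age: int | None = None
    sex: str | None = None
    method: str | None = None
    family_history: str | None = None
    previous_er_visit: str | None = None
    patient_id: str | None = None

    @property
    def episode_date(self) -> _dt.date:
        return self.sa_date if self.sa_date is not None else self.admission_date


@dataclass
class MonthlySeries:
    """Consecutive monthly SA episode counts for one country."""

    country: str
    start: pd.Period
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Period(self.start, freq="M")
        c = np.asarray(self.counts)
        if c.ndim != 1 or len(c) < 1:
            raise ValueError("counts must be a non-empty 1-d array")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(int)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self.counts), freq="M")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": self.country,
                "month": self.months.astype(str),
                "count": self.counts,
            }
        )


@dataclass
class IndicatorPanel:
    """Monthly covariate panel for one country.

    ``data`` is indexed by a monthly :class:`pandas.PeriodIndex`;
    ``kinds`` tags each column ``"ordinal"`` (integer policy levels) or
    ``"continuous"`` (e.g. log-scaled death counts); ``meta`` records the
    daily-to-monthly reduction rule used per column.
    """

    country: str
    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.PeriodIndex):
            self.data = self.data.copy()
            self.data.index = pd.PeriodIndex(self.data.index, freq="M")
        for col in self.data.columns:
            self.kinds.setdefault(col, "continuous")
            kind = self.kinds[col]
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in indicator {col!r}")
            if kind == "continuous" and np.any(vals < 0):
                raise ValueError(f"continuous indicator {col!r} has negative values")
            if kind == "ordinal":
                if not np.all(np.equal(np.mod(vals, 1), 0)):
                    raise ValueError(f"ordinal indicator {col!r} has non-integer values")
                maxlev = ORDINAL_CODEBOOK.get(col)
                if maxlev is not None and np.any(vals > maxlev):
                    raise ValueError(
                        f"ordinal indicator {col!r} exceeds codebook maximum {maxlev}"
                    )

    @property
    def months(self) -> pd.PeriodIndex:
        return self.data.index

    @property
    def start(self) -> pd.Period:
        return self.data.index[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


class LinelistError(ValueError):
    """Fatal problem with a line-list file (missing column, empty file)."""


def _parse_date(raw: str) -> _dt.date:
    """Parse ISO-8601 (YYYY-MM-DD) or compact YYYYMMDD; anything else fails."""
    s = str(raw).strip()
    if len(s) == 8 and s.isdigit():
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    return _dt.date.fromisoformat(s)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return df


def read_linelist(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    value_maps: Mapping[str, Mapping[str, str]] | None = None,
    strict: bool = False,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Read an admission line-list from delimited text.

    Parameters
    ----------
    path:
        CSV (or TSV, by extension) file with a header row.
    schema:
        Mapping from logical field names (see :data:`LINELIST_COLUMNS`)
        to the file's column names.  Fields absent from the mapping are
        looked up under their canonical name; missing optional columns
        are treated as all-missing.
    value_maps:
        Per-field raw-to-canonical maps for the categorical columns,
        merged over :data:`DEFAULT_VALUE_MAPS`.
    strict:
        If True, rows violating an invariant (age outside [0, 17],
        attempt date after admission) are rejected; if False the
        offending value becomes missing.

    Returns
    -------
    (records, rejected):
        Parsed records, and a row-indexed report of rejected rows with
        a ``reason`` column.  Rows with unparseable dates are always
        rejected.
    """
    df = _read_delimited(path)
    if df.empty:
        raise LinelistError(f"empty line-list file: {path}")
    schema = dict(schema or {})
    maps = {k: dict(v) for k, v in DEFAULT_VALUE_MAPS.items()}
    for fld, m in (value_maps or {}).items():
        maps.setdefault(fld, {}).update({str(k).lower(): v for k, v in m.items()})

    def colname(field_name: str) -> str | None:
        name = schema.get(field_name, field_name)
        return name if name in df.columns else None

    for mandatory in ("country", "admission_date"):
        if colname(mandatory) is None:
            raise LinelistError(f"missing mandatory column: {mandatory!r}")

    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            admission = _parse_date(row[colname("admission_date")])
        except (ValueError, TypeError):
            rejected.append((i, "unparseable admission_date"))
            continue
        sa_date: _dt.date | None = None
        c = colname("sa_date")
        if c is not None and str(row[c]).strip() != "":
            try:
                sa_date = _parse_date(row[c])
            except (ValueError, TypeError):
                rejected.append((i, "unparseable sa_date"))
                continue
        if sa_date is not None and sa_date > admission:
            if strict:
                rejected.append((i, "sa_date after admission_date"))
                continue
            sa_date = None

        age: int | None = None
        c = colname("age")
        if c is not None and str(row[c]).strip() != "":
            try:
                age = int(float(row[c]))
            except ValueError:
                age = None
            if age is not None and not (0 <= age <= 17):
                if strict:
                    rejected.append((i, "age out of range"))
                    continue
                age = None

        def categorical(field_name: str) -> str | None:
            c = colname(field_name)
            if c is None:
                return None
            raw = str(row[c]).strip()
            if raw == "":
                return None
            return maps.get(field_name, {}).get(raw.lower())

        c = colname("patient_id")
        pid = str(row[c]).strip() if c is not None and str(row[c]).strip() else None
        records.append(
            PatientRecord(
                country=str(row[colname("country")]).strip(),
                admission_date=admission,
                sa_date=sa_date,
                age=age,
                sex=categorical("sex"),
                method=categorical("method"),
                family_history=categorical("family_history"),
                previous_er_visit=categorical("previous_er_visit"),
                patient_id=pid,
            )
        )
    report = pd.DataFrame(rejected, columns=["row", "reason"])
    if len(report):
        logger.warning("rejected %d line-list rows", len(report))
    return records, report


def write_linelist(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as canonical CSV (fixed column order, ISO dates)."""
    rows = []
    for r in records:
        rows.append(
            {
                "country": r.country,
                "patient_id": r.patient_id or "",
                "admission_date": r.admission_date.isoformat(),
                "sa_date": r.sa_date.isoformat() if r.sa_date is not None else "",
                "age": "" if r.age is None else str(r.age),
                "sex": r.sex or "",
                "method": r.method or "",
                "family_history": r.family_history or "",
                "previous_er_visit": r.previous_er_visit or "",
            }
        )
    df = pd.DataFrame(rows, columns=list(LINELIST_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def deduplicate_episodes(
    records: Sequence[PatientRecord], max_gap_days: int = 7
) -> tuple[list[PatientRecord], int]:
    """Reduce admission rows to SA episodes.

    Per patient and admission, multiple attempts within ``max_gap_days``
    days before the admission collapse to one episode carrying the
    characteristics of the *first* attempt; attempts more than
    ``max_gap_days`` days before their admission are dropped.  Records
    without a patient identifier are each their own episode (logged).

    Returns the episode list and the number of dropped records.
    """
    kept: list[PatientRecord] = []
    dropped = 0
    n_anonymous = 0
    groups: dict[tuple[str, _dt.date], list[PatientRecord]] = {}
    for r in records:
        sa = r.episode_date
        if (r.admission_date - sa).days > max_gap_days:
            dropped += 1
            continue
        if r.patient_id is None:
            n_anonymous += 1
            kept.append(r if r.sa_date is not None else replace(r, sa_date=sa))
        else:
            groups.setdefault((r.patient_id, r.admission_date), []).append(r)
    for (_, _), rows in groups.items():
        first = min(rows, key=lambda r: r.episode_date)
        if first.sa_date is None:
            first = replace(first, sa_date=first.episode_date)
        kept.append(first)
    if n_anonymous:
        logger.info(
            "%d records lack patient_id; each treated as an independent episode",
            n_anonymous,
        )
    kept.sort(key=lambda r: (r.episode_date, r.admission_date, r.patient_id or ""))
    return kept, dropped


def aggregate_monthly(
    records: Sequence[PatientRecord],
    country: str,
    window: tuple[str | pd.Period, str | pd.Period],
    max_gap_days: int = 7,
) -> MonthlySeries:
    """Aggregate a line-list into a deduplicated monthly episode series.

    Episodes are binned by the calendar month of the attempt (first-SA)
    date; months with no episodes yield zero.  A window outside the data
    range produces a zero-filled series with a warning.
    """
    start = pd.Period(window[0], freq="M")
    end = pd.Period(window[1], freq="M")
    if end < start:
        raise ValueError("window end before start")
    episodes, _ = deduplicate_episodes(
        [r for r in records if r.country == country], max_gap_days=max_gap_days
    )
    months = pd.period_range(start, end, freq="M")
    counts = np.zeros(len(months), dtype=int)
    in_window = 0
    for r in episodes:
        p = pd.Period(r.episode_date, freq="M")
        if start <= p <= end:
            counts[(p - start).n] += 1
            in_window += 1
    if episodes and in_window == 0:
        logger.warning(
            "window %s..%s contains none of the %d episodes for %s",
            start,
            end,
            len(episodes),
            country,
        )
    return MonthlySeries(country=country, start=start, counts=counts)


def _reduce_ordinal(daily: pd.Series, rule: str) -> int:
    vals = daily.dropna().astype(int)
    if rule == "majority":
        counts = vals.value_counts()
        top = counts[counts == counts.max()]
        return int(max(top.index))  # ties broken toward the higher level
    if rule == "max":
        return int(vals.max())
    if rule == "eom":
        return int(vals.iloc[-1])
    raise ValueError(f"unknown ordinal reduction rule: {rule!r}")


def read_oxcgrt(
    path: str | Path,
    country: str,
    window: tuple[str | pd.Period, str | pd.Period],
    reduction: Mapping[str, str] | None = None,
    country_col: str = "CountryName",
    date_col: str = "Date",
    log_base: str = "log10",
    fill_forward: bool = False,
) -> IndicatorPanel:
    """Read the OxCGRT daily wide CSV into a monthly indicator panel.

    Ordinal policy columns are reduced daily-to-monthly by the rule in
    ``reduction`` (default ``"majority"``: most frequent daily level,
    ties broken toward the higher, i.e. more restrictive, level;
    alternatives ``"max"`` and ``"eom"``).  Cumulative confirmed cases
    and deaths are converted to monthly new counts and transformed
    ``log10(x + 1)``.
    """
    df = pd.read_csv(path, dtype={date_col: str})
    df = df[df[country_col] == country]
    if df.empty:
        raise ValueError(f"country {country!r} not present in {path}")
    df = df.rename(columns=OXCGRT_NAME_MAP)
    dates = df[date_col].map(_parse_date)
    df = df.assign(_month=pd.PeriodIndex([pd.Period(d, freq="M") for d in dates]))
    df = df.assign(_day=list(dates)).sort_values("_day")

    start = pd.Period(window[0], freq="M")
    end = pd.Period(window[1], freq="M")
    months = pd.period_range(start, end, freq="M")
    reduction = dict(reduction or {})

    ordinal_cols = [c for c in df.columns if c in ORDINAL_CODEBOOK]
    out: dict[str, list[float]] = {c: [] for c in ordinal_cols}
    kinds = {c: "ordinal" for c in ordinal_cols}
    meta: dict[str, str] = {}
    grouped = dict(tuple(df.groupby("_month")))

    last_seen: dict[str, float] = {}
    for m in months:
        sub = grouped.get(m)
        if sub is None or sub.empty:
            if not fill_forward:
                raise ValueError(f"no daily rows for month {m}; enable fill_forward")
            for c in ordinal_cols:
                out[c].append(last_seen.get(c, 0.0))
            continue
        for c in ordinal_cols:
            rule = reduction.get(c, "majority")
            val = _reduce_ordinal(sub[c], rule)
            out[c].append(val)
            last_seen[c] = val
            meta[c] = rule

    data = pd.DataFrame(out, index=months)

    for cum_col, new_name in (
        ("confirmed_cases", "log_cases"),
        ("confirmed_deaths", "log_deaths"),
    ):
        if cum_col not in df.columns:
            continue
        eom = []
        prev = 0.0
        for m in months:
            sub = grouped.get(m)
            if sub is None or sub.empty:
                eom.append(prev)
                continue
            v = pd.to_numeric(sub[cum_col], errors="coerce").dropna()
            eom.append(float(v.iloc[-1]) if len(v) else prev)
            prev = eom[-1]
        eom_arr = np.asarray(eom, dtype=float)
        new = np.diff(np.concatenate([[0.0], eom_arr]))
        new = np.clip(new, 0.0, None)  # cumulative corrections can go backwards
        if log_base == "log10":
            data[new_name] = np.log10(new + 1.0)
        elif log_base == "ln":
            data[new_name] = np.log1p(new)
        else:
            raise ValueError(f"unknown log_base {log_base!r}")
        kinds[new_name] = "continuous"
        meta[new_name] = f"monthly new counts, {log_base}(x+1)"

    return IndicatorPanel(country=country, data=data, kinds=kinds, meta=meta)


def series_to_csv(series_list: Sequence[MonthlySeries], path: str | Path) -> None:
    """Write monthly series as tidy CSV (country, month, count)."""
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False, lineterminator="\n"
    )


def series_from_csv(path: str | Path) -> list[MonthlySeries]:
    df = pd.read_csv(path)
    out = []
    for country, sub in df.groupby("country", sort=True):
        sub = sub.copy()
        sub["month"] = pd.PeriodIndex(sub["month"], freq="M")
        sub = sub.sort_values("month")
        months = sub["month"].to_numpy()
        if len(months) > 1 and not all(
            (months[i + 1] - months[i]).n == 1 for i in range(len(months) - 1)
        ):
            raise ValueError(f"months for {country!r} are not consecutive")
        out.append(
            MonthlySeries(
                country=str(country),
                start=months[0],
                counts=sub["count"].to_numpy(),
            )
        )
    return out


def panel_to_csv(panels: Sequence[IndicatorPanel], path: str | Path) -> None:
    """Write indicator panels as tidy CSV (country, month, one column per indicator)."""
    frames = []
    for p in panels:
        f = p.data.copy()
        f.insert(0, "month", p.months.astype(str))
        f.insert(0, "country", p.country)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, lineterminator="\n")


def panel_from_csv(
    path: str | Path, kinds: Mapping[str, str] | None = None
) -> list[IndicatorPanel]:
    df = pd.read_csv(path)
    out = []
    for country, sub in df.groupby("country", sort=True):
        sub = sub.copy().sort_values("month")
        idx = pd.PeriodIndex(sub["month"], freq="M")
        data = sub.drop(columns=["country", "month"]).set_index(idx)
        k = dict(kinds or {})
        for col in data.columns:
            if col not in k:
                k[col] = "ordinal" if col in ORDINAL_CODEBOOK else "continuous"
        out.append(IndicatorPanel(country=str(country), data=data, kinds=k))
    return out
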