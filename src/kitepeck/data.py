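"""Event-log data model: loading, validation and brood-day covariates.

The analysis consumes four plain-CSV tables describing video-recorded broods:

``broods.csv``
    one row per nestling: ``brood_id, nestling_id, hatch_date, hatch_rank``
    with ``hatch_rank`` in {S, M, J} (senior / middle / junior by hatch order).
``pecks.csv``
    one row per directed aggressive strike:
    ``brood_id, date, time, attacker_id, recipient_id``.
``bouts.csv``
    one row per parental feeding bout to a single nestling:
    ``brood_id, date, time, recipient_id``.
``deliveries.csv``
    one row per prey item brought to the nest:
    ``brood_id, date, category, fraction, observer_mass_g`` (mass may be blank).

Dates are ISO-8601 (``YYYY-MM-DD``), times ``HH:MM:SS`` at 1-second
resolution.  Ages are integer days with the hatch day counted as day 0.

Brood-days fall into two analysis phases keyed to the age of the junior
nestling: phase 1 while it is 1--10 days old (the period of highest nestling
vulnerability), phase 2 while 11--20 days old; all other days are excluded.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ReferentialError, SchemaError

RANKS = ("S", "M", "J")

VALID_CATEGORIES = (
    "amphibian",
    "anthropogenic",
    "bird",
    "invertebrate",
    "mammal",
    "unclassified",
)

VALID_FRACTIONS = (1.0, 0.5, 0.25)

#: Default manually-analysed observation window, half-open [08:00, 14:00).
WINDOW_START = _dt.time(8, 0, 0)
WINDOW_END = _dt.time(14, 0, 0)

_SCHEMAS = {
    "pecks": ["brood_id", "date", "time", "attacker_id", "recipient_id"],
    "bouts": ["brood_id", "date", "time", "recipient_id"],
    "deliveries": ["brood_id", "date", "category", "fraction", "observer_mass_g"],
    "broods": ["brood_id", "nestling_id", "hatch_date", "hatch_rank"],
}


@dataclass
class ValidationReport:
    """Rows dropped or flagged while assembling a dataset.

    A clean dataset produces an empty report; hard schema/referential
    violations raise instead of being recorded here.
    """

    dropped: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.dropped and not self.flagged

    def to_dict(self) -> dict:
        return {"dropped": list(self.dropped), "flagged": list(self.flagged)}


@dataclass
class Dataset:
    """A validated set of event-log tables for one study.

    Attributes
    ----------
    pecks, bouts, deliveries, broods
        The four tables with parsed date/time columns.  ``pecks`` and
        ``bouts`` additionally carry ``attacker_rank`` / ``recipient_rank``
        columns resolved from the brood table.
    report
        Validation report listing dropped/flagged rows.
    """

    pecks: pd.DataFrame
    bouts: pd.DataFrame
    deliveries: pd.DataFrame
    broods: pd.DataFrame
    report: ValidationReport = field(default_factory=ValidationReport)

    def nestling_ranks(self) -> pd.Series:
        """Map nestling_id -> hatch_rank."""
        return self.broods.set_index("nestling_id")["hatch_rank"]

    def hatch_dates(self) -> pd.Series:
        """Map nestling_id -> hatch_date."""
        return self.broods.set_index("nestling_id")["hatch_date"]

    def junior_hatch_dates(self) -> pd.Series:
        """Map brood_id -> hatch date of the junior nestling."""
        juniors = self.broods[self.broods["hatch_rank"] == "J"]
        return juniors.set_index("brood_id")["hatch_date"]

    def rank_hatch_dates(self) -> pd.DataFrame:
        """Wide table brood_id x rank -> hatch_date."""
        return self.broods.pivot(
            index="brood_id", columns="hatch_rank", values="hatch_date"
        )


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in _SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column '{col}'")


def _parse_dates(series: pd.Series, table: str, col: str) -> pd.Series:
    values = series.dropna()
    if len(values) and all(
        isinstance(v, _dt.date) and not isinstance(v, _dt.datetime) for v in values
    ):
        return series
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{table}: unparseable {col} {series.iloc[row]!r} at row {row}"
        )
    return parsed.dt.date

def _parse_times(series: pd.Series, table: str) -> pd.Series:
    values = series.dropna()
    if len(values) and all(isinstance(v, _dt.time) for v in values):
        return series
    parsed = pd.to_datetime(series, format="%H:%M:%S", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{table}: unparseable time {series.iloc[row]!r} at row {row}"
        )
    return parsed.dt.time


def _check_membership(
    df: pd.DataFrame, cols: list[str], broods: pd.DataFrame, table: str
) -> None:
    members = broods.groupby("brood_id")["nestling_id"].agg(set).to_dict()
    for col in cols:
        for row, (brood, nid) in enumerate(zip(df["brood_id"], df[col])):
            if nid not in members.get(brood, set()):
                raise ReferentialError(
                    f"{table}: row {row}: {col} {nid!r} not a member of "
                    f"brood {brood!r}"
                )


def load_dataset(
    pecks_path: str | Path,
    bouts_path: str | Path,
    deliveries_path: str | Path,
    broods_path: str | Path,
    *,
    triads_only: bool = True,
    relabel_tied_seniors: bool = False,
    seed: int | None = None,
) -> Dataset:
    """Read and validate the four event-log CSVs.

    Parameters
    ----------
    triads_only
        Drop broods whose size differs from three (the permutation null is
        defined for a two-recipient pool); dropped broods are recorded in the
        validation report.
    relabel_tied_seniors
        When the two oldest nestlings share a hatch date, randomly swap the
        S/M labels (seeded) — mirrors field practice when the oldest pair is
        visually indistinguishable.
    seed
        Seed for the optional relabelling.

    Raises
    ------
    SchemaError, ParseError, ReferentialError
        On malformed input, naming the offending column/row.
    """
    frames = {}
    paths = {
        "pecks": pecks_path,
        "bouts": bouts_path,
        "deliveries": deliveries_path,
        "broods": broods_path,
    }
    for table, path in paths.items():
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        _require_columns(df, table)
        frames[table] = df

    return build_dataset(
        frames["pecks"],
        frames["bouts"],
        frames["deliveries"],
        frames["broods"],
        triads_only=triads_only,
        relabel_tied_seniors=relabel_tied_seniors,
        seed=seed,
    )


def build_dataset(
    pecks: pd.DataFrame,
    bouts: pd.DataFrame,
    deliveries: pd.DataFrame,
    broods: pd.DataFrame,
    *,
    triads_only: bool = True,
    relabel_tied_seniors: bool = False,
    seed: int | None = None,
) -> Dataset:
    """Validate in-memory tables into a :class:`Dataset` (see load_dataset)."""
    report = ValidationReport()

    broods = broods.copy()
    for table, df in [("pecks", pecks), ("bouts", bouts),
                      ("deliveries", deliveries), ("broods", broods)]:
        _require_columns(df, table)

    broods["hatch_date"] = _parse_dates(broods["hatch_date"], "broods", "hatch_date")
    bad_rank = ~broods["hatch_rank"].isin(RANKS)
    if bad_rank.any():
        row = int(np.flatnonzero(bad_rank.to_numpy())[0])
        raise SchemaError(
            f"broods: row {row}: hatch_rank must be one of {RANKS}, "
            f"got {broods['hatch_rank'].iloc[row]!r}"
        )
    if broods["nestling_id"].duplicated().any():
        dup = broods.loc[broods["nestling_id"].duplicated(), "nestling_id"].iloc[0]
        raise ReferentialError(f"broods: duplicate nestling_id {dup!r}")
    for brood_id, grp in broods.groupby("brood_id"):
        if grp["hatch_rank"].duplicated().any():
            raise ReferentialError(
                f"broods: brood {brood_id!r} has duplicated hatch_rank"
            )
        by_rank = grp.set_index("hatch_rank")["hatch_date"]
        order = [r for r in RANKS if r in by_rank.index]
        dates = [by_rank[r] for r in order]
        if any(a > b for a, b in zip(dates, dates[1:])):
            raise SchemaError(
                f"broods: brood {brood_id!r}: hatch dates not non-decreasing "
                f"in rank order S<=M<=J"
            )

    if triads_only:
        sizes = broods.groupby("brood_id").size()
        bad = sizes[sizes != 3].index.tolist()
        if bad:
            report.dropped.append(
                f"broods of size != 3 dropped before permutation analysis: {bad}"
            )
            broods = broods[~broods["brood_id"].isin(bad)].reset_index(drop=True)
            pecks = pecks[~pecks["brood_id"].isin(bad)].reset_index(drop=True)
            bouts = bouts[~bouts["brood_id"].isin(bad)].reset_index(drop=True)
            deliveries = deliveries[
                ~deliveries["brood_id"].isin(bad)
            ].reset_index(drop=True)

    if relabel_tied_seniors:
        rng = np.random.default_rng(seed)
        wide = broods.pivot(index="brood_id", columns="hatch_rank",
                            values="hatch_date")
        tied = wide.index[(wide.get("S") == wide.get("M"))]
        for brood_id in tied:
            if rng.random() < 0.5:
                sel = broods["brood_id"] == brood_id
                swap = {"S": "M", "M": "S"}
                broods.loc[sel, "hatch_rank"] = broods.loc[sel, "hatch_rank"].map(
                    lambda r: swap.get(r, r)
                )
                report.flagged.append(
                    f"brood {brood_id!r}: tied S/M hatch dates randomly relabelled"
                )

    pecks = pecks.copy()
    pecks["date"] = _parse_dates(pecks["date"], "pecks", "date")
    pecks["time"] = _parse_times(pecks["time"], "pecks")
    self_peck = pecks["attacker_id"] == pecks["recipient_id"]
    if self_peck.any():
        row = int(np.flatnonzero(self_peck.to_numpy())[0])
        raise ReferentialError(
            f"pecks: row {row}: attacker equals recipient "
            f"({pecks['attacker_id'].iloc[row]!r})"
        )
    _check_membership(pecks, ["attacker_id", "recipient_id"], broods, "pecks")

    bouts = bouts.copy()
    bouts["date"] = _parse_dates(bouts["date"], "bouts", "date")
    bouts["time"] = _parse_times(bouts["time"], "bouts")
    _check_membership(bouts, ["recipient_id"], broods, "bouts")

    deliveries = deliveries.copy().replace({"": None})
    deliveries["date"] = _parse_dates(deliveries["date"], "deliveries", "date")
    bad_cat = ~deliveries["category"].isin(VALID_CATEGORIES)
    if bad_cat.any():
        row = int(np.flatnonzero(bad_cat.to_numpy())[0])
        raise SchemaError(
            f"deliveries: row {row}: unknown category "
            f"{deliveries['category'].iloc[row]!r}"
        )
    raw_frac = deliveries["fraction"]
    frac = pd.to_numeric(raw_frac, errors="coerce")
    unparsed = frac.isna() & raw_frac.notna()
    if unparsed.any():
        row = int(np.flatnonzero(unparsed.to_numpy())[0])
        raise SchemaError(
            f"deliveries: row {row}: fraction must be in {{1, 0.5, 0.25}}, "
            f"got {raw_frac.iloc[row]!r}"
        )
    # unrecorded fraction defaults to a whole item (conservative)
    missing_frac = frac.isna()
    if missing_frac.any():
        report.flagged.append(
            f"deliveries: {int(missing_frac.sum())} rows with missing fraction "
            f"defaulted to 1"
        )
    deliveries["fraction"] = frac.fillna(1.0)
    bad_frac = ~deliveries["fraction"].isin(VALID_FRACTIONS)
    if bad_frac.any():
        row = int(np.flatnonzero(bad_frac.to_numpy())[0])
        raise SchemaError(
            f"deliveries: row {row}: fraction must be in {{1, 0.5, 0.25}}, "
            f"got {deliveries['fraction'].iloc[row]!r}"
        )
    raw_mass = deliveries["observer_mass_g"]
    mass = pd.to_numeric(raw_mass, errors="coerce")
    unparsed = mass.isna() & raw_mass.notna()
    if unparsed.any():
        row = int(np.flatnonzero(unparsed.to_numpy())[0])
        raise SchemaError(
            f"deliveries: row {row}: unparseable observer_mass_g "
            f"{raw_mass.iloc[row]!r}"
        )
    if (mass <= 0).any():
        row = int(np.flatnonzero((mass <= 0).to_numpy())[0])
        raise SchemaError(
            f"deliveries: row {row}: observer_mass_g must be > 0 when present"
        )
    deliveries["observer_mass_g"] = mass

    ranks = broods.set_index("nestling_id")["hatch_rank"]
    pecks["attacker_rank"] = pecks["attacker_id"].map(ranks)
    pecks["recipient_rank"] = pecks["recipient_id"].map(ranks)
    bouts["recipient_rank"] = bouts["recipient_id"].map(ranks)

    return Dataset(pecks=pecks, bouts=bouts, deliveries=deliveries,
                   broods=broods, report=report)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a dataset back to the four-CSV layout (round-trip safe)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    pecks = dataset.pecks[
        ["brood_id", "date", "time", "attacker_id", "recipient_id"]
    ].copy()
    bouts = dataset.bouts[["brood_id", "date", "time", "recipient_id"]].copy()
    deliveries = dataset.deliveries[
        ["brood_id", "date", "category", "fraction", "observer_mass_g"]
    ].copy()
    broods = dataset.broods[
        ["brood_id", "nestling_id", "hatch_date", "hatch_rank"]
    ].copy()

    for name, df in [("pecks", pecks), ("bouts", bouts),
                     ("deliveries", deliveries), ("broods", broods)]:
        df = df.copy()
        for col in df.columns:
            if col in ("date", "hatch_date"):
                df[col] = df[col].map(lambda d: d.isoformat())
            elif col == "time":
                df[col] = df[col].map(lambda t: t.strftime("%H:%M:%S"))
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def filter_observation_window(
    events: pd.DataFrame,
    start_time: _dt.time = WINDOW_START,
    end_time: _dt.time = WINDOW_END,
) -> pd.DataFrame:
    """Keep events whose time-of-day lies in the half-open window [start, end).

    The half-open convention prevents double counting at the boundary.
    Idempotent; an empty result is allowed.
    """
    if not start_time < end_time:
        raise ValueError("start_time must precede end_time")
    if events.empty:
        return events.copy()
    tod = events["time"]
    keep = (tod >= start_time) & (tod < end_time)
    return events[keep.to_numpy()].reset_index(drop=True)


def assign_phase(age_junior: int) -> str:
    """Phase of a brood-day from the junior nestling's age in days.

    Returns ``"1"`` for junior age 1--10, ``"2"`` for 11--20 and
    ``"excluded"`` otherwise (including dates before the junior hatched).
    """
    if 1 <= age_junior <= 10:
        return "1"
    if 11 <= age_junior <= 20:
        return "2"
    return "excluded"


def age_difference(
    broods: pd.DataFrame, attacker_id: str, recipient_id: str
) -> int:
    """Signed age difference hatch(attacker) − hatch(recipient), in days.

    Negative when the attacker is older (hatched earlier) than the recipient,
    positive when younger; antisymmetric in its arguments.
    """
    idx = broods.set_index("nestling_id")
    try:
        a, r = idx.loc[attacker_id], idx.loc[recipient_id]
    except KeyError as exc:
        raise ReferentialError(f"unknown nestling id {exc.args[0]!r}") from exc
    if a["brood_id"] != r["brood_id"]:
        raise ReferentialError(
            f"{attacker_id!r} and {recipient_id!r} belong to different broods"
        )
    return (a["hatch_date"] - r["hatch_date"]).days


def brood_day_covariates(
    dataset: Dataset,
    weights=None,
    *,
    window: tuple[_dt.time, _dt.time] = (WINDOW_START, WINDOW_END),
    biomass_in_window: bool = True,
    dates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per brood-day covariates: nestling ages, phase, delivered biomass.

    One row per brood-day, covering — unless ``dates`` supplies an explicit
    ``brood_id, date`` frame — every calendar date from each brood's first to
    last recorded peck that falls in phase 1 or 2 (so zero-peck days inside
    the observed span are represented).

    Parameters
    ----------
    weights
        :class:`kitepeck.biomass.CategoryWeightTable`; when ``None`` the
        ``biomass_g`` column is NaN.
    biomass_in_window
        Restrict deliveries to the observation window timestamps are not
        recorded for deliveries (daily resolution), so this currently has no
        effect beyond documenting the convention; retained for future
        sub-daily delivery logs.
    """
    from .biomass import daily_biomass_table  # local import to avoid cycle

    hatch = dataset.rank_hatch_dates()

    if dates is None:
        span = dataset.pecks.groupby("brood_id")["date"].agg(["min", "max"])
        rows = []
        for brood_id, (dmin, dmax) in span.iterrows():
            d = dmin
            while d <= dmax:
                rows.append((brood_id, d))
                d = d + _dt.timedelta(days=1)
        dates = pd.DataFrame(rows, columns=["brood_id", "date"])

    cov = dates.copy()
    for rank in RANKS:
        cov[f"age_{rank}"] = [
            (d - hatch.loc[b, rank]).days for b, d in zip(cov["brood_id"], cov["date"])
        ]
    cov["phase"] = [assign_phase(a) for a in cov["age_J"]]
    cov = cov[cov["phase"] != "excluded"].reset_index(drop=True)

    if weights is not None:
        biomass = daily_biomass_table(dataset.deliveries, weights)
        cov = cov.merge(biomass, on=["brood_id", "date"], how="left")
        cov["biomass_g"] = cov["biomass_g"].fillna(0.0)
    else:
        cov["biomass_g"] = np.nan
    return cov
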