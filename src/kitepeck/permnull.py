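"""Permutation null model for daily directed sibling aggression.

The "tendency to peck" controls for the opportunity to attack: each observed
daily directed interaction frequency is compared to its expectation under a
null model in which every peck's recipient is re-drawn uniformly from the
pool of possible recipients — in a brood of three, the actual recipient or
the one other sibling.  The deviation (observed − expected) is positive when
a target is preferentially attacked and negative when it is avoided.

With a two-recipient pool the per-event re-draw makes each permuted count a
Binomial(n, 1/2) variable given the attacker's daily total n, so the exact
expectation is n/2; :func:`expected_counts_analytic` is the closed form and
:func:`expected_counts_mc` the Monte-Carlo version used by the published
procedure (10,000 re-allocations).  Row totals are conserved exactly in both.

Counts tables are kept in long form: one row per directed dyad per brood-day
(6 rows: S→M, S→J, M→S, M→J, J→S, J→M).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .data import RANKS, Dataset

DYADS = [(a, r) for a, r in itertools.permutations(RANKS, 2)]

#: Seconds below which consecutive pecks in the same ordered dyad are treated
#: as one escalated "battle" by :func:`first_peck_filter`.
DEFAULT_BATTLE_GAP_S = 60.0


def _other_rank(attacker: str, recipient: str) -> str:
    return next(r for r in RANKS if r not in (attacker, recipient))


def daily_directed_counts(
    pecks: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    include_zero_days: bool = True,
) -> pd.DataFrame:
    """Tabulate daily directed peck counts per brood-day.

    Parameters
    ----------
    pecks
        Peck events carrying ``attacker_rank`` / ``recipient_rank`` columns
        (already window-filtered, triad broods only).
    covariates
        Optional brood-day frame (``brood_id, date``); when given and
        ``include_zero_days`` is true, covered brood-days with no pecks are
        emitted as all-zero rows flagged ``zero_day=True``.

    Returns
    -------
    DataFrame
        Long table ``brood_id, date, attacker_rank, recipient_rank, count,
        zero_day`` with 6 rows per brood-day; the total count equals the
        number of input peck events.
    """
    if pecks.empty and covariates is None:
        return pd.DataFrame(
            columns=["brood_id", "date", "attacker_rank", "recipient_rank",
                     "count", "zero_day"]
        )
    observed = (
        pecks.groupby(
            ["brood_id", "date", "attacker_rank", "recipient_rank"], observed=True
        )
        .size()
        .rename("count")
        .reset_index()
        if not pecks.empty
        else pd.DataFrame(
            columns=["brood_id", "date", "attacker_rank", "recipient_rank", "count"]
        )
    )

    days = (
        observed[["brood_id", "date"]].drop_duplicates()
        if not pecks.empty
        else pd.DataFrame(columns=["brood_id", "date"])
    )
    if covariates is not None and include_zero_days:
        days = (
            pd.concat([days, covariates[["brood_id", "date"]]])
            .drop_duplicates()
            .reset_index(drop=True)
        )

    dyads = pd.DataFrame(DYADS, columns=["attacker_rank", "recipient_rank"])
    full = days.merge(dyads, how="cross")
    full = full.merge(
        observed, on=["brood_id", "date", "attacker_rank", "recipient_rank"],
        how="left",
    )
    full["count"] = full["count"].fillna(0).astype(int)
    day_totals = full.groupby(["brood_id", "date"])["count"].transform("sum")
    full["zero_day"] = day_totals == 0
    if not include_zero_days:
        full = full[~full["zero_day"]].reset_index(drop=True)
    return full.sort_values(
        ["brood_id", "date", "attacker_rank", "recipient_rank"]
    ).reset_index(drop=True)


def _attacker_totals(counts: pd.DataFrame) -> pd.Series:
    return counts.groupby(["brood_id", "date", "attacker_rank"])["count"].transform(
        "sum"
    )


def expected_counts_analytic(counts: pd.DataFrame) -> pd.DataFrame:
    """Closed-form null expectation: half the attacker's daily total per dyad."""
    out = counts.copy()
    out["expected"] = _attacker_totals(counts).to_numpy() / 2.0
    return out


def expected_counts_mc(
    counts: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo null expectation from ``n_perm`` recipient re-allocations.

    For every peck the recipient is re-drawn uniformly from the attacker's two
    siblings; the expected count is the mean over permutations.  Per
    attacker-day the two expected counts sum to the observed total exactly
    (the second recipient's permuted count is the complement of the first).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    out = counts.reset_index(drop=True).reset_index(names="_orig_row")
    out = out.sort_values(
        ["brood_id", "date", "attacker_rank", "recipient_rank"]
    ).reset_index(drop=True)
    totals = (
        out.groupby(["brood_id", "date", "attacker_rank"])["count"]
        .sum()
        .reset_index()
    )
    n = totals["count"].to_numpy()
    # permuted count for the rank-order-first recipient of each attacker-day
    draws = rng.binomial(n[:, None], 0.5, size=(len(n), n_perm))
    first = draws.mean(axis=1)
    totals["_e_first"] = first
    out = out.merge(totals.drop(columns="count"),
                    on=["brood_id", "date", "attacker_rank"], how="left")
    # within each attacker-day the recipients are in rank-order; the first
    # gets the simulated mean, the second the exact complement
    is_first = (
        out.groupby(["brood_id", "date", "attacker_rank"]).cumcount() == 0
    ).to_numpy()
    tot = _attacker_totals(out).to_numpy()
    out["expected"] = np.where(is_first, out["_e_first"], tot - out["_e_first"])
    return (
        out.sort_values("_orig_row")
        .drop(columns=["_e_first", "_orig_row"])
        .reset_index(drop=True)
    )


def expected_matrix_analytic(counts3x3: np.ndarray) -> np.ndarray:
    """3x3 convenience form of :func:`expected_counts_analytic`."""
    counts3x3 = np.asarray(counts3x3, dtype=float)
    expected = np.zeros_like(counts3x3)
    for i in range(3):
        row_total = counts3x3[i].sum()
        for j in range(3):
            if i != j:
                expected[i, j] = row_total / 2.0
    return expected


def expected_matrix_mc(
    counts3x3: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """3x3 convenience form of :func:`expected_counts_mc`."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    counts3x3 = np.asarray(counts3x3)
    expected = np.zeros((3, 3), dtype=float)
    for i in range(3):
        others = [j for j in range(3) if j != i]
        n = int(counts3x3[i].sum())
        first = rng.binomial(n, 0.5, size=n_perm).mean() if n else 0.0
        expected[i, others[0]] = first
        expected[i, others[1]] = n - first
    return expected


def deviation_table(
    counts: pd.DataFrame,
    expected: pd.DataFrame,
    covariates: pd.DataFrame,
    broods: pd.DataFrame,
) -> pd.DataFrame:
    """Join deviations with brood-day covariates into the modelling table.

    One row per directed dyad per brood-day with ``observed``, ``expected``,
    ``deviation`` (= observed − expected), the signed age difference
    ``delta_days`` (hatch(attacker) − hatch(recipient); negative when the
    attacker is older), ``biomass_g`` and ``phase``.  Brood-days lacking
    covariates (e.g. missing biomass) are dropped with a warning entry
    returned on the frame's ``attrs['dropped_brood_days']``.
    """
    key = ["brood_id", "date", "attacker_rank", "recipient_rank"]
    tab = counts.merge(expected[key + ["expected"]], on=key, how="left")
    tab["deviation"] = tab["count"] - tab["expected"]
    tab = tab.rename(columns={"count": "observed"})

    hatch = broods.pivot(index="brood_id", columns="hatch_rank",
                         values="hatch_date")
    att = np.array(
        [hatch.loc[b, a] for b, a in zip(tab["brood_id"], tab["attacker_rank"])]
    )
    rec = np.array(
        [hatch.loc[b, r] for b, r in zip(tab["brood_id"], tab["recipient_rank"])]
    )
    tab["delta_days"] = [(a - r).days for a, r in zip(att, rec)]

    before = len(tab)
    cov_cols = ["brood_id", "date", "biomass_g", "phase", "age_S", "age_M", "age_J"]
    tab = tab.merge(covariates[cov_cols], on=["brood_id", "date"], how="inner")
    tab = tab[tab["biomass_g"].notna()].reset_index(drop=True)
    dropped = before - len(tab)
    tab.attrs["dropped_brood_days"] = dropped // 6
    if dropped:
        import warnings

        warnings.warn(
            f"deviation_table: dropped {dropped} dyad rows lacking covariates",
            stacklevel=2,
        )
    return tab


def bootstrap_splits(
    pecks: pd.DataFrame,
    frac: float = 0.8,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
):
    """Yield ``n_boot`` random subsets of ``floor(frac * N)`` peck events.

    Sampling is uniform without replacement within each subset (the unit is
    the peck event); the generator is seeded for reproducibility.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(pecks)
    if n < 2:
        raise ValueError("need at least 2 peck events to split")
    rng = np.random.default_rng(rng)
    size = int(np.floor(frac * n))
    for _ in range(n_boot):
        idx = rng.choice(n, size=size, replace=False)
        yield pecks.iloc[np.sort(idx)].reset_index(drop=True)


def first_peck_filter(
    pecks: pd.DataFrame, battle_gap_seconds: float = DEFAULT_BATTLE_GAP_S
) -> pd.DataFrame:
    """Keep only the opening peck of each dyadic battle.

    A peck is dropped iff the previous peck in the same ordered dyad (same
    brood, attacker and recipient) occurred strictly less than
    ``battle_gap_seconds`` but more than 0 seconds earlier; pecks sharing a
    timestamp (1 s recording resolution) are not "earlier" and are retained,
    as is everything with a gap of 0.  Escalated exchanges thus contribute a
    single event each.
    """
    if battle_gap_seconds < 0:
        raise ValueError("battle_gap_seconds must be >= 0")
    if pecks.empty or battle_gap_seconds == 0:
        return pecks.copy().reset_index(drop=True)
    df = pecks.copy()
    secs = np.array(
        [t.hour * 3600 + t.minute * 60 + t.second for t in df["time"]], dtype=float
    )
    df["_abs_s"] = [
        d.toordinal() * 86400.0 + s for d, s in zip(df["date"], secs)
    ]
    def _keep(times: pd.Series) -> pd.Series:
        t = times.to_numpy()
        uniq, inverse = np.unique(t, return_inverse=True)
        prev = np.concatenate([[np.nan], uniq[:-1]])
        since_prev = t - prev[inverse]  # seconds since nearest earlier peck
        ok = np.isnan(since_prev) | (since_prev >= battle_gap_seconds)
        return pd.Series(ok, index=times.index)

    keep = (
        df.groupby(["brood_id", "attacker_id", "recipient_id"], group_keys=False)
        ["_abs_s"]
        .apply(_keep)
    )
    out = df[keep.reindex(df.index)].drop(columns="_abs_s")
    return out.sort_index().reset_index(drop=True)
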