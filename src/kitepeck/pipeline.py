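"""End-to-end orchestration: ingest → biomass → null model → models → reports.

Two pipelines mirror the two halves of the analysis:

``run_tendency_pipeline``
    window filter → daily directed counts → Monte-Carlo permutation null →
    deviations → bootstrap re-splits → per-side smooth fits → mean curves
    with 95% bands at the min/median/max daily biomass → pattern labels.
``run_allocation_pipeline``
    window filter → daily peck log-ratios → join bouts to brood-day
    covariates → multinomial additive fit → share curves over biomass and
    log-ratio grids with cluster-bootstrap bands.

Each run writes CSV/JSON artifacts plus a machine-readable manifest (seed,
parameters, package version) sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import (
    FoodAllocationModel,
    daily_peck_log_ratio,
    fit_allocation_model,
    predict_allocation_shares,
)
from .biomass import CategoryWeightTable
from .data import Dataset, brood_day_covariates, filter_observation_window
from .permnull import (
    bootstrap_splits,
    daily_directed_counts,
    deviation_table,
    expected_counts_mc,
    first_peck_filter,
)
from .tendency import (
    SIDES,
    biomass_levels,
    classify_pattern,
    fit_tendency_model,
    predict_tendency_curves,
    split_side,
)

logger = logging.getLogger("kitepeck")


@dataclass
class TendencyParams:
    """Tuning knobs of the tendency pipeline (defaults = published procedure)."""

    n_perm: int = 10_000
    n_boot: int = 100
    frac: float = 0.8
    seed: int = 42
    first_peck_only: bool = False
    battle_gap_s: float = 60.0
    include_zero_days: bool = False
    gam_params: dict = field(default_factory=dict)


@dataclass
class AllocationParams:
    n_boot: int = 100
    seed: int = 42
    ratio_c: float = 0.5
    grid_points: int = 25
    model_params: dict = field(default_factory=dict)


@dataclass
class TendencyResult:
    deviations: pd.DataFrame
    curves: pd.DataFrame
    patterns: dict
    summary: pd.DataFrame
    manifest: dict


@dataclass
class AllocationResult:
    ratios: pd.DataFrame
    model: FoodAllocationModel
    shares_vs_biomass: pd.DataFrame
    shares_vs_ratio: pd.DataFrame
    manifest: dict


def _manifest(stage: str, params, seed: int, extra: dict | None = None) -> dict:
    m = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "params": dataclasses.asdict(params),
    }
    if extra:
        m.update(extra)
    return m


def _log_filter(stage: str, before: int, after: int) -> None:
    logger.info("%s: %d -> %d rows", stage, before, after)


def compute_deviations(
    pecks: pd.DataFrame,
    covariates: pd.DataFrame,
    broods: pd.DataFrame,
    n_perm: int,
    rng,
    include_zero_days: bool,
) -> pd.DataFrame:
    counts = daily_directed_counts(
        pecks, covariates if include_zero_days else None,
        include_zero_days=include_zero_days,
    )
    expected = expected_counts_mc(counts, n_perm=n_perm, rng=rng)
    return deviation_table(counts, expected, covariates, broods)


def run_tendency_pipeline(
    dataset: Dataset,
    weights: CategoryWeightTable,
    params: TendencyParams | None = None,
    out_dir: str | Path | None = None,
) -> TendencyResult:
    """Full tendency-to-peck analysis on a validated dataset."""
    params = params or TendencyParams()
    rng = np.random.default_rng(params.seed)

    n0 = len(dataset.pecks)
    pecks = filter_observation_window(dataset.pecks)
    _log_filter("observation window", n0, len(pecks))
    if params.first_peck_only:
        n0 = len(pecks)
        pecks = first_peck_filter(pecks, params.battle_gap_s)
        _log_filter("first-peck filter", n0, len(pecks))

    covariates = brood_day_covariates(dataset, weights)

    # point estimate on the full (filtered) data
    deviations = compute_deviations(
        pecks, covariates, dataset.broods, params.n_perm, rng,
        params.include_zero_days,
    )

    # bootstrap the 80% split; refit both sides each time
    side_fits: dict[str, list] = {side: [] for side in SIDES}
    for subset in bootstrap_splits(pecks, params.frac, params.n_boot, rng):
        dev_b = compute_deviations(
            subset, covariates, dataset.broods, params.n_perm, rng,
            params.include_zero_days,
        )
        for side in SIDES:
            try:
                side_fits[side].append(
                    fit_tendency_model(
                        dev_b, side,
                        include_zero_days=params.include_zero_days,
                        **params.gam_params,
                    )
                )
            except Exception as exc:  # a thin side may fail on some subsets
                logger.warning("bootstrap fit failed on side %s: %s", side, exc)

    curves = []
    for side in SIDES:
        fits = side_fits[side]
        if len(fits) < 2:
            logger.warning("side %s: fewer than 2 bootstrap fits; skipped", side)
            continue
        rows = split_side(deviations, side)
        levels = biomass_levels(rows)
        lo, hi = int(rows["delta_days"].min()), int(rows["delta_days"].max())
        grid = np.arange(lo, hi + 1)
        # m-out-of-n correction: an 80% re-split understates full-sample
        # variability by sqrt((1 - frac) / frac)
        factor = float(np.sqrt(params.frac / (1.0 - params.frac))) \
            if params.frac < 1 else 1.0
        curves.append(
            predict_tendency_curves(fits, levels, grid, side=side,
                                    scale_factor=factor)
        )
    curves = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()

    patterns: dict = {"assumptions": {
        "delta0_assignment": "hatch order (earlier rank -> attacker_older)",
        "biomass_levels": "min/median/max over modelled brood-days per side",
        "prediction_grid": "integer days spanning the observed range per side",
    }}
    older = curves[curves["side"] == "attacker_older"] if len(curves) else curves
    for (phase, level), grp in (
        older.groupby(["phase", "biomass_level"]) if len(older) else []
    ):
        patterns.setdefault(f"phase{phase}", {})[level] = classify_pattern(grp)

    summary = export_network_summary(pecks, covariates)

    manifest = _manifest(
        "tendency", params, params.seed,
        {"n_pecks": int(len(pecks)), "n_broods": int(dataset.broods["brood_id"].nunique())},
    )
    result = TendencyResult(deviations, curves, patterns, summary, manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        deviations.to_csv(out_dir / "deviations.csv", index=False)
        curves.to_csv(out_dir / "curves.csv", index=False)
        summary.to_csv(out_dir / "network_summary.csv", index=False)
        (out_dir / "patterns.json").write_text(json.dumps(patterns, indent=2))
        (out_dir / "manifest_tendency.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    return result


def run_allocation_pipeline(
    dataset: Dataset,
    weights: CategoryWeightTable,
    params: AllocationParams | None = None,
    out_dir: str | Path | None = None,
) -> AllocationResult:
    """Full food-allocation analysis on a validated dataset."""
    params = params or AllocationParams()
    rng = np.random.default_rng(params.seed)

    pecks = filter_observation_window(dataset.pecks)
    bouts = filter_observation_window(dataset.bouts)
    covariates = brood_day_covariates(dataset, weights)
    counts = daily_directed_counts(pecks, covariates, include_zero_days=True)
    ratios = daily_peck_log_ratio(counts, c=params.ratio_c)

    model = fit_allocation_model(
        bouts, covariates, ratios, **params.model_params
    )
    tab = model.training_table_
    mean_age = float(tab["age_oldest"].mean())

    bio_grid = pd.DataFrame(
        {"biomass_g": np.linspace(tab["biomass_g"].min(), tab["biomass_g"].max(),
                                  params.grid_points)}
    )
    ratio_grid = pd.DataFrame(
        {"log_peck_ratio": np.linspace(tab["log_peck_ratio"].min(),
                                       tab["log_peck_ratio"].max(),
                                       params.grid_points)}
    )
    shares_bio = predict_allocation_shares(model, bio_grid, at_age_oldest=mean_age)
    shares_ratio = predict_allocation_shares(model, ratio_grid, at_age_oldest=mean_age)

    # brood-day cluster bootstrap for the uncertainty bands; resampled data
    # rarely span the full-grid covariate range, so clamp warnings are noise
    import warnings as _warnings

    days = tab[["brood_id", "date"]].drop_duplicates().reset_index(drop=True)
    boot_bio, boot_ratio = [], []
    for _ in range(params.n_boot):
        pick = days.iloc[rng.integers(0, len(days), size=len(days))]
        sample = pick.merge(tab, on=["brood_id", "date"], how="left")
        try:
            m = FoodAllocationModel(**params.model_params).fit(
                sample[["biomass_g", "log_peck_ratio", "age_oldest", "brood_id"]],
                sample["recipient_rank"].to_numpy(),
            )
            m.training_table_ = sample
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                boot_bio.append(
                    predict_allocation_shares(m, bio_grid, at_age_oldest=mean_age)
                )
                boot_ratio.append(
                    predict_allocation_shares(m, ratio_grid, at_age_oldest=mean_age)
                )
        except Exception as exc:
            logger.warning("allocation bootstrap fit failed: %s", exc)

    for shares, boots in [(shares_bio, boot_bio), (shares_ratio, boot_ratio)]:
        for rank in ("S", "M", "J"):
            if boots:
                stack = np.array([b[rank].to_numpy() for b in boots])
                lo, hi = np.percentile(stack, [2.5, 97.5], axis=0)
            else:
                lo = hi = shares[rank].to_numpy()
            shares[f"{rank}_lo95"] = lo
            shares[f"{rank}_hi95"] = hi

    manifest = _manifest(
        "allocation", params, params.seed,
        {"n_bouts": int(len(tab)), "mean_age_oldest": mean_age},
    )
    result = AllocationResult(ratios, model, shares_bio, shares_ratio, manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ratios.to_csv(out_dir / "peck_log_ratios.csv", index=False)
        shares_bio.to_csv(out_dir / "shares_vs_biomass.csv", index=False)
        shares_ratio.to_csv(out_dir / "shares_vs_ratio.csv", index=False)
        (out_dir / "manifest_allocation.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    return result


def export_network_summary(
    pecks: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Mean daily dyadic peck counts and dyad percentages per phase x food tercile.

    Food terciles (poor / average / favourable) are assigned to brood-days by
    ranking daily biomass within each phase.  Percentages are each dyad's
    share of all pecks in its phase and sum to 100 within phase.
    """
    counts = daily_directed_counts(pecks, covariates, include_zero_days=True)
    cov = covariates[["brood_id", "date", "phase", "biomass_g"]].copy()
    counts = counts.merge(cov, on=["brood_id", "date"], how="inner")

    def _tercile(s: pd.Series) -> pd.Series:
        if s.nunique() < 3:
            return pd.Series(["average"] * len(s), index=s.index)
        return pd.qcut(s.rank(method="first"), 3,
                       labels=["poor", "average", "favourable"])

    day = counts[["brood_id", "date", "phase", "biomass_g"]].drop_duplicates()
    day["food"] = day.groupby("phase")["biomass_g"].transform(_tercile)
    counts = counts.merge(day[["brood_id", "date", "food"]],
                          on=["brood_id", "date"], how="left")

    mean_daily = (
        counts.groupby(["phase", "food", "attacker_rank", "recipient_rank"],
                       observed=True)["count"]
        .mean()
        .rename("mean_daily_pecks")
        .reset_index()
    )
    phase_totals = counts.groupby("phase")["count"].transform("sum")
    counts["_pt"] = phase_totals
    dyad_share = (
        counts.groupby(["phase", "attacker_rank", "recipient_rank"],
                       observed=True)
        .apply(lambda g: 100.0 * g["count"].sum() / g["_pt"].iloc[0]
               if g["_pt"].iloc[0] > 0 else 0.0, include_groups=False)
        .rename("pct_of_phase_pecks")
        .reset_index()
    )
    out = mean_daily.merge(dyad_share,
                           on=["phase", "attacker_rank", "recipient_rank"],
                           how="left")
    return out.sort_values(
        ["phase", "food", "attacker_rank", "recipient_rank"]
    ).reset_index(drop=True)
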