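"""Smooth models of the tendency to peck vs. age difference and food.

The deviation from random interactions (observed − permutation-expected daily
dyad count) is modelled as a Gaussian response with a phase-specific
tensor-product smooth surface over (age difference, daily biomass) and a
penalized brood intercept.  Two separate models are fitted for dyads where
the attacker is older vs. younger than the recipient, because behaviour need
not be continuous through an age difference of zero.  Uncertainty comes from
refitting on bootstrap re-splits of the event log and taking pointwise
percentile intervals of the predictions.

Pattern classification (attacker-older side) follows the three-way framework
for aggression down a dominance hierarchy:

close_competitor
    preferential attack of similar-aged siblings (CI above 0 at |Δ| <= 1)
    together with avoidance of the much younger sibling (CI below 0 at the
    most negative Δ).
downward_heuristic
    indistinguishable from random across the whole age-difference range
    (every CI covers 0).
bullying
    preferential attack of the youngest only (CI above 0 at the most
    negative Δ and nowhere else).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._pspline import BSplineBasis, fit_penalized_ls, row_kron, tensor_penalty
from .errors import DegenerateDesignError, FitError

SIDES = ("attacker_older", "attacker_younger")
_RANK_ORDER = {"S": 0, "M": 1, "J": 2}

_REQUIRED_COLS = ("delta_days", "biomass_g", "phase", "brood_id")


class TendencyGAM(RegressorMixin, BaseEstimator):
    """Penalized tensor-product spline regression for peck-tendency deviations.

    Parameters
    ----------
    delta_df, biomass_df : int
        Marginal B-spline basis dimensions of the tensor smooth (default 5).
    degree : int
        Spline degree (default cubic).
    lambda_smooth_grid, lambda_brood_grid : sequence of float
        Candidate smoothing parameters for the surface difference penalty
        (one per phase) and the ridge on brood intercepts; the combination
        minimising GCV is kept.
    lambda_null_grid : sequence of float
        Candidate weights, relative to the design scale, of a shrinkage
        ("double penalty") ridge on the whole surface.  The difference
        penalty leaves plane-like surfaces unpenalized, so pure noise can
        masquerade as a tilted surface; letting GCV also shrink the null
        space means a data set with no age-difference structure is fitted as
        a flat zero surface.  Includes 0, so shrinkage is optional per fit.

    Attributes
    ----------
    coef_ : ndarray
        Stacked coefficients (per-phase tensor blocks, then brood dummies).
    phases_, broods_ : list
        Levels seen during fit.
    lambdas_, gcv_, edf_ : fit diagnostics.
    """

    def __init__(
        self,
        delta_df: int = 5,
        biomass_df: int = 5,
        degree: int = 3,
        lambda_smooth_grid=(0.1, 1.0, 10.0, 100.0, 1e3),
        lambda_brood_grid=(1.0, 100.0),
        lambda_null_grid=(0.0, 0.01, 1.0, 100.0),
        penalty_order: int = 2,
    ):
        self.delta_df = delta_df
        self.biomass_df = biomass_df
        self.degree = degree
        self.lambda_smooth_grid = lambda_smooth_grid
        self.lambda_brood_grid = lambda_brood_grid
        self.lambda_null_grid = lambda_null_grid
        self.penalty_order = penalty_order

    # -- design ---------------------------------------------------------
    def _smooth_design(self, X: pd.DataFrame) -> np.ndarray:
        b_delta = self._basis_delta.design(X["delta_days"].to_numpy(float))
        b_bio = self._basis_bio.design(X["biomass_g"].to_numpy(float))
        tensor = row_kron(b_delta, b_bio)
        blocks = []
        phase = X["phase"].astype(str).to_numpy()
        for ph in self.phases_:
            mask = (phase == ph).astype(float)[:, None]
            blocks.append(tensor * mask)
        return np.hstack(blocks)

    def _full_design(self, X: pd.DataFrame, for_fit: bool) -> np.ndarray:
        smooth = self._smooth_design(X)
        n = len(X)
        brood_block = np.zeros((n, len(self.broods_)))
        if "brood_id" in X.columns:
            brood_idx = {b: i for i, b in enumerate(self.broods_)}
            for row, b in enumerate(X["brood_id"]):
                col = brood_idx.get(b)
                if col is not None:
                    brood_block[row, col] = 1.0
        elif for_fit:
            raise ValueError("fit requires a brood_id column")
        return np.hstack([smooth, brood_block])

    # -- estimator API ----------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        X = self._validate_frame(X, fitting=True)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if X["delta_days"].nunique() < 2:
            raise DegenerateDesignError(
                "only one age-difference value on this side; pool sides or "
                "add data before fitting a smooth"
            )

        d = X["delta_days"].to_numpy(float)
        b = X["biomass_g"].to_numpy(float)
        self._basis_delta = BSplineBasis(
            d.min(), d.max(), df=self.delta_df, degree=self.degree
        )
        self._basis_bio = BSplineBasis(
            b.min(), b.max(), df=self.biomass_df, degree=self.degree
        )
        self.phases_ = sorted(X["phase"].astype(str).unique())
        self.broods_ = sorted(X["brood_id"].unique())

        design = self._full_design(X, for_fit=True)
        p_tensor = tensor_penalty(
            self._basis_delta.penalty(self.penalty_order),
            self._basis_bio.penalty(self.penalty_order),
        )
        block = self.delta_df * self.biomass_df
        scale = np.trace(design.T @ design) / design.shape[1]
        penalties = []
        for i, ph in enumerate(self.phases_):
            sl = slice(i * block, (i + 1) * block)
            penalties.append((f"smooth_{ph}", p_tensor, sl))
            penalties.append(("null", np.eye(block), sl))
        n_smooth = block * len(self.phases_)
        penalties.append(
            ("brood", np.eye(len(self.broods_)),
             slice(n_smooth, n_smooth + len(self.broods_)))
        )
        grid = {f"smooth_{ph}": self.lambda_smooth_grid for ph in self.phases_}
        grid["null"] = [lam * scale for lam in self.lambda_null_grid]
        grid["brood"] = self.lambda_brood_grid

        res = fit_penalized_ls(design, y, penalties, grid)
        self.coef_ = res["coef"]
        self.lambdas_ = res["lambdas"]
        self.gcv_ = res["gcv"]
        self.edf_ = res["edf"]
        self.n_features_in_ = design.shape[1]
        resid = y - design @ self.coef_
        self.residual_mean_ = float(resid.mean())
        self.residual_sd_ = float(resid.std())
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = self._validate_frame(X, fitting=False)
        unknown = set(X["phase"].astype(str)) - set(self.phases_)
        if unknown:
            raise ValueError(f"phase(s) {sorted(unknown)} not seen during fit")
        design = self._full_design(X, for_fit=False)
        return design @ self.coef_

    @staticmethod
    def _validate_frame(X: pd.DataFrame, fitting: bool) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named covariates")
        required = [c for c in _REQUIRED_COLS if fitting or c != "brood_id"]
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise ValueError(f"X missing columns: {missing}")
        return X


def split_side(deviations: pd.DataFrame, side: str) -> pd.DataFrame:
    """Rows of the deviation table belonging to one model side.

    Age-difference zero (same-day hatchlings) is assigned by hatch order: the
    attacker earlier in S>M>J order goes to the attacker-older model.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    delta = deviations["delta_days"].to_numpy()
    att = deviations["attacker_rank"].map(_RANK_ORDER).to_numpy()
    rec = deviations["recipient_rank"].map(_RANK_ORDER).to_numpy()
    older = (delta < 0) | ((delta == 0) & (att < rec))
    mask = older if side == "attacker_older" else ~older
    return deviations[mask].reset_index(drop=True)


def fit_tendency_model(
    deviations: pd.DataFrame,
    side: str,
    *,
    include_zero_days: bool = False,
    **gam_params,
) -> TendencyGAM:
    """Fit the per-side smooth model on a deviation table.

    Requires at least 2 broods and 20 rows on the chosen side; zero-peck
    brood-days are excluded from fitting unless ``include_zero_days``.
    """
    rows = split_side(deviations, side)
    if "zero_day" in rows.columns and not include_zero_days:
        rows = rows[~rows["zero_day"]].reset_index(drop=True)
    if rows["brood_id"].nunique() < 2:
        raise FitError("need deviations from at least 2 broods")
    if len(rows) < 20:
        raise FitError(f"need >= 20 rows on side {side!r}, got {len(rows)}")
    model = TendencyGAM(**gam_params)
    model.fit(rows[list(_REQUIRED_COLS)], rows["deviation"].to_numpy())
    model.side_ = side
    return model


def biomass_levels(deviations_side: pd.DataFrame) -> dict[str, float]:
    """min / median / max daily biomass over the modelled brood-days."""
    per_day = deviations_side.drop_duplicates(["brood_id", "date"])["biomass_g"]
    return {
        "min": float(per_day.min()),
        "median": float(per_day.median()),
        "max": float(per_day.max()),
    }


def predict_tendency_curves(
    fits: list[TendencyGAM],
    biomass_levels: dict[str, float],
    delta_grid,
    side: str | None = None,
    scale_factor: float = 1.0,
) -> pd.DataFrame:
    """Aggregate bootstrap fits into mean curves with pointwise 95% bands.

    One curve per phase x biomass level: the mean and the 2.5/97.5 percentile
    of the bootstrap predictions at every grid point.

    ``scale_factor`` stretches the percentile band around the bootstrap mean;
    the pipeline passes sqrt(frac / (1 - frac)) as the m-out-of-n correction
    for bands built from fractional re-splits of the data, which on their own
    understate full-sample variability.  The default 1.0 is the plain
    percentile rule.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fitted model")
    side = side or getattr(fits[0], "side_", "attacker_older")
    delta_grid = np.asarray(delta_grid, dtype=float)
    phases = sorted({ph for f in fits for ph in f.phases_})

    records = []
    for ph in phases:
        for level, grams in biomass_levels.items():
            grid = pd.DataFrame(
                {
                    "delta_days": delta_grid,
                    "biomass_g": grams,
                    "phase": ph,
                }
            )
            preds = np.array(
                [f.predict(grid) for f in fits if ph in f.phases_]
            )
            lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
            mean = preds.mean(axis=0)
            if scale_factor != 1.0:
                lo = mean + scale_factor * (lo - mean)
                hi = mean + scale_factor * (hi - mean)
            for k, dd in enumerate(delta_grid):
                records.append(
                    {
                        "side": side,
                        "phase": ph,
                        "biomass_level": level,
                        "biomass_g": grams,
                        "delta_days": dd,
                        "mean": mean[k],
                        "lo95": lo[k],
                        "hi95": hi[k],
                    }
                )
    return pd.DataFrame.from_records(records)


def classify_pattern(curve: pd.DataFrame) -> str:
    """Label one attacker-older tendency curve.

    ``curve`` holds a single side x phase x biomass level with columns
    ``delta_days, mean, lo95, hi95``.  Returns one of ``close_competitor``,
    ``downward_heuristic``, ``bullying`` or ``mixed`` (see module docstring
    for the decision rule).
    """
    if "side" in curve.columns:
        sides = set(curve["side"])
        if sides != {"attacker_older"}:
            raise ValueError(
                "pattern classification is defined down-rank "
                f"(attacker_older side only), got {sorted(sides)}"
            )
    curve = curve.sort_values("delta_days")
    delta = curve["delta_days"].to_numpy(float)
    above = (curve["lo95"] > 0).to_numpy()
    below = (curve["hi95"] < 0).to_numpy()
    covers = ~above & ~below

    near = np.abs(delta) <= 1
    mostneg = delta == delta.min()

    if near.any() and above[near].all() and below[mostneg].all():
        return "close_competitor"
    if covers.all():
        return "downward_heuristic"
    if above[mostneg].all() and not above[~mostneg].any():
        return "bullying"
    return "mixed"
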