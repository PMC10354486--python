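"""Multinomial additive model of food allocation among S, M and J.

Each parental feeding bout goes to exactly one of the three hatch ranks.  The
probability of each rank receiving a bout is modelled as a multinomial logit
with smooth (B-spline) effects of the day's total delivered biomass (basis
dimension 4), of the day's log peck ratio (dimension 3, quadratic) and of the
age of the oldest nestling (dimension 5), plus a ridge-penalized brood
intercept.  The log peck ratio, ln(pecks received by M / pecks received by J)
with a Haldane–Anscombe constant for zero days, is a daily proxy for the
prevailing aggression pattern: positive values indicate close-competitor
fighting among the older pair, values at or below zero a downward-heuristic
spread of attacks.

The estimator is fitted by penalized maximum likelihood (ridge multinomial
logistic regression); uncertainty bands for predicted share curves come from
a brood-day cluster bootstrap in the pipeline layer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from ._pspline import BSplineBasis
from .data import RANKS
from .errors import FitError

_COVARIATES = ("biomass_g", "log_peck_ratio", "age_oldest")


def daily_peck_log_ratio(counts: pd.DataFrame, c: float = 0.5) -> pd.DataFrame:
    """Daily ln((pecks received by M + c) / (pecks received by J + c)).

    ``counts`` is the long daily directed counts table; attacks received by a
    rank sum over both possible attackers.  ``c > 0`` keeps zero-peck days
    finite (days with no pecks at all map to 0).
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    received = (
        counts.groupby(["brood_id", "date", "recipient_rank"])["count"]
        .sum()
        .unstack("recipient_rank")
        .fillna(0.0)
    )
    for rank in ("M", "J"):
        if rank not in received.columns:
            received[rank] = 0.0
    if c == 0 and ((received["M"] == 0) | (received["J"] == 0)).any():
        raise ValueError(
            "zero received-peck count with c = 0 gives an undefined log "
            "ratio; use c > 0 (default 0.5)"
        )
    out = received.reset_index()[["brood_id", "date"]]
    out["log_peck_ratio"] = np.log(
        (received["M"].to_numpy() + c) / (received["J"].to_numpy() + c)
    )
    return out


class FoodAllocationModel(ClassifierMixin, BaseEstimator):
    """Penalized multinomial additive model for feeding-bout recipients.

    Parameters
    ----------
    biomass_df, ratio_df, age_df : int
        Basis dimensions of the three smoothers (defaults 4, 3, 5; the ratio
        smoother uses quadratic splines so a dimension of 3 is feasible).
    C : float
        Inverse ridge strength of the underlying multinomial logit.

    Attributes
    ----------
    classes_ : the rank labels (subset of S/M/J actually observed).
    brood_effects_ : DataFrame (class x brood) of brood-intercept coefficients.
    """

    def __init__(
        self,
        biomass_df: int = 4,
        ratio_df: int = 3,
        age_df: int = 5,
        C: float = 10.0,
        max_iter: int = 2000,
    ):
        self.biomass_df = biomass_df
        self.ratio_df = ratio_df
        self.age_df = age_df
        self.C = C
        self.max_iter = max_iter

    def _make_bases(self, X: pd.DataFrame) -> None:
        b = X["biomass_g"].to_numpy(float)
        r = X["log_peck_ratio"].to_numpy(float)
        a = X["age_oldest"].to_numpy(float)
        self._bases = {
            "biomass_g": BSplineBasis(b.min(), b.max(), df=self.biomass_df,
                                      degree=min(3, self.biomass_df - 1)),
            "log_peck_ratio": BSplineBasis(r.min(), r.max(), df=self.ratio_df,
                                           degree=min(3, self.ratio_df - 1)),
            "age_oldest": BSplineBasis(a.min(), a.max(), df=self.age_df,
                                       degree=min(3, self.age_df - 1)),
        }
        self.ranges_ = {
            name: (basis.lo, basis.hi) for name, basis in self._bases.items()
        }

    def _design(self, X: pd.DataFrame, check_range: bool = False) -> np.ndarray:
        blocks = []
        for name in _COVARIATES:
            x = X[name].to_numpy(float)
            if check_range:
                lo, hi = self.ranges_[name]
                if (x < lo).any() or (x > hi).any():
                    warnings.warn(
                        f"{name}: prediction grid extends beyond the observed "
                        f"range [{lo:g}, {hi:g}]; values are clamped",
                        stacklevel=2,
                    )
            # drop the first basis column of each smoother (absorbed by the
            # intercept) to avoid three redundant sum-to-one blocks
            blocks.append(self._bases[name].design(x)[:, 1:])
        n = len(X)
        brood_block = np.zeros((n, len(self.broods_)))
        if "brood_id" in X.columns:
            idx = {b: i for i, b in enumerate(self.broods_)}
            for row, b in enumerate(X["brood_id"]):
                col = idx.get(b)
                if col is not None:
                    brood_block[row, col] = 1.0
        blocks.append(brood_block)
        return np.hstack(blocks)

    def fit(self, X: pd.DataFrame, y):
        missing = [c for c in _COVARIATES if c not in X.columns]
        if missing:
            raise ValueError(f"X missing columns: {missing}")
        if "brood_id" not in X.columns:
            raise ValueError("fit requires a brood_id column")
        y = np.asarray(y, dtype=object)
        observed = set(y)
        never = [r for r in RANKS if r not in observed]
        if never:
            raise FitError(
                f"rank(s) never observed as bout recipients: {never}; the "
                "multinomial model needs all three categories"
            )
        self.broods_ = sorted(X["brood_id"].unique())
        self._make_bases(X)
        design = self._design(X)
        self._clf = LogisticRegression(
            C=self.C, max_iter=self.max_iter, solver="lbfgs"
        )
        self._clf.fit(design, y)
        self.classes_ = self._clf.classes_
        n_smooth = design.shape[1] - len(self.broods_)
        self.coef_ = self._clf.coef_
        self.brood_effects_ = pd.DataFrame(
            self._clf.coef_[:, n_smooth:], index=self.classes_,
            columns=self.broods_,
        )
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "classes_")
        design = self._design(X, check_range=True)
        return self._clf.predict_proba(design)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_shares(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predicted S/M/J shares (columns in rank order) per row of ``X``."""
        proba = self.predict_proba(X)
        out = pd.DataFrame(proba, columns=list(self.classes_), index=X.index)
        return out[[r for r in RANKS if r in out.columns]]


def fit_allocation_model(
    bouts: pd.DataFrame,
    covariates: pd.DataFrame,
    ratios: pd.DataFrame,
    *,
    max_age_oldest: int = 21,
    **params,
) -> FoodAllocationModel:
    """Join bouts to brood-day covariates and fit the allocation model.

    Bouts on brood-days whose oldest nestling exceeds ``max_age_oldest`` days
    are excluded (feeding bouts were only scored to that age).
    """
    tab = bouts.merge(covariates, on=["brood_id", "date"], how="inner")
    tab = tab.merge(ratios, on=["brood_id", "date"], how="inner")
    tab["age_oldest"] = tab["age_S"]
    tab = tab[tab["age_oldest"] <= max_age_oldest].reset_index(drop=True)
    if tab.empty:
        raise FitError("no bouts joined to covariates within the age window")
    model = FoodAllocationModel(**params)
    model.fit(
        tab[["biomass_g", "log_peck_ratio", "age_oldest", "brood_id"]],
        tab["recipient_rank"].to_numpy(),
    )
    model.training_table_ = tab
    return model


def predict_allocation_shares(
    model: FoodAllocationModel,
    grid: pd.DataFrame,
    at_age_oldest: float | None = None,
) -> pd.DataFrame:
    """Shares along a covariate grid, other covariates held at training means.

    ``grid`` supplies any subset of ``biomass_g``, ``log_peck_ratio``,
    ``age_oldest``; missing covariates are filled with their training-data
    means (or ``at_age_oldest`` for the age).  Returns the grid with S, M, J
    share columns summing to 1 on every row.
    """
    check_is_fitted(model, "classes_")
    tab = getattr(model, "training_table_", None)
    grid = grid.copy()
    for name in _COVARIATES:
        if name not in grid.columns:
            if name == "age_oldest" and at_age_oldest is not None:
                grid[name] = at_age_oldest
            elif tab is not None:
                grid[name] = tab[name].mean()
            else:
                raise ValueError(f"grid missing column {name!r}")
    shares = model.predict_shares(grid)
    return pd.concat([grid.reset_index(drop=True),
                      shares.reset_index(drop=True)], axis=1)
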