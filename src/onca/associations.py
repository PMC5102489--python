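"""Cross-site statistical linking of suitability, prey and habitat structure.

Pairwise product–moment correlations with uncorrected two-sided p-values
(a rank-based option behind a flag, and Holm adjustment available but off
by default, matching the uncorrected-p reporting convention of field
studies); an ensemble-regression association between SDM suitability and
structure variables, scored as the correlation between out-of-bag random
forest predictions and the observed response; and the priority-area overlay
mask (low human footprint ∧ high canopy roughness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import RandomForestRegressor

from .errors import InconsistentInputError, InvalidArgumentError, NoDataError


@dataclass
class AssociationResult:
    """A correlation-style association between variables across sites."""

    variables: str
    r: float
    p_uncorrected: float
    n: int
    method: str
    dropped: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise InvalidArgumentError("r outside [-1, 1]")
        if self.n < 3:
            raise InvalidArgumentError("need at least 3 sites")


def correlate(x, y, method: str = "pearson",
              label: str = "x~y") -> AssociationResult:
    """Product–moment (default) or rank correlation with uncorrected p.

    Pairs with missing values are dropped (count recorded); zero variance in
    either vector is an error rather than a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InconsistentInputError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int(np.count_nonzero(~keep))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise NoDataError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NoDataError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = pearsonr(x, y)
    elif method == "spearman":
        r, p = spearmanr(x, y)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return AssociationResult(variables=label, r=float(r), p_uncorrected=float(p),
                             n=int(x.size), method=f"pairwise-{method}",
                             dropped=dropped)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (opt-in; default reporting is uncorrected)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def rf_association(response, predictors: pd.DataFrame, seed: int = 0,
                   trees: int = 500, label: str = "rf",
                   predictor_cap: int = 10) -> AssociationResult:
    """Random-forest association between a response and site predictors.

    Fits a regression forest and reports r = correlation between out-of-bag
    predictions and the observed response, with the p-value of that
    correlation. Categorical predictors must arrive as class indicators
    (use :func:`encode_predictors`). Deterministic given seed and tree count.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.to_numpy(dtype=float)
    if len(predictors.columns) < 1:
        raise InvalidArgumentError("need at least one predictor")
    if y.size < 10:
        raise InvalidArgumentError("need at least 10 sites")
    if y.size < 10 * 2 and X.shape[1] > predictor_cap:
        import warnings
        warnings.warn("more predictors than the cap with few sites: "
                      "degraded fit likely")
    rf = RandomForestRegressor(n_estimators=trees, oob_score=True,
                               random_state=seed, bootstrap=True)
    rf.fit(X, y)
    oob = rf.oob_prediction_
    if np.std(oob) == 0:
        return AssociationResult(variables=label, r=0.0, p_uncorrected=1.0,
                                 n=int(y.size), method="ensemble-regression")
    r, p = pearsonr(oob, y)
    return AssociationResult(variables=label, r=float(r), p_uncorrected=float(p),
                             n=int(y.size), method="ensemble-regression")


def encode_predictors(frame: pd.DataFrame,
                      categorical: tuple[str, ...] = ("modal_geology",),
                      ) -> pd.DataFrame:
    """One-hot encode the categorical columns, passing the rest through."""
    cat = [c for c in categorical if c in frame.columns]
    return pd.get_dummies(frame, columns=cat, dtype=float)


def threshold_overlay(suitability: np.ndarray | None, hfi: np.ndarray,
                      roughness: np.ndarray, hfi_cut: float = 15.0,
                      rough_cut: float = 12.0,
                      validity: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, float]:
    """Priority mask: cells with HFI < cut and canopy roughness > cut.

    Returns ``(mask, fraction)`` where fraction is the share of valid,
    non-NaN cells that satisfy both conditions. ``suitability`` is accepted
    for raster-alignment checking but does not enter the rule.
    """
    hfi = np.asarray(hfi, dtype=float)
    roughness = np.asarray(roughness, dtype=float)
    if hfi.shape != roughness.shape or (
            suitability is not None and np.shape(suitability) != hfi.shape):
        raise InconsistentInputError("rasters are not aligned")
    if validity is None:
        validity = np.ones(hfi.shape, dtype=bool)
    elif validity.shape != hfi.shape:
        raise InconsistentInputError("validity mask is not aligned")
    ok = validity & ~np.isnan(hfi) & ~np.isnan(roughness)
    mask = ok & (hfi < hfi_cut) & (roughness > rough_cut)
    denom = int(np.count_nonzero(ok))
    fraction = float(np.count_nonzero(mask)) / denom if denom else 0.0
    return mask, fraction


def association_table(results: list[AssociationResult],
                      holm: bool = False) -> pd.DataFrame:
    """Tidy frame of association results; optional Holm-adjusted column."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if holm and len(df):
        df["p_holm"] = holm_adjust(df["p_uncorrected"].to_numpy())
    return df
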