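"""Presence-only maximum-entropy habitat suitability modelling.

The model is the Gibbs distribution raw(x) ∝ exp(Σ_j λ_j f_j(x)) over
background cells, fitted by maximizing the β-regularized presence
log-likelihood

    (1/m) Σ_i λ·f(x_i) − log Z(λ) − Σ_j β_j |λ_j| ,

whose optimum satisfies |E_raw[f_j] − presence mean of f_j| ≤ β_j for every
feature. Features are linear and quadratic transforms of [0,1]-rescaled
continuous layers plus one indicator per observed categorical class.
Suitability is reported through the entropy-based logistic transform
e^H·raw/(1 + e^H·raw) (implicit prevalence 0.5). Evaluation is rank-based
AUC against background, with significance calibrated by a 99-replicate
random-presence null model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .errors import (InconsistentInputError, InvalidArgumentError,
                     ModelStateError, NoDataError)
from .landscape import LayerStack

log = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = ("rainfall", "altitude", "footprint")
DEFAULT_CATEGORICAL = ("vegetation", "biogeo")

#: Floor on the presence-sample feature s.d. used in the default
#: regularization β_j = reg · max(s_j, SD_FLOOR)/√m, so β stays positive for
#: degenerate presence samples. reg=0 disables regularization exactly.
SD_FLOOR = 0.05


@dataclass
class FeatureSchema:
    """Everything needed to rebuild the feature matrix on a new stack."""

    continuous: tuple[str, ...]
    categorical: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]          # layer -> (min, max) at training
    classes: dict[str, tuple[int, ...]]             # layer -> observed class ids
    names: tuple[str, ...]


@dataclass
class FeatureMatrix:
    """Per-cell feature values over the valid cells of a stack.

    ``matrix`` has one row per valid cell (row-major flat order of the grid)
    and one column per feature; ``cell_index`` maps rows to flat grid
    indices. Continuous features lie in [0,1]; indicators in {0,1}.
    """

    matrix: np.ndarray
    names: tuple[str, ...]
    cell_index: np.ndarray
    schema: FeatureSchema
    shape: tuple[int, int]
    sampling_rows: np.ndarray  # row positions whose cells carry observer effort


def build_features(stack: LayerStack,
                   continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
                   categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
                   schema: FeatureSchema | None = None) -> FeatureMatrix:
    """Build linear+quadratic and class-indicator features over valid cells.

    With ``schema`` given, the training-time rescaling ranges and class lists
    are reused so a fitted model can be projected onto a new stack; classes
    unseen at training yield all-zero indicator rows.
    """
    valid = stack.validity
    if not valid.any():
        raise NoDataError("stack has no valid cells")
    cell_index = np.flatnonzero(valid.ravel())
    cols: list[np.ndarray] = []
    names: list[str] = []
    ranges: dict[str, tuple[float, float]] = {}
    classes: dict[str, tuple[int, ...]] = {}

    for name in continuous:
        vals = stack.continuous[name].ravel()[cell_index].astype(float)
        if schema is None:
            lo, hi = float(vals.min()), float(vals.max())
        else:
            lo, hi = schema.ranges[name]
        if hi == lo:
            warnings.warn(f"layer {name!r} is constant over valid cells; "
                          "its features were dropped")
            log.warning("dropping constant layer %r", name)
            ranges[name] = (lo, hi)
            continue
        z = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
        cols += [z, z ** 2]
        names += [name, f"{name}^2"]
        ranges[name] = (lo, hi)

    for name in categorical:
        vals = stack.categorical[name].ravel()[cell_index]
        ids = (tuple(int(c) for c in np.unique(vals)) if schema is None
               else schema.classes[name])
        if schema is None and len(ids) < 2:
            warnings.warn(f"categorical layer {name!r} has a single class; "
                          "its indicators were dropped")
            classes[name] = ids
            continue
        for c in ids:
            cols.append((vals == c).astype(float))
            names.append(f"{name}={c}")
        classes[name] = ids

    if not cols:
        raise NoDataError("no non-constant features could be built")
    if schema is None:
        schema = FeatureSchema(continuous=tuple(continuous),
                               categorical=tuple(categorical),
                               ranges=ranges, classes=classes,
                               names=tuple(names))
    elif tuple(names) != schema.names:
        raise InconsistentInputError("rebuilt features do not match the schema")
    sampling_rows = np.flatnonzero(stack.sampling.ravel()[cell_index])
    return FeatureMatrix(matrix=np.column_stack(cols), names=tuple(names),
                         cell_index=cell_index, schema=schema,
                         shape=stack.shape, sampling_rows=sampling_rows)


@dataclass
class SuitabilityModel:
    """A fitted maxent model: weights, regularization, entropy, diagnostics."""

    lambdas: np.ndarray
    beta: np.ndarray
    entropy: float
    schema: FeatureSchema
    background_rows: np.ndarray
    log_z: float
    converged: bool
    n_iter: int
    final_change: float
    tol: float
    max_iter: int
    presence_means: np.ndarray
    train_rows: np.ndarray | None = None
    test_rows: np.ndarray | None = None
    replicates: list[np.ndarray] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.lambdas is not None

    def raw(self, features: np.ndarray) -> np.ndarray:
        """Gibbs density raw(x) = exp(λ·f(x) − log Z); sums to 1 over background."""
        return np.exp(features @ self.lambdas - self.log_z)

    def logistic(self, features: np.ndarray) -> np.ndarray:
        """Entropy-based logistic suitability in [0,1], increasing in raw."""
        s = features @ self.lambdas - self.log_z + self.entropy
        return 1.0 / (1.0 + np.exp(-s))


def default_beta(presence_features: np.ndarray, reg_multiplier: float) -> np.ndarray:
    """β_j = reg · max(s_j, SD_FLOOR)/√m with s_j the presence-sample s.d."""
    m = presence_features.shape[0]
    sd = presence_features.std(axis=0, ddof=1) if m > 1 else \
        np.zeros(presence_features.shape[1])
    return reg_multiplier * np.maximum(sd, SD_FLOOR) / np.sqrt(m)


def fit_maxent(features: FeatureMatrix, presence_rows: np.ndarray,
               background_rows: np.ndarray | None = None,
               reg_multiplier: float = 1.0, max_iter: int = 5000,
               tol: float = 1e-5, beta: np.ndarray | None = None,
               bootstrap_reps: int = 0, seed: int = 0) -> SuitabilityModel:
    """Fit the β-regularized maxent model by deterministic quasi-Newton ascent.

    ``presence_rows``/``background_rows`` index rows of ``features.matrix``;
    the background defaults to the sampling-mask rows (bias-restricted
    training). The L1 penalty is handled by splitting λ into positive and
    negative parts and running bound-constrained L-BFGS; iteration stops when
    the max weight update falls below ``tol`` or at ``max_iter``. Optional
    bootstrap replicates refit on presences resampled with replacement.
    """
    presence_rows = np.asarray(presence_rows)
    if presence_rows.size < 10:
        raise InvalidArgumentError("need at least 10 presence rows")
    if background_rows is None:
        background_rows = features.sampling_rows
    background_rows = np.asarray(background_rows)
    if not np.isin(presence_rows, background_rows).all():
        raise InconsistentInputError(
            "presence rows outside the background support")

    F_bg = features.matrix[background_rows]
    pres_mean = features.matrix[presence_rows].mean(axis=0)
    if beta is None:
        beta = default_beta(features.matrix[presence_rows], reg_multiplier)
    beta = np.asarray(beta, dtype=float)

    lambdas, info = _solve(F_bg, pres_mean, beta, max_iter, tol)
    log_z = float(logsumexp(F_bg @ lambdas))
    w = np.exp(F_bg @ lambdas - log_z)
    entropy = float(-(w * np.log(np.clip(w, 1e-300, None))).sum())

    model = SuitabilityModel(
        lambdas=lambdas, beta=beta, entropy=entropy, schema=features.schema,
        background_rows=background_rows, log_z=log_z,
        converged=info["converged"], n_iter=info["n_iter"],
        final_change=info["final_change"], tol=tol, max_iter=max_iter,
        presence_means=pres_mean)

    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        for _ in range(bootstrap_reps):
            boot = rng.choice(presence_rows, size=presence_rows.size, replace=True)
            bm = features.matrix[boot].mean(axis=0)
            bl, _ = _solve(F_bg, bm, beta, max_iter, tol)
            model.replicates.append(bl)
    return model


def _solve(F_bg: np.ndarray, pres_mean: np.ndarray, beta: np.ndarray,
           max_iter: int, tol: float) -> tuple[np.ndarray, dict]:
    """Minimize logZ(λ) − p̄·λ + β·(u+v) over λ = u − v, u,v ≥ 0."""
    n, j = F_bg.shape

    def objective(theta):
        lam = theta[:j] - theta[j:]
        s = F_bg @ lam
        lz = logsumexp(s)
        w = np.exp(s - lz)
        grad_lam = w @ F_bg - pres_mean
        f = lz - pres_mean @ lam + beta @ (theta[:j] + theta[j:])
        g = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return f, g

    last = {"theta": np.zeros(2 * j), "change": np.inf, "nit": 0}

    def cb(theta):
        last["change"] = float(np.max(np.abs(theta - last["theta"])))
        last["theta"] = theta.copy()
        last["nit"] += 1

    res = minimize(objective, np.zeros(2 * j), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * j), callback=cb,
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol,
                            "maxls": 50})
    lam = res.x[:j] - res.x[j:]
    converged = bool(res.success or last["change"] < tol)
    return lam, {"converged": converged, "n_iter": int(res.nit),
                 "final_change": last["change"]}


def split_presences(presence_rows: np.ndarray, seed: int,
                    train_frac: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform random 75/25 partition of presence cells."""
    rng = np.random.default_rng(seed)
    rows = np.asarray(presence_rows)
    perm = rng.permutation(rows.size)
    n_train = int(round(train_frac * rows.size))
    return rows[perm[:n_train]], rows[perm[n_train:]]


def logistic_output(model: SuitabilityModel, cell_features: np.ndarray,
                    background_features: np.ndarray | None = None) -> np.ndarray:
    """Logistic suitability of feature rows; bootstrap mean when replicates exist.

    ``background_features`` (the training-background feature rows) is only
    needed when the model carries bootstrap replicates, each of which has
    its own normalizer and entropy.
    """
    if model is None or model.lambdas is None:
        raise ModelStateError("model is not fitted")
    if not model.replicates:
        return model.logistic(cell_features)
    if background_features is None:
        raise InvalidArgumentError(
            "bootstrap-averaged output needs the background feature rows")
    out = model.logistic(cell_features)
    for lam in model.replicates:
        out = out + _logistic_for(lam, cell_features, background_features)
    return out / (1 + len(model.replicates))


def evaluate_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random background cell).

    Ties count 0.5; equals the normalized Mann–Whitney U statistic.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size < 1:
        raise NoDataError("empty test-presence set")
    if b.size < 2:
        raise NoDataError("need at least 2 background cells")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def fit_and_score(features: FeatureMatrix, presence_rows: np.ndarray,
                  background_rows: np.ndarray, seed: int,
                  train_frac: float = 0.75, **fit_kwargs,
                  ) -> tuple[SuitabilityModel, float]:
    """Split presences 75/25, fit on the training part, AUC on the test part."""
    train, test = split_presences(presence_rows, seed, train_frac)
    if test.size == 0:
        train = test = np.asarray(presence_rows)
    model = fit_maxent(features, train, background_rows, **fit_kwargs)
    model.train_rows, model.test_rows = train, test
    scores = features.matrix @ model.lambdas
    auc = evaluate_auc(scores[test], scores[background_rows])
    return model, auc


@dataclass
class NullModelResult:
    """Observed AUC against 99 models fitted to random presences."""

    observed_auc: float
    null_aucs: np.ndarray
    threshold: float          # 95th-ranked null AUC (1-based ascending)
    significant: bool
    p_value: float            # (1 + #{null >= observed}) / (1 + n_reps)
    n_failed: int = 0

    @property
    def degraded(self) -> bool:
        return self.n_failed > 0


def null_model_test(features: FeatureMatrix, observed_auc: float,
                    n_presences: int, background_rows: np.ndarray,
                    seed: int, n_reps: int = 99, rank_index: int = 95,
                    **fit_kwargs) -> NullModelResult:
    """Random-presence null-model significance test for an SDM.

    Each of the ``n_reps`` (default 99) replicates draws ``n_presences``
    cells uniformly without replacement from the study mask, runs the same
    split-fit-AUC protocol as the observed model, and records the AUC. The
    observed model is significant (p < 0.05) when its AUC exceeds the
    95th-ranked null AUC.
    """
    background_rows = np.asarray(background_rows)
    if n_presences > background_rows.size:
        raise InvalidArgumentError("more presences requested than study cells")
    rng = np.random.default_rng(seed)
    aucs, failed = [], 0
    for _ in range(n_reps):
        pres = rng.choice(background_rows, size=n_presences, replace=False)
        try:
            _, auc = fit_and_score(features, pres, background_rows,
                                   seed=int(rng.integers(2 ** 31)), **fit_kwargs)
            aucs.append(auc)
        except Exception:       # a failed replicate degrades, not aborts
            failed += 1
    null_aucs = np.sort(np.asarray(aucs))
    if null_aucs.size == 0:
        raise NoDataError("all null replicates failed")
    k = min(rank_index, null_aucs.size) - 1
    threshold = float(null_aucs[k])
    p = (1.0 + np.count_nonzero(null_aucs >= observed_auc)) / (1.0 + n_reps)
    return NullModelResult(observed_auc=float(observed_auc), null_aucs=null_aucs,
                           threshold=threshold,
                           significant=bool(observed_auc > threshold),
                           p_value=float(p), n_failed=failed)


def gain(model: SuitabilityModel, features: FeatureMatrix,
         presence_rows: np.ndarray) -> float:
    """Regularized log-likelihood improvement over uniform, per presence."""
    F = features.matrix
    n_bg = model.background_rows.size
    ll = float((F[presence_rows] @ model.lambdas).mean() - model.log_z)
    penalty = float(model.beta @ np.abs(model.lambdas))
    return ll - penalty + np.log(n_bg)


def jackknife_importance(features: FeatureMatrix, presence_rows: np.ndarray,
                         background_rows: np.ndarray | None = None,
                         test_rows: np.ndarray | None = None,
                         **fit_kwargs) -> pd.DataFrame:
    """Leave-one-variable-out / single-variable importance.

    For each environmental variable, refit using only that variable's
    features and using all but that variable's features; report training
    gain and AUC for both. With a single variable the "without" columns are
    flagged NaN.
    """
    schema = features.schema
    variables = [v for v in schema.continuous
                 if any(n == v or n == f"{v}^2" for n in features.names)]
    variables += [v for v in schema.categorical
                  if any(n.startswith(f"{v}=") for n in features.names)]
    if len(variables) < 2:
        warnings.warn("jackknife with a single variable: 'without' runs undefined")
    if background_rows is None:
        background_rows = features.sampling_rows
    if test_rows is None:
        test_rows = presence_rows

    def _cols(var):
        return np.array([i for i, n in enumerate(features.names)
                         if n == var or n == f"{var}^2" or n.startswith(f"{var}=")])

    def _run(col_idx):
        sub = FeatureMatrix(matrix=features.matrix[:, col_idx],
                            names=tuple(features.names[i] for i in col_idx),
                            cell_index=features.cell_index, schema=schema,
                            shape=features.shape,
                            sampling_rows=features.sampling_rows)
        m = fit_maxent(sub, presence_rows, background_rows, **fit_kwargs)
        scores = sub.matrix @ m.lambdas
        return (gain(m, sub, presence_rows),
                evaluate_auc(scores[test_rows], scores[background_rows]))

    rows = []
    all_idx = np.arange(len(features.names))
    for var in variables:
        cols = _cols(var)
        g_alone, a_alone = _run(cols)
        if len(variables) > 1:
            rest = np.setdiff1d(all_idx, cols)
            g_without, a_without = _run(rest)
        else:
            g_without = a_without = np.nan
        rows.append((var, g_alone, g_without, a_alone, a_without))
    return pd.DataFrame(rows, columns=["variable", "gain_alone", "gain_without",
                                       "auc_alone", "auc_without"])


def project(model: SuitabilityModel, stack: LayerStack,
            features: FeatureMatrix | None = None) -> np.ndarray:
    """Project logistic suitability onto a stack sharing the training schema.

    Returns a (rows, cols) array, NaN outside the validity mask. When
    bootstrap replicates exist the reported suitability is the replicate
    mean (each replicate scored with its own normalizer and entropy over the
    training background).
    """
    if model is None or model.lambdas is None:
        raise ModelStateError("model is not fitted")
    if features is None:
        features = build_features(stack, model.schema.continuous,
                                  model.schema.categorical, schema=model.schema)
    out = np.full(stack.rows * stack.cols, np.nan)
    if features.cell_index.size:
        F = features.matrix
        if model.replicates:
            acc = np.zeros(F.shape[0])
            for lam in [model.lambdas] + model.replicates:
                acc += _logistic_for(lam, F, F[_safe_bg(model, F)])
            out[features.cell_index] = acc / (1 + len(model.replicates))
        else:
            out[features.cell_index] = model.logistic(F)
    return out.reshape(stack.shape)


def _safe_bg(model: SuitabilityModel, F: np.ndarray) -> np.ndarray:
    bg = model.background_rows
    return bg[bg < F.shape[0]] if bg.max(initial=0) >= F.shape[0] else bg


def _logistic_for(lam: np.ndarray, F: np.ndarray, F_bg: np.ndarray) -> np.ndarray:
    lz = float(logsumexp(F_bg @ lam))
    w = np.exp(F_bg @ lam - lz)
    h = float(-(w * np.log(np.clip(w, 1e-300, None))).sum())
    s = F @ lam - lz + h
    return 1.0 / (1.0 + np.exp(-s))
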