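"""Predictive models of dry mass and fruit number from descriptor tables.

Model families: ordinary least squares (``linear``), per-predictor
second-order polynomials without cross-terms (``quadratic``), and L2/L1
penalized regressions (``ridge``/``lasso``, predictors standardized
internally, coefficients reported on the original scale).  Prediction
accuracy is assessed by the cross-validation protocol used for trait
prediction in high-throughput phenotyping: for each of ``n_permutations``
random permutations, a training set of a given size and a disjoint holdout
set are drawn, the model is fitted on the training set, and accuracy is the
squared Pearson correlation (r^2) between observed and predicted values on
the holdout — note this differs from 1 - SSE/SST for biased predictions.

Two fitted reference equations ship with the package:

    rosette dry mass (g) = -0.00133 + 0.00134 * RA + 0.00274 * Circ
    fruit number         = 0.181 * n_actual_junctions
                           + 0.003 * n_slab_pixels
                           + 0.226 * n_triple_points

with RA in cm^2 and Circ dimensionless; the nine-descriptor skeleton table
uses the column names of :mod:`phenorosette.skeleton`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV

logger = logging.getLogger(__name__)

__all__ = [
    "TraitModel",
    "CVConfig",
    "CVResult",
    "fit",
    "predict",
    "cross_validate",
    "stepwise_select",
    "reference_dry_mass_model",
    "reference_fruit_model",
]

FAMILIES = ("linear", "quadratic", "ridge", "lasso")


@dataclass
class TraitModel:
    """A fitted (or reference) predictive model.

    ``coefficients`` maps predictor names to slopes; the quadratic family
    additionally stores ``<name>^2`` entries.  ``predictor_order`` lists the
    base predictors in design order.
    """

    family: str
    intercept: float
    coefficients: dict[str, float]
    penalty: float = 0.0
    predictor_order: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.family,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "penalty": self.penalty,
            "predictor_order": self.predictor_order,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TraitModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith(
            "{"
        ):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class CVConfig:
    """Cross-validation sweep: training sizes, permutations, holdout."""

    training_sizes: Sequence[int]
    n_permutations: int = 100
    holdout_size: int = 100
    seed: int = 0


@dataclass
class CVResult:
    """Mean r^2 and 95% CI per (family, training_size), across
    permutations; ``table`` is a tidy DataFrame."""

    table: pd.DataFrame

    def mean_r2(self, family: str, training_size: int) -> float:
        t = self.table
        row = t[(t.family == family) & (t.training_size == training_size)]
        if row.empty:
            raise KeyError((family, training_size))
        return float(row.mean_r2.iloc[0])


def _check_design(X: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in X.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    arr = X[list(columns)].to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("design matrix contains missing values")
    return arr


def _quadratic_expand(
    arr: np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols, out_names = [], []
    for j, name in enumerate(names):
        cols.append(arr[:, j])
        out_names.append(name)
        cols.append(arr[:, j] ** 2)
        out_names.append(f"{name}^2")
    return np.column_stack(cols), out_names


def _aliased_columns(design: np.ndarray, names: Sequence[str]) -> list[int]:
    """Indices of columns made redundant by earlier columns (pivoted QR on
    the design including the intercept; earlier columns win)."""
    n = design.shape[0]
    full = np.column_stack([np.ones(n), design])
    # incremental rank: column j is aliased if adding it does not raise rank
    aliased = []
    kept = full[:, :1]
    for j in range(design.shape[1]):
        cand = np.column_stack([kept, full[:, j + 1]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            aliased.append(j)
    return aliased


def fit(
    X: pd.DataFrame,
    y: Sequence[float],
    family: str = "linear",
    penalty: Optional[float] = None,
    predictors: Optional[Sequence[str]] = None,
    on_collinear: str = "error",
) -> TraitModel:
    """Fit a trait model of the given family.

    linear/quadratic use least squares; ridge/lasso standardize predictors
    internally, select the penalty by inner 5-fold CV over a log-spaced
    grid when not given, and report coefficients on the original scale.

    Rank-deficient least-squares designs raise a ValueError naming the
    collinear columns, unless ``on_collinear="drop"``, in which case the
    aliased columns are dropped with a log message and zero coefficients
    (the convention of pivoting least-squares implementations).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if predictors is None:
        predictors = [c for c in X.columns]
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 rows to fit")
    arr = _check_design(X, predictors)
    names = list(predictors)

    if family == "quadratic":
        design, design_names = _quadratic_expand(arr, names)
    else:
        design, design_names = arr, list(names)

    if family in ("linear", "quadratic"):
        aliased = _aliased_columns(design, design_names)
        if aliased:
            bad = [design_names[j] for j in aliased]
            if on_collinear == "error":
                raise ValueError(f"collinear predictor columns: {bad}")
            logger.info("dropping aliased columns: %s", bad)
            keep = [j for j in range(design.shape[1]) if j not in aliased]
            design_fit = design[:, keep]
            kept_names = [design_names[j] for j in keep]
        else:
            design_fit, kept_names = design, design_names
        A = np.column_stack([np.ones(len(y)), design_fit])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        coefs = dict.fromkeys(design_names, 0.0)
        coefs.update(dict(zip(kept_names, beta[1:].tolist())))
        return TraitModel(
            family=family,
            intercept=float(beta[0]),
            coefficients={k: float(v) for k, v in coefs.items()},
            predictor_order=names,
        )

    # penalized families: standardize, fit, back-transform
    mu = design.mean(axis=0)
    sd = design.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (design - mu) / sd_safe
    if penalty is None:
        grid = np.logspace(-4, 3, 30)
        if family == "ridge":
            est = RidgeCV(alphas=grid, cv=5).fit(Z, y)
            penalty = float(est.alpha_)
        else:
            est = LassoCV(alphas=grid, cv=5, max_iter=50000).fit(Z, y)
            penalty = float(est.alpha_)
    if family == "ridge":
        est = Ridge(alpha=penalty).fit(Z, y)
    else:
        est = Lasso(alpha=penalty, max_iter=50000).fit(Z, y)
    slopes = est.coef_ / sd_safe
    slopes[sd == 0] = 0.0
    intercept = float(est.intercept_ - np.sum(slopes * mu))
    return TraitModel(
        family=family,
        intercept=intercept,
        coefficients={
            k: float(v) for k, v in zip(design_names, slopes.tolist())
        },
        penalty=float(penalty),
        predictor_order=names,
    )


def predict(model: TraitModel, X: pd.DataFrame) -> np.ndarray:
    """Apply a trait model: intercept + sum(coefficient * predictor),
    with squared terms for the quadratic family.  Raises if a predictor
    column is missing."""
    base = model.predictor_order or [
        c for c in model.coefficients if not c.endswith("^2")
    ]
    arr = _check_design(X, base)
    out = np.full(len(X), model.intercept, dtype=float)
    for j, name in enumerate(base):
        out += model.coefficients.get(name, 0.0) * arr[:, j]
        sq = model.coefficients.get(f"{name}^2")
        if sq is not None:
            out += sq * arr[:, j] ** 2
    return out


def _pearson_r2(obs: np.ndarray, pred: np.ndarray) -> Optional[float]:
    if np.std(obs) == 0:
        return None  # caller skips the permutation
    if np.std(pred) == 0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r**2)


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    families: Sequence[str] = ("linear",),
    cfg: CVConfig = None,
) -> CVResult:
    """Cross-validate model families over a grid of training sizes.

    Per permutation the rows are shuffled once; the first ``s`` rows train,
    the last ``holdout_size`` rows are the holdout (disjoint by the size
    constraint).  r^2 = squared Pearson correlation of observed vs
    predicted on the holdout.  Aggregates mean and 2.5/97.5 percentiles
    across permutations; fully reproducible from ``cfg.seed``.
    """
    if cfg is None:
        raise ValueError("a CVConfig is required")
    y = np.asarray(y, dtype=float)
    n = len(y)
    max_size = max(cfg.training_sizes)
    if max_size + cfg.holdout_size > n:
        raise ValueError(
            f"training size {max_size} + holdout {cfg.holdout_size} "
            f"exceeds {n} rows"
        )
    rng = np.random.default_rng(cfg.seed)
    rows = []
    scores: dict[tuple[str, int], list[float]] = {
        (f, s): [] for f in families for s in cfg.training_sizes
    }
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(n)
        holdout = perm[n - cfg.holdout_size :]
        y_hold = y[holdout]
        X_hold = X.iloc[holdout]
        if np.std(y_hold) == 0:
            logger.info("holdout with zero variance in y; permutation skipped")
            continue
        for s in cfg.training_sizes:
            train = perm[:s]
            for fam in families:
                model = fit(
                    X.iloc[train],
                    y[train],
                    family=fam,
                    on_collinear="drop",
                )
                r2 = _pearson_r2(y_hold, predict(model, X_hold))
                scores[(fam, s)].append(r2)
    for (fam, s), vals in scores.items():
        vals = np.asarray(vals, dtype=float)
        rows.append(
            {
                "family": fam,
                "training_size": s,
                "mean_r2": float(np.mean(vals)) if vals.size else np.nan,
                "ci_low": float(np.percentile(vals, 2.5))
                if vals.size
                else np.nan,
                "ci_high": float(np.percentile(vals, 97.5))
                if vals.size
                else np.nan,
                "n_permutations": int(vals.size),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["family", "training_size"], ignore_index=True
    )
    return CVResult(table=table)


def _aic(rss: float, n: int, k: int) -> float:
    # R's extractAIC scale: n*log(RSS/n) + 2*edf (constant terms dropped)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * k


def _ols_rss(design: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), design]) if design.size else np.ones(
        (len(y), 1)
    )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid)


def stepwise_select(X: pd.DataFrame, y: Sequence[float]) -> TraitModel:
    """Bidirectional stepwise AIC selection for a linear model.

    Starts from the full additive model; at each step evaluates every
    single-column drop and add in column order and takes the best
    AIC-lowering move, until no move improves.  The result never has a
    higher AIC than the full model.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    arr = _check_design(X, names)
    n = len(y)

    def aic_of(subset: list[str]) -> float:
        idx = [names.index(c) for c in subset]
        return _aic(_ols_rss(arr[:, idx], y), n, len(subset) + 1)

    current = list(names)
    current_aic = aic_of(current)
    while True:
        best_move, best_aic = None, current_aic
        for c in names:  # scan order = column order
            if c in current:
                cand = [x for x in current if x != c]
            else:
                cand = current + [c]
            a = aic_of(cand)
            if a < best_aic - 1e-12:
                best_move, best_aic = cand, a
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
    current = [c for c in names if c in current]
    if current:
        model = fit(X, y, family="linear", predictors=current)
    else:
        model = TraitModel(
            family="linear",
            intercept=float(np.mean(y)),
            coefficients={},
            predictor_order=[],
        )
    model.metadata["selected_by"] = "stepwise_aic"
    model.metadata["aic"] = current_aic
    return model


def reference_dry_mass_model() -> TraitModel:
    """The shipped rosette dry-mass equation (stepwise-selected linear
    model): DM = -0.00133 + 0.00134*RA + 0.00274*Circ."""
    return TraitModel(
        family="linear",
        intercept=-0.00133,
        coefficients={"RA": 0.00134, "Circ": 0.00274},
        predictor_order=["RA", "Circ"],
        metadata={
            "response": "rosette dry mass",
            "units": "g, assuming RA in cm^2 (coefficient magnitudes; the "
            "source protocol elsewhere reports mass in mg)",
        },
    )


def reference_fruit_model() -> TraitModel:
    """The shipped fruit-number equation (stepwise-selected linear model):
    fruits = 0.181*n_actual_junctions + 0.003*n_slab_pixels
    + 0.226*n_triple_points."""
    return TraitModel(
        family="linear",
        intercept=0.0,
        coefficients={
            "n_actual_junctions": 0.181,
            "n_slab_pixels": 0.003,
            "n_triple_points": 0.226,
        },
        predictor_order=[
            "n_actual_junctions",
            "n_slab_pixels",
            "n_triple_points",
        ],
        metadata={"response": "fruit number", "units": "fruits"},
    )
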