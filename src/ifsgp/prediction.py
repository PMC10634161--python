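"""Random-forest regression for genomic prediction, plus accuracy metrics.

The forest is a bagged regression forest with mtry = floor(sqrt(p_used))
candidate features per split, 500 trees and a minimal node size of 5 by
default; mtry is recomputed from the number of SNPs actually supplied at
fit time, so it tracks the growing subsets of an incremental sweep.  The
engine is scikit-learn's RandomForestRegressor; this module fixes the
contract (bootstrap resampling per tree, prediction = mean over trees),
not the engine.

Accuracy is the coefficient of determination R^2 = 1 - SS_res/SS_tot
computed on held-out pairs.  It can be negative when predictions are worse
than the observed mean, and negative values propagate unclipped through
the pipeline.  Pearson's r is offered as an alternative reporting metric
only; R^2 equals r^2 only for unconstrained linear regression fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._util import IfsgpError, UndefinedMetricError
from .plink_io import GenotypeMatrix, PhenotypeVector


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    min_node_size follows the convention that a node with at most
    min_node_size training samples becomes terminal; mtry=None means
    floor(sqrt(p_used)) recomputed at each fit.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    seed: int = 0
    n_threads: int = 1

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            if self.mtry > n_features:
                raise IfsgpError(
                    f"mtry={self.mtry} exceeds number of features ({n_features})"
                )
            return self.mtry
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class PredictorHandle:
    """A fitted forest bound to the SNP columns it was trained on."""

    model: RandomForestRegressor
    feature_idx: np.ndarray


def _as_matrix(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosages
    return np.asarray(genotypes)


def fit_forest(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    feature_idx: np.ndarray,
    train_idx: np.ndarray,
    config: ForestConfig,
) -> PredictorHandle:
    """Train a regression forest on the selected SNP columns of the training rows.

    Deterministic for a fixed seed and thread count; across thread counts
    only statistical equivalence is guaranteed.
    """
    feature_idx = np.asarray(feature_idx)
    train_idx = np.asarray(train_idx)
    if feature_idx.size == 0:
        raise IfsgpError("feature_idx must be non-empty")
    x = _as_matrix(genotypes)[np.ix_(train_idx, feature_idx)].astype(np.float32)
    y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype)
    y = y[train_idx]

    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.resolved_mtry(feature_idx.size),
        # a node with <= min_node_size samples is terminal
        min_samples_split=config.min_node_size + 1,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=config.n_threads,
    )
    model.fit(x, y)
    return PredictorHandle(model=model, feature_idx=feature_idx)


def predict(
    handle: PredictorHandle,
    genotypes: GenotypeMatrix | np.ndarray,
    idx: np.ndarray,
) -> np.ndarray:
    """Predict phenotypes for the requested individuals (one value each)."""
    idx = np.asarray(idx)
    x = _as_matrix(genotypes)[np.ix_(idx, handle.feature_idx)].astype(np.float32)
    if x.shape[1] != handle.model.n_features_in_:
        raise IfsgpError("feature set differs from the one used at fit time")
    return handle.model.predict(x)


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; negative values allowed."""
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise IfsgpError("observed and predicted must be 1-D vectors of equal length")
    if len(observed) < 2:
        raise IfsgpError("need at least two pairs to compute R^2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: observed values have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Sample Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise IfsgpError("observed and predicted must be 1-D vectors of equal length")
    oc = observed - observed.mean()
    pc = predicted - predicted.mean()
    denom = math.sqrt(float(oc @ oc) * float(pc @ pc))
    if denom == 0.0:
        raise UndefinedMetricError("Pearson r undefined for constant input")
    return float(oc @ pc) / denom
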