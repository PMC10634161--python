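"""The incremental feature selection sweep.

For every cross-validation repetition and fold, a fresh association scan is
run on the training individuals only and the SNPs re-ranked; models are
then trained on growing prefixes of that ranking according to a step
schedule whose step size increases at set intervals (1 until 100, 5 until
500, 10 until 1000, ...).  The test fold contributes to neither the
ranking nor the fit — feature selection on the full data would inflate the
apparent accuracy.

Per repetition, out-of-fold predictions from all folds are pooled and a
single R^2 is computed per SNP count; the curve stores the mean and the
standard error of the mean over repetitions.  The final schedule point
uses all SNPs and serves as the full-model baseline.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._util import IfsgpError, derive_seed
from .association import gwas_scan, rank_snps
from .plink_io import GenotypeMatrix, PhenotypeVector
from .prediction import ForestConfig, fit_forest, pearson_r, predict, r_squared

logger = logging.getLogger(__name__)

#: (upper_bound, step_size) regimes of the default schedule; the first three
#: are fixed by the protocol, the extrapolation beyond 1000 keeps roughly
#: geometric spacing. None = unbounded final regime.
DEFAULT_BREAKPOINTS: list[tuple[int | None, int]] = [
    (100, 1),
    (500, 5),
    (1000, 10),
    (5000, 50),
    (10000, 100),
    (50000, 500),
    (100000, 1000),
    (None, 5000),
]

#: Coarse regimes for smoke runs and the test profile: ~25 schedule points
#: up to a few thousand SNPs instead of several hundred, at the cost of a
#: less finely resolved accuracy curve.
COARSE_BREAKPOINTS: list[tuple[int | None, int]] = [
    (10, 1),
    (50, 5),
    (100, 25),
    (500, 100),
    (2000, 500),
    (10000, 2000),
    (None, 20000),
]


@dataclass
class StepSchedule:
    """Strictly increasing SNP counts to sweep, from 1 up to p."""

    snp_counts: np.ndarray
    breakpoints: list[tuple[int | None, int]]

    def __len__(self) -> int:
        return len(self.snp_counts)


@dataclass
class CvPlan:
    """Per-repetition fold assignments for repeated k-fold cross-validation."""

    n_folds: int
    n_repetitions: int
    assignments: np.ndarray  # (n_repetitions, n_individuals) fold labels
    seed: int

    def fold_indices(self, repetition: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one repetition/fold."""
        labels = self.assignments[repetition]
        test = np.flatnonzero(labels == fold)
        train = np.flatnonzero(labels != fold)
        return train, test


@dataclass
class IfsCurve:
    """Accuracy as a function of the number of top-ranked SNPs used."""

    snp_counts: np.ndarray
    mean_r2: np.ndarray
    se_r2: np.ndarray
    per_repetition_r2: np.ndarray  # (n_counts, n_repetitions)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "n_snps": self.snp_counts,
                "mean_r2": self.mean_r2,
                "se_r2": self.se_r2,
            }
        )
        for rep in range(self.per_repetition_r2.shape[1]):
            frame[f"rep{rep + 1}_r2"] = self.per_repetition_r2[:, rep]
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IfsCurve":
        frame = pd.read_csv(path, sep="\t")
        rep_cols = [c for c in frame.columns if c.startswith("rep")]
        return cls(
            snp_counts=frame["n_snps"].to_numpy(np.int64),
            mean_r2=frame["mean_r2"].to_numpy(),
            se_r2=frame["se_r2"].to_numpy(),
            per_repetition_r2=frame[rep_cols].to_numpy(),
        )


def build_schedule(
    p: int, breakpoints: list[tuple[int | None, int]] | None = None
) -> StepSchedule:
    """Construct the SNP-count schedule for p total SNPs.

    Counts start at 1 and advance by each regime's step up to its bound
    (capped at p); p is appended if not already reached, so the sweep
    always ends with the full-SNP model.
    """
    if p < 1:
        raise IfsgpError(f"need at least one SNP, got p={p}")
    regimes = DEFAULT_BREAKPOINTS if breakpoints is None else breakpoints
    last_bound = 0
    for bound, step in regimes:
        if step < 1:
            raise IfsgpError("step sizes must be positive")
        if bound is not None:
            if bound <= last_bound:
                raise IfsgpError("breakpoint bounds must be increasing")
            last_bound = bound

    counts: list[int] = []
    current = 0
    for bound, step in regimes:
        limit = p if bound is None else min(bound, p)
        while current + step <= limit:
            current += step
            counts.append(current)
        if current >= p:
            break
    if not counts or counts[-1] != p:
        counts.append(p)
    return StepSchedule(np.asarray(counts, dtype=np.int64), list(regimes))


def make_cv_plan(
    n_individuals: int, n_folds: int = 5, n_repetitions: int = 10, seed: int = 0
) -> CvPlan:
    """Randomly reorder individuals each repetition and deal them into folds.

    Within each repetition the folds partition all individuals and sizes
    differ by at most one.
    """
    if n_individuals < n_folds:
        raise IfsgpError("fewer individuals than folds")
    assignments = np.empty((n_repetitions, n_individuals), dtype=np.int64)
    for rep in range(n_repetitions):
        rng = np.random.default_rng(derive_seed(seed, 1, rep))
        order = rng.permutation(n_individuals)
        labels = np.arange(n_individuals) % n_folds
        assignments[rep, order] = labels
    return CvPlan(n_folds, n_repetitions, assignments, seed)


def run_ifs(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    schedule: StepSchedule,
    plan: CvPlan,
    forest: ForestConfig,
    metric: str = "r2",
    pooled: bool = True,
    on_fit: Callable[[int, int, int, np.ndarray, np.ndarray], None] | None = None,
) -> IfsCurve:
    """Run the leakage-safe repeated-CV sweep and return the accuracy curve.

    ``metric`` selects the accuracy measure ('r2' or Pearson 'r').  With
    ``pooled`` (default) one accuracy value per repetition is computed from
    the pooled out-of-fold predictions; otherwise per-fold values are
    averaged.  ``on_fit(rep, fold, n_snps, train_idx, test_idx)`` is an
    audit hook invoked before every forest fit.
    """
    if metric not in ("r2", "r"):
        raise IfsgpError("metric must be 'r2' or 'r'")
    score = r_squared if metric == "r2" else pearson_r
    n = genotypes.n_individuals
    if plan.assignments.shape[1] != n:
        raise IfsgpError("CV plan was built for a different number of individuals")
    if schedule.snp_counts[-1] > genotypes.n_snps:
        raise IfsgpError("schedule exceeds the number of SNPs")

    n_counts = len(schedule)
    per_rep = np.empty((n_counts, plan.n_repetitions))
    n_models = 0
    t_start = time.perf_counter()

    for rep in range(plan.n_repetitions):
        pooled_pred = np.empty((n_counts, n)) if pooled else None
        fold_scores = np.empty((n_counts, plan.n_folds)) if not pooled else None
        for fold in range(plan.n_folds):
            train_idx, test_idx = plan.fold_indices(rep, fold)
            # ranking depends only on the training fold, not on the SNP
            # count, so compute it once per (repetition, fold)
            ranking = rank_snps(gwas_scan(genotypes, phenotype, train_idx))
            for step, n_snps in enumerate(schedule.snp_counts):
                if on_fit is not None:
                    on_fit(rep, fold, int(n_snps), train_idx, test_idx)
                cfg = ForestConfig(
                    n_trees=forest.n_trees,
                    mtry=forest.mtry,
                    min_node_size=forest.min_node_size,
                    seed=derive_seed(forest.seed, 2, rep, fold, step),
                    n_threads=forest.n_threads,
                )
                handle = fit_forest(
                    genotypes, phenotype, ranking.top(int(n_snps)), train_idx, cfg
                )
                pred = predict(handle, genotypes, test_idx)
                n_models += 1
                if pooled:
                    pooled_pred[step, test_idx] = pred
                else:
                    fold_scores[step, fold] = score(
                        phenotype.values[test_idx], pred
                    )
        if pooled:
            for step in range(n_counts):
                per_rep[step, rep] = score(phenotype.values, pooled_pred[step])
        else:
            per_rep[:, rep] = fold_scores.mean(axis=1)
        logger.info(
            "IFS repetition %d/%d done (%.1fs elapsed, %d models fitted)",
            rep + 1,
            plan.n_repetitions,
            time.perf_counter() - t_start,
            n_models,
        )

    expected = n_counts * plan.n_folds * plan.n_repetitions
    logger.info("IFS sweep fitted %d models (expected %d)", n_models, expected)
    return IfsCurve(
        snp_counts=schedule.snp_counts.copy(),
        mean_r2=per_rep.mean(axis=1),
        se_r2=per_rep.std(axis=1, ddof=1) / np.sqrt(plan.n_repetitions)
        if plan.n_repetitions > 1
        else np.zeros(n_counts),
        per_repetition_r2=per_rep,
    )
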