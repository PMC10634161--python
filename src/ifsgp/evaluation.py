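"""The outer hold-out protocol: select on the training partition, report on held-out data.

The data are split once, 80%/20%, into a selection partition (phi) and a
hold-out partition (psi).  The incremental sweep — including every
association scan and forest fit — runs on phi only; the smoothed optimum
determines how many top SNPs to keep.  A fresh scan on all of phi then
fixes the final ranking, one forest is trained on phi with the selected
SNPs and one with all SNPs, and both are scored on psi.  The difference
between the two hold-out accuracies is the advantage of feature selection;
when the optimum is the full SNP set the selected-model entry is reported
as absent because it would duplicate the baseline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import IfsgpError, derive_seed
from .association import gwas_scan, rank_snps
from .ifs_core import (
    CvPlan,
    IfsCurve,
    StepSchedule,
    build_schedule,
    make_cv_plan,
    run_ifs,
)
from .plink_io import GenotypeMatrix, PhenotypeVector
from .prediction import ForestConfig, fit_forest, pearson_r, predict, r_squared
from .smoothing import SelectionResult, SmoothedCurve, select_optimum

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    The full profile reproduces the protocol defaults (500 trees, 5 folds,
    10 repetitions); the test profile trades precision for speed and is
    meant for smoke runs and continuous integration.
    """

    n_folds: int = 5
    n_repetitions: int = 10
    n_trees: int = 500
    min_node_size: int = 5
    mtry: int | None = None
    breakpoints: list[tuple[int | None, int]] | None = None
    metric: str = "r2"
    smooth_x: str = "log"
    bass: float = 0.0
    pooled: bool = True
    seed: int = 0
    n_threads: int = 1

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        defaults = dict(n_repetitions=3, n_trees=100)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class EvaluationReport:
    """Hold-out accuracies of the selected-SNP model and the all-SNP baseline."""

    n_individuals: int
    n_snps: int
    n_selected: int
    pct_selected: float
    r2_selected_psi: float | None
    r2_all_psi: float
    advantage: float | None
    use_all_snps: bool
    curve: IfsCurve
    selection: SelectionResult
    seeds: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_snps": self.n_snps,
            "n_selected": self.n_selected,
            "pct_selected": self.pct_selected,
            "r2_selected_psi": self.r2_selected_psi,
            "r2_all_psi": self.r2_all_psi,
            "advantage": self.advantage,
            "use_all_snps": self.use_all_snps,
            "seeds": self.seeds,
            "curve": {
                "snp_counts": self.curve.snp_counts.tolist(),
                "mean_r2": self.curve.mean_r2.tolist(),
                "se_r2": self.curve.se_r2.tolist(),
                "per_repetition_r2": self.curve.per_repetition_r2.tolist(),
            },
            "selection": {
                "optimal_count": self.selection.optimal_count,
                "optimal_smoothed_r2": self.selection.optimal_smoothed_r2,
                "use_all_snps": self.selection.use_all_snps,
                "selected_snp_ids": self.selection.selected_snp_ids,
                "smoothed_r2": self.selection.smoothed.smoothed_r2.tolist(),
                "span_used": self.selection.smoothed.span_used.tolist(),
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        curve = IfsCurve(
            snp_counts=np.asarray(d["curve"]["snp_counts"], dtype=np.int64),
            mean_r2=np.asarray(d["curve"]["mean_r2"]),
            se_r2=np.asarray(d["curve"]["se_r2"]),
            per_repetition_r2=np.asarray(d["curve"]["per_repetition_r2"]),
        )
        smoothed = SmoothedCurve(
            snp_counts=curve.snp_counts,
            smoothed_r2=np.asarray(d["selection"]["smoothed_r2"]),
            span_used=np.asarray(d["selection"]["span_used"]),
        )
        selection = SelectionResult(
            optimal_count=d["selection"]["optimal_count"],
            optimal_smoothed_r2=d["selection"]["optimal_smoothed_r2"],
            use_all_snps=d["selection"]["use_all_snps"],
            smoothed=smoothed,
            selected_snp_ids=d["selection"]["selected_snp_ids"],
        )
        return cls(
            n_individuals=d["n_individuals"],
            n_snps=d["n_snps"],
            n_selected=d["n_selected"],
            pct_selected=d["pct_selected"],
            r2_selected_psi=d["r2_selected_psi"],
            r2_all_psi=d["r2_all_psi"],
            advantage=d["advantage"],
            use_all_snps=d["use_all_snps"],
            curve=curve,
            selection=selection,
            seeds=d["seeds"],
        )


def split_phi_psi(n_individuals: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random 80%/20% split into selection (phi) and hold-out (psi) index sets.

    |phi| = round-half-up(0.8 n); both index arrays are sorted and together
    cover every individual exactly once.  Reproducible by seed.
    """
    if n_individuals < 10:
        raise IfsgpError(f"need at least 10 individuals for an 80/20 split, got {n_individuals}")
    n_phi = int(np.floor(0.8 * n_individuals + 0.5))
    rng = np.random.default_rng(derive_seed(seed, 0))
    order = rng.permutation(n_individuals)
    return np.sort(order[:n_phi]), np.sort(order[n_phi:])


def evaluate(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    config: RunConfig | None = None,
    schedule: StepSchedule | None = None,
    on_fit=None,
) -> EvaluationReport:
    """Run the full pipeline on filtered data and report hold-out accuracy.

    Expects missing-free inputs (apply ``filter_missing`` beforehand).  A
    custom ``schedule`` overrides the one built from ``config.breakpoints``.
    """
    cfg = config or RunConfig()
    if np.any(phenotype.missing_mask):
        raise IfsgpError("phenotype contains missing values; run filter_missing first")

    n, p = genotypes.n_individuals, genotypes.n_snps
    seeds = {
        "master": cfg.seed,
        "split": derive_seed(cfg.seed, 0),
        "cv": derive_seed(cfg.seed, 1),
        "forest": derive_seed(cfg.seed, 2),
        "final_forest": derive_seed(cfg.seed, 3),
    }

    phi_idx, psi_idx = split_phi_psi(n, cfg.seed)
    g_phi = genotypes.take_individuals(phi_idx)
    y_phi = phenotype.take(phi_idx)

    if schedule is None:
        schedule = build_schedule(p, cfg.breakpoints)
    plan = make_cv_plan(len(phi_idx), cfg.n_folds, cfg.n_repetitions, seed=cfg.seed)
    forest_cfg = ForestConfig(
        n_trees=cfg.n_trees,
        mtry=cfg.mtry,
        min_node_size=cfg.min_node_size,
        seed=cfg.seed,
        n_threads=cfg.n_threads,
    )

    t0 = time.perf_counter()
    curve = run_ifs(
        g_phi,
        y_phi,
        schedule,
        plan,
        forest_cfg,
        metric=cfg.metric,
        pooled=cfg.pooled,
        on_fit=on_fit,
    )
    logger.info("IFS sweep finished in %.1fs", time.perf_counter() - t0)

    selection = select_optimum(curve, smooth_x=cfg.smooth_x, bass=cfg.bass)

    # final ranking from a fresh scan on all of phi (most data without
    # touching the hold-out partition)
    final_ranking = rank_snps(gwas_scan(g_phi, y_phi))
    selected = final_ranking.top(selection.optimal_count)
    selection.selected_snp_ids = [str(s) for s in genotypes.snp_ids[selected]]

    score = r_squared if cfg.metric == "r2" else pearson_r
    y_psi_obs = phenotype.values[psi_idx]

    all_cfg = dataclasses.replace(forest_cfg, seed=seeds["final_forest"])
    all_handle = fit_forest(genotypes, phenotype, np.arange(p), phi_idx, all_cfg)
    r2_all = float(score(y_psi_obs, predict(all_handle, genotypes, psi_idx)))

    if selection.use_all_snps:
        r2_selected: float | None = None
        advantage: float | None = None
    else:
        sel_cfg = dataclasses.replace(forest_cfg, seed=derive_seed(cfg.seed, 4))
        sel_handle = fit_forest(genotypes, phenotype, selected, phi_idx, sel_cfg)
        r2_selected = float(score(y_psi_obs, predict(sel_handle, genotypes, psi_idx)))
        advantage = r2_selected - r2_all

    return EvaluationReport(
        n_individuals=n,
        n_snps=p,
        n_selected=selection.optimal_count,
        pct_selected=100.0 * selection.optimal_count / p,
        r2_selected_psi=r2_selected,
        r2_all_psi=r2_all,
        advantage=advantage,
        use_all_snps=selection.use_all_snps,
        curve=curve,
        selection=selection,
        seeds=seeds,
    )
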