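"""Single-marker association scan and deterministic SNP ranking.

Each SNP is tested with a simple linear regression of the phenotype on the
additive dosage (no covariates, no structure correction), and the two-sided
Wald t-test p-value on the slope is used purely as an ordering criterion —
no multiple-testing correction is applied anywhere.  Ranking sorts
ascending on p-value with ties broken by genomic coordinates so the order
is reproducible across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import IfsgpError
from .plink_io import MISSING, GenotypeMatrix, PhenotypeVector


@dataclass
class AssociationResult:
    """Per-SNP p-values and slopes from a scan of one training subset."""

    p_values: np.ndarray
    slopes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.p_values)

    def to_frame(self, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
        """Tabular export: snp_id, chrom, pos, slope, p_value."""
        snp_id = (
            genotypes.snp_ids
            if genotypes is not None
            else np.arange(self.n_snps).astype(str)
        )
        return pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "slope": self.slopes,
                "p_value": self.p_values,
            }
        )

    def to_tsv(self, path: str | Path, genotypes: GenotypeMatrix | None = None) -> None:
        self.to_frame(genotypes).to_csv(path, sep="\t", index=False)


@dataclass
class SnpRanking:
    """A permutation of SNP indices, most significant first."""

    ranked_indices: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.ranked_indices[:k]


def gwas_scan(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    train_idx: np.ndarray | None = None,
) -> AssociationResult:
    """Scan every SNP with phenotype ~ intercept + dosage on the training rows.

    The p-value is the two-sided t-test on the regression slope with
    n_train - 2 degrees of freedom.  SNPs with zero dosage variance on the
    training rows (monomorphic) get p = 1 and slope = 0 by convention.  A
    constant phenotype yields all p = 1 with a warning, flagging an
    uninformative trait.
    """
    if train_idx is None:
        train_idx = np.arange(genotypes.n_individuals)
    train_idx = np.asarray(train_idx)
    n = len(train_idx)
    if n < 3:
        raise IfsgpError(f"association scan needs >= 3 training individuals, got {n}")

    x = genotypes.dosages[train_idx].astype(np.float64)
    if np.any(x == MISSING):
        raise IfsgpError("missing dosages in scan input; run filter_missing first")
    y = phenotype.values[train_idx]
    if np.any(phenotype.missing_mask[train_idx]):
        raise IfsgpError("missing phenotypes in scan input; run filter_missing first")

    p = genotypes.n_snps
    chrom = genotypes.snps["chrom"].to_numpy(dtype=str)
    pos = genotypes.snps["pos"].to_numpy(dtype=np.int64)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)

    polymorphic = sxx > 0
    slopes = np.zeros(p)
    p_values = np.ones(p)

    if syy == 0.0:
        warnings.warn(
            "phenotype is constant on the training set; all p-values set to 1",
            stacklevel=2,
        )
        return AssociationResult(p_values, slopes, chrom, pos)

    safe_sxx = np.where(polymorphic, sxx, 1.0)
    slopes = np.where(polymorphic, sxy / safe_sxx, 0.0)
    ss_res = np.maximum(syy - slopes * sxy, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = ss_res / df
        se = np.sqrt(sigma2 / safe_sxx)
        t = np.where(se > 0, slopes / se, np.where(slopes != 0, np.inf, 0.0))
    p_values = 2.0 * stats.t.sf(np.abs(t), df)
    p_values[~polymorphic] = 1.0
    slopes[~polymorphic] = 0.0
    return AssociationResult(p_values, slopes, chrom, pos)


def rank_snps(result: AssociationResult) -> SnpRanking:
    """Stable ascending sort on (p_value, chromosome, position)."""
    order = np.lexsort((result.pos, result.chrom, result.p_values))
    return SnpRanking(ranked_indices=order)
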