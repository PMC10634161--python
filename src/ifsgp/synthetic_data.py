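"""Synthetic genotype-phenotype datasets with known causal architecture.

SNP dosages are drawn per marker as Binomial(2, f) with the allele
frequency f uniform over a configurable range — independent markers by
default, with an optional block-correlation mode that induces LD-like
correlation between neighbouring markers.  The phenotype is an additive
score over a chosen set of causal SNPs, optionally augmented with
pairwise epistatic terms (products of centred dosages), plus Gaussian
environmental noise scaled so that the genetic fraction of phenotypic
variance matches a target heritability.  The realized variance ratio is
recorded, not assumed.

The generator emulates the shape of real SNP-chip datasets (dosage matrix,
marker map, quantitative trait) but not coalescent haplotype structure or
population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import IfsgpError
from .plink_io import MISSING, GenotypeMatrix, PhenotypeVector, write_plink

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    heritability is the target fraction of phenotypic variance explained by
    the genetic score (narrow-sense plus any epistatic terms); maf_range
    bounds the per-SNP allele frequency draw; block_size/block_rho switch on
    the optional correlated-marker mode (block_size=1 means independent
    SNPs).
    """

    n_individuals: int = 400
    n_snps: int = 2000
    n_causal: int = 20
    heritability: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_epistatic_pairs: int = 0
    effect_distribution: str = "gaussian"
    missing_rate: float = 0.0
    block_size: int = 1
    block_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise IfsgpError("n_individuals and n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise IfsgpError("n_causal must lie in [0, n_snps]")
        if 2 * self.n_epistatic_pairs > self.n_causal:
            raise IfsgpError("need n_causal >= 2 * n_epistatic_pairs")
        if not 0.0 <= self.heritability <= 1.0:
            raise IfsgpError("heritability must lie in [0, 1]")
        if self.heritability > 0 and self.n_causal == 0:
            raise IfsgpError("positive heritability requires causal SNPs")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise IfsgpError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise IfsgpError("missing_rate must lie in [0, 1)")
        if self.effect_distribution not in ("gaussian", "laplace"):
            raise IfsgpError("effect_distribution must be 'gaussian' or 'laplace'")


@dataclass
class SyntheticDataset:
    """A simulated dataset plus its ground truth."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    causal_indices: np.ndarray
    effects: np.ndarray
    epistatic_pairs: np.ndarray  # (k, 2) causal-index pairs
    epistatic_effects: np.ndarray
    genetic_values: np.ndarray
    allele_freqs: np.ndarray
    realized_h2: float
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _draw_dosages(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    n, p = cfg.n_individuals, cfg.n_snps
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    if cfg.block_size <= 1 or cfg.block_rho == 0.0:
        dosages = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)
        return dosages, freqs
    # Correlated mode: two latent standard-normal haplotype draws per
    # individual follow an AR(1) process along each block; thresholding at
    # the allele-frequency quantile yields correlated Bernoulli alleles.
    from scipy.stats import norm

    rho = cfg.block_rho
    dosages = np.empty((n, p), dtype=np.int8)
    for start in range(0, p, cfg.block_size):
        width = min(cfg.block_size, p - start)
        alleles = np.zeros((n, width), dtype=np.int8)
        for _hap in range(2):
            z = np.empty((n, width))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, width):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            thresholds = norm.ppf(freqs[start : start + width])
            alleles += (z < thresholds).astype(np.int8)
        dosages[:, start : start + width] = alleles
    return dosages, freqs


def _marker_map(p: int, rng: np.random.Generator) -> pd.DataFrame:
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=p)]
    return pd.DataFrame(
        {
            "chrom": "1",
            "snp": [f"snp{i}" for i in range(p)],
            "cm": 0.0,
            "pos": np.arange(1, p + 1) * 100,
            "a1": [a for a, _ in pairs],
            "a2": [b for _, b in pairs],
        }
    )


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; deterministic function of the config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps

    dosages, freqs = _draw_dosages(rng, config)

    causal = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    if config.effect_distribution == "gaussian":
        effects = rng.standard_normal(config.n_causal)
    else:
        effects = rng.laplace(size=config.n_causal)

    pairs = np.empty((config.n_epistatic_pairs, 2), dtype=np.int64)
    epi_effects = np.empty(config.n_epistatic_pairs)
    if config.n_epistatic_pairs:
        chosen = rng.choice(config.n_causal, size=2 * config.n_epistatic_pairs, replace=False)
        pairs = causal[chosen].reshape(-1, 2)
        epi_effects = rng.standard_normal(config.n_epistatic_pairs)

    x = dosages.astype(np.float64)
    centred = x - x.mean(axis=0)
    genetic = centred[:, causal] @ effects if config.n_causal else np.zeros(n)
    for (i, j), gamma in zip(pairs, epi_effects):
        genetic = genetic + gamma * centred[:, i] * centred[:, j]

    var_g = float(np.var(genetic))
    h2 = config.heritability
    if h2 == 0.0 or var_g == 0.0:
        scale = 0.0
        noise_sd = 1.0
        if h2 > 0:
            raise IfsgpError("zero genetic variance with positive heritability")
    else:
        # scale the genetic score to variance h2 and the noise to 1-h2 so
        # the variance ratio matches the target heritability
        scale = np.sqrt(h2 / var_g)
        noise_sd = np.sqrt(1.0 - h2)
    # store the scaled effects: they are the per-allele effects that
    # actually generate the phenotype, so the truth sidecar reconstructs
    # the additive score exactly
    effects = effects * scale
    epi_effects = epi_effects * scale
    scaled = genetic * scale
    noise = rng.standard_normal(n) * noise_sd
    phenotype = scaled + noise

    if config.missing_rate > 0:
        mask = rng.random(size=(n, p)) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING

    var_y = float(np.var(phenotype))
    realized_h2 = float(np.var(scaled) / var_y) if var_y > 0 else 0.0

    genotypes = GenotypeMatrix(
        dosages,
        pd.DataFrame(
            {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)]}
        ),
        _marker_map(p, rng),
    )
    return SyntheticDataset(
        genotypes=genotypes,
        phenotype=PhenotypeVector(phenotype),
        causal_indices=causal,
        effects=effects,
        epistatic_pairs=pairs,
        epistatic_effects=epi_effects,
        genetic_values=scaled,
        allele_freqs=freqs,
        realized_h2=realized_h2,
        config=config,
    )


def write_fixture(dataset: SyntheticDataset, prefix: str | Path) -> None:
    """Serialize via write_plink plus a TSV truth sidecar (<prefix>.truth.tsv)."""
    prefix = Path(prefix)
    write_plink(dataset.genotypes, dataset.phenotype, prefix)
    in_pair = np.isin(dataset.causal_indices, dataset.epistatic_pairs.ravel())
    truth = pd.DataFrame(
        {
            "snp_index": dataset.causal_indices,
            "effect": dataset.effects,
            "in_epistatic_pair": in_pair.astype(int),
        }
    )
    truth.to_csv(prefix.parent / (prefix.name + ".truth.tsv"), sep="\t", index=False)
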