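"""Reading and writing PLINK 1.x binary genotype triplets (.bed/.bim/.fam).

The .bed file stores genotypes as 2-bit codes in SNP-major order: after the
3-byte header (magic ``0x6C 0x1B`` plus mode byte ``0x01``), each SNP
occupies ``ceil(n/4)`` bytes, with individuals packed low-bit-first.  Codes
are ``00`` = homozygous A1, ``01`` = missing, ``10`` = heterozygous,
``11`` = homozygous A2.  By default the dosage counts the A1 allele of the
.bim (the usual minor allele), so a homozygous-A2 individual has dosage 0;
pass ``count_a1=False`` to flip the orientation.  Downstream association
ranking is orientation-invariant, but round-trips require a fixed
convention.

Missing dosages are stored as the sentinel :data:`MISSING` (-1) in an
``int8`` matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConsistencyError, EmptyDataError, FormatError

logger = logging.getLogger(__name__)

MISSING: int = -1

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit code -> dosage, counting A1 (index is the code)
_DECODE_A1 = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DECODE_A2 = np.array([0, MISSING, 1, 2], dtype=np.int8)

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


@dataclass
class GenotypeMatrix:
    """An n_individuals x n_snps dosage matrix with marker metadata.

    ``dosages`` holds values in {0, 1, 2, MISSING} as int8.  ``samples`` is a
    DataFrame with columns ``fid``/``iid``; ``snps`` carries the six .bim
    columns.  (chromosome, position) pairs give a total order used for
    deterministic tie-breaking downstream.
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ConsistencyError("dosages must be a 2-D matrix")
        if self.dosages.shape[0] != len(self.samples):
            raise ConsistencyError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.samples)} samples"
            )
        if self.dosages.shape[1] != len(self.snps):
            raise ConsistencyError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.snps)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp"].to_numpy()

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx],
            self.samples.iloc[idx].reset_index(drop=True),
            self.snps,
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.samples,
            self.snps.iloc[idx].reset_index(drop=True),
        )


@dataclass
class PhenotypeVector:
    """A real-valued phenotype aligned one-to-one with GenotypeMatrix rows."""

    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ConsistencyError("missing_mask misaligned with values")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, idx: np.ndarray) -> "PhenotypeVector":
        idx = np.asarray(idx)
        return PhenotypeVector(self.values[idx], self.missing_mask[idx])


def _suffixed(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required PLINK file not found: {path}")
    return path


def _decode_bed(raw: bytes, n: int, p: int, count_a1: bool) -> np.ndarray:
    if raw[:2] != _MAGIC:
        raise FormatError("not a PLINK .bed file (bad magic bytes)")
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise FormatError("only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise ConsistencyError(
            f".bed payload is {body.size} bytes; expected {bytes_per_snp * p} "
            f"for {n} individuals x {p} SNPs"
        )
    if p == 0:
        return np.empty((n, 0), dtype=np.int8)
    codes = body.reshape(p, bytes_per_snp)
    # expand each byte into its four 2-bit fields, low bits first
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (codes[:, :, None] >> shifts) & 0b11
    two_bit = two_bit.reshape(p, bytes_per_snp * 4)[:, :n]
    table = _DECODE_A1 if count_a1 else _DECODE_A2
    return np.ascontiguousarray(table[two_bit].T)


def _encode_bed(dosages: np.ndarray, count_a1: bool) -> bytes:
    n, p = dosages.shape
    table = _DECODE_A1 if count_a1 else _DECODE_A2
    # dosage -> 2-bit code (inverse of the decode table; MISSING -> 01)
    code_of = np.empty(4, dtype=np.uint8)
    for code, dosage in enumerate(table):
        code_of[int(dosage) % 4] = code  # MISSING=-1 wraps to index 3
    codes = code_of[dosages.T % 4]  # (p, n)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    return _MAGIC + bytes([_SNP_MAJOR]) + packed.tobytes()


def _read_phenotype_file(path: Path, samples: pd.DataFrame, column: int) -> np.ndarray:
    """Read a whitespace-delimited FID IID VALUE... file aligned to samples.

    ``column`` is the 1-based index of the value column counting from the
    first non-ID column (1 = third file column).  A header line is detected
    by the value field failing to parse as a number.
    """
    table = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str, float_precision="round_trip"
    )
    if table.shape[1] < 2 + column:
        raise FormatError(
            f"phenotype file has {table.shape[1]} columns; need at least {2 + column}"
        )
    first_value = table.iloc[0, 1 + column]
    try:
        float(first_value)
    except (TypeError, ValueError):
        table = table.iloc[1:]
    values = pd.to_numeric(table.iloc[:, 1 + column], errors="coerce")
    keyed = pd.Series(
        values.to_numpy(), index=pd.MultiIndex.from_frame(table.iloc[:, :2])
    )
    keyed = keyed[~keyed.index.duplicated(keep="first")]
    idx = pd.MultiIndex.from_frame(samples[["fid", "iid"]].astype(str))
    return keyed.reindex(idx).to_numpy(dtype=np.float64)


def read_plink(
    prefix: str | Path,
    pheno_file: str | Path | None = None,
    pheno_col: int = 1,
    count_a1: bool = True,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Read ``prefix``.bed/.bim/.fam into memory.

    The phenotype comes from .fam column 6 with -9 and 0 treated as missing;
    a separate phenotype file (FID IID VALUE..., optional header) overrides
    the .fam column when given.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _require(_suffixed(prefix, ".bim")),
        sep=r"\s+",
        header=None,
        names=BIM_COLUMNS,
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        _require(_suffixed(prefix, ".fam")),
        sep=r"\s+",
        header=None,
        names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str},
        float_precision="round_trip",
    )
    raw = _require(_suffixed(prefix, ".bed")).read_bytes()
    dosages = _decode_bed(raw, len(fam), len(bim), count_a1)
    genotypes = GenotypeMatrix(dosages, fam[["fid", "iid"]].copy(), bim)

    if pheno_file is not None:
        values = _read_phenotype_file(Path(pheno_file), genotypes.samples, pheno_col)
    else:
        values = pd.to_numeric(fam["phenotype"], errors="coerce").to_numpy(np.float64)
        values[np.isin(values, (-9.0, 0.0))] = np.nan
    return genotypes, PhenotypeVector(values)


def write_plink(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector | None,
    prefix: str | Path,
    count_a1: bool = True,
) -> None:
    """Write a .bed/.bim/.fam triplet readable by :func:`read_plink`.

    Round-trips are bit-exact on dosages and metadata.  Missing phenotypes
    are written as -9 per the .fam convention.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _suffixed(prefix, ".bed").write_bytes(_encode_bed(genotypes.dosages, count_a1))

    genotypes.snps[BIM_COLUMNS].to_csv(
        _suffixed(prefix, ".bim"), sep="\t", header=False, index=False
    )

    fam = genotypes.samples[["fid", "iid"]].copy()
    fam["father"] = 0
    fam["mother"] = 0
    fam["sex"] = 0
    if phenotype is None:
        fam["phenotype"] = -9
    else:
        if len(phenotype) != genotypes.n_individuals:
            raise ConsistencyError("phenotype length does not match genotypes")
        fam["phenotype"] = [
            "-9" if missing else repr(float(v))
            for v, missing in zip(phenotype.values, phenotype.missing_mask)
        ]
    fam.to_csv(_suffixed(prefix, ".fam"), sep="\t", header=False, index=False)


def filter_missing(
    genotypes: GenotypeMatrix, phenotype: PhenotypeVector
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Remove individuals with missing phenotype, then SNPs with any missing dosage.

    Individuals are dropped first so that a SNP missing only in unphenotyped
    individuals is retained.  Counts removed are logged for auditing.  No
    allele-frequency or HWE filtering is performed.
    """
    keep_ind = ~phenotype.missing_mask
    if not keep_ind.any():
        raise EmptyDataError("all individuals have missing phenotypes")
    g = genotypes.take_individuals(np.flatnonzero(keep_ind))
    y = phenotype.take(np.flatnonzero(keep_ind))

    keep_snp = ~(g.dosages == MISSING).any(axis=0)
    g = g.take_snps(np.flatnonzero(keep_snp))

    logger.info(
        "filter_missing: removed %d/%d individuals (missing phenotype), "
        "%d/%d SNPs (missing genotypes)",
        (~keep_ind).sum(),
        len(keep_ind),
        (~keep_snp).sum(),
        len(keep_snp),
    )
    return g, y
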