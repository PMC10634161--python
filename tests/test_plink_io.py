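import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifsgp import (
    MISSING,
    ConsistencyError,
    EmptyDataError,
    FormatError,
    filter_missing,
    read_plink,
    write_plink,
)

from conftest import geno_from_array, pheno


def roundtrip(tmp_path, dosages, phenotype=None, name="rt"):
    g = geno_from_array(dosages)
    y = phenotype if phenotype is not None else pheno(np.arange(1.0, len(dosages) + 1))
    prefix = tmp_path / name
    write_plink(g, y, prefix)
    return g, y, read_plink(prefix)


class TestBedCodec:
    def test_hom_allele2_has_dosage_zero_counting_a1(self, tmp_path):
        _, _, (g2, _) = roundtrip(tmp_path, [[0]])
        assert g2.dosages.tolist() == [[0]]

    def test_orientation_flag_flips_dosages(self, tmp_path):
        g = geno_from_array([[0, 1, 2], [2, 1, 0]])
        prefix = tmp_path / "flip"
        write_plink(g, pheno([1.0, 2.0]), prefix)
        g_a1, _ = read_plink(prefix)
        g_a2, _ = read_plink(prefix, count_a1=False)
        assert np.array_equal(g_a2.dosages, 2 - g_a1.dosages)

    def test_empty_snp_matrix_writes_bare_header(self, tmp_path):
        g = geno_from_array(np.empty((3, 0), dtype=np.int8))
        write_plink(g, pheno([1.0, 2.0, 3.0]), tmp_path / "empty")
        assert (tmp_path / "empty.bed").read_bytes() == bytes([0x6C, 0x1B, 0x01])

    def test_five_individuals_pack_into_two_bytes_per_snp(self, tmp_path):
        dosages = np.array([[0], [1], [2], [0], [1]], dtype=np.int8)
        g = geno_from_array(dosages)
        write_plink(g, pheno(np.ones(5)), tmp_path / "pad")
        raw = (tmp_path / "pad.bed").read_bytes()
        assert len(raw) == 3 + 2  # header + ceil(5/4) bytes for the one SNP

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 7),
        p=st.integers(0, 9),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_is_bit_exact(self, n, p, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        dosages = rng.choice([0, 1, 2, MISSING], size=(n, p)).astype(np.int8)
        values = rng.normal(size=n)
        tmp = tmp_path_factory.mktemp("rt")
        g, y, (g2, y2) = roundtrip(tmp, dosages, pheno(values))
        assert np.array_equal(g.dosages, g2.dosages)
        cols = ["chrom", "snp", "pos", "a1", "a2"]
        assert np.array_equal(
            g2.snps[cols].astype(str).to_numpy(), g.snps[cols].astype(str).to_numpy()
        )
        assert g2.samples.equals(g.samples)
        assert np.array_equal(y.values, y2.values)

    def test_decoded_dosage_frequencies_match_source(self, tmp_path):
        rng = np.random.default_rng(5)
        dosages = rng.choice([0, 1, 2, MISSING], size=(101, 37)).astype(np.int8)
        g, _, (g2, _) = roundtrip(tmp_path, dosages, pheno(rng.normal(size=101)))
        for value in (0, 1, 2, MISSING):
            assert np.array_equal(
                (g.dosages == value).sum(axis=0), (g2.dosages == value).sum(axis=0)
            )


class TestFamPhenotype:
    def test_minus_nine_is_missing(self, tmp_path):
        y = pheno([1.5, np.nan, 2.5])
        _, _, (_, y2) = roundtrip(tmp_path, np.zeros((3, 2), dtype=np.int8), y)
        assert y2.missing_mask.tolist() == [False, True, False]
        assert (tmp_path / "rt.fam").read_text().splitlines()[1].split()[-1] == "-9"

    def test_separate_phenotype_file_overrides_fam(self, tmp_path):
        g = geno_from_array(np.zeros((3, 2), dtype=np.int8))
        prefix = tmp_path / "p"
        write_plink(g, pheno([1.0, 2.0, 3.0]), prefix)
        (tmp_path / "alt.txt").write_text(
            "FID IID TRAIT\nF2 I2 30\nF0 I0 10\n"  # header, shuffled, F1 absent
        )
        _, y = read_plink(prefix, pheno_file=tmp_path / "alt.txt")
        assert y.values[0] == 10 and y.values[2] == 30
        assert y.missing_mask.tolist() == [False, True, False]


class TestFormatErrors:
    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_plink(tmp_path / "nope")

    def _write_triplet(self, tmp_path, bed_bytes):
        (tmp_path / "x.bed").write_bytes(bed_bytes)
        (tmp_path / "x.bim").write_text("1\tsnp0\t0\t10\tA\tG\n")
        (tmp_path / "x.fam").write_text("F0\tI0\t0\t0\t0\t1.0\n")

    def test_bad_magic_raises_format_error(self, tmp_path):
        self._write_triplet(tmp_path, bytes([0x00, 0x1B, 0x01, 0x00]))
        with pytest.raises(FormatError):
            read_plink(tmp_path / "x")

    def test_individual_major_mode_rejected(self, tmp_path):
        self._write_triplet(tmp_path, bytes([0x6C, 0x1B, 0x00, 0x00]))
        with pytest.raises(FormatError):
            read_plink(tmp_path / "x")

    def test_size_mismatch_raises_consistency_error(self, tmp_path):
        self._write_triplet(tmp_path, bytes([0x6C, 0x1B, 0x01, 0x00, 0x00]))
        with pytest.raises(ConsistencyError):
            read_plink(tmp_path / "x")


class TestFilterMissing:
    def test_identity_when_nothing_missing(self):
        g = geno_from_array([[0, 1], [2, 1], [1, 0]])
        y = pheno([1.0, 2.0, 3.0])
        g2, y2 = filter_missing(g, y)
        assert np.array_equal(g2.dosages, g.dosages)
        assert np.array_equal(y2.values, y.values)

    def test_individual_dropped_before_snps(self):
        # SNP 0 is missing only in the unphenotyped individual, so dropping
        # that individual first rescues the SNP
        g = geno_from_array([[MISSING, 1], [2, 1], [1, 0]])
        y = pheno([np.nan, 2.0, 3.0])
        g2, y2 = filter_missing(g, y)
        assert g2.n_individuals == 2 and g2.n_snps == 2
        assert np.array_equal(g2.dosages, [[2, 1], [1, 0]])

    def test_snp_missing_in_phenotyped_individual_is_dropped(self):
        g = geno_from_array([[0, MISSING], [2, 1], [1, 0]])
        g2, _ = filter_missing(g, pheno([1.0, 2.0, 3.0]))
        assert g2.n_snps == 1
        assert g2.snps["snp"].tolist() == ["snp0"]

    def test_idempotent(self):
        g = geno_from_array([[MISSING, 1], [2, 1], [1, MISSING]])
        y = pheno([np.nan, 2.0, 3.0])
        g1, y1 = filter_missing(g, y)
        g2, y2 = filter_missing(g1, y1)
        assert np.array_equal(g1.dosages, g2.dosages)
        assert np.array_equal(y1.values, y2.values)

    def test_all_individuals_missing_raises(self):
        g = geno_from_array([[0], [1]])
        with pytest.raises(EmptyDataError):
            filter_missing(g, pheno([np.nan, np.nan]))
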