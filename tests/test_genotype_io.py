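"""Unit tests for PLINK I/O, QC filters, normalization and residualization."""

import numpy as np
import pytest

from multiblup.genotype_io import (
    MISSING,
    GenotypeMatrix,
    QcThresholds,
    Sample,
    SnpRecord,
    allele_frequencies,
    apply_qc,
    hwe_exact_test,
    normalize,
    read_plink,
    residualize_phenotype,
    write_plink,
)
from multiblup.simulate import simulate_genotypes


class TestPlinkRoundTrip:
    def test_roundtrip_identity(self, tmp_path, tiny_genotypes):
        prefix = str(tmp_path / "toy")
        write_plink(tiny_genotypes, prefix)
        back = read_plink(prefix)
        assert np.array_equal(back.calls, tiny_genotypes.calls)
        assert back.snps == tiny_genotypes.snps
        assert [(s.family_id, s.individual_id) for s in back.samples] == [
            ("f1", "i1"), ("f2", "i2"), ("f3", "i3")
        ]

    def test_roundtrip_simulated(self, tmp_path):
        g = simulate_genotypes(37, 23, seed=7)  # n not a multiple of 4
        prefix = str(tmp_path / "sim")
        write_plink(g, prefix)
        back = read_plink(prefix)
        assert np.array_equal(back.calls, g.calls)

    def test_single_sample_single_snp_byte_count(self, tmp_path):
        g = GenotypeMatrix(
            samples=[Sample("f", "i")],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=np.array([[1]], dtype=np.int8),
        )
        prefix = str(tmp_path / "one")
        write_plink(g, prefix)
        # 3-byte header + 1 byte holding the single two-bit genotype
        assert (tmp_path / "one.bed").stat().st_size == 4
        assert len((tmp_path / "one.bim").read_text().splitlines()) == 1
        assert len((tmp_path / "one.fam").read_text().splitlines()) == 1

    def test_refuses_empty(self, tmp_path, tiny_genotypes):
        empty = GenotypeMatrix(samples=tiny_genotypes.samples, snps=[],
                               calls=np.empty((3, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            write_plink(empty, str(tmp_path / "bad"))

    def test_bad_magic(self, tmp_path, tiny_genotypes):
        prefix = str(tmp_path / "toy")
        write_plink(tiny_genotypes, prefix)
        raw = (tmp_path / "toy.bed").read_bytes()
        (tmp_path / "toy.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(ValueError, match="magic"):
            read_plink(prefix)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_plink(str(tmp_path / "nothing"))

    def test_payload_size_mismatch(self, tmp_path, tiny_genotypes):
        prefix = str(tmp_path / "toy")
        write_plink(tiny_genotypes, prefix)
        raw = (tmp_path / "toy.bed").read_bytes()
        (tmp_path / "toy.bed").write_bytes(raw + b"\x00")
        with pytest.raises(ValueError, match="payload"):
            read_plink(prefix)

    def test_hand_encoded_byte(self, tmp_path):
        # byte 0xD8 = 0b11011000; two-bit codes read low-to-high are
        # 00, 10, 01, 11 -> hom allele1, het, missing, hom allele2
        (tmp_path / "h.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0xD8]))
        (tmp_path / "h.bim").write_text("1 rs1 0 100 A G\n")
        (tmp_path / "h.fam").write_text(
            "".join(f"f{i} i{i} 0 0 0 -9\n" for i in range(4))
        )
        g = read_plink(str(tmp_path / "h"))
        assert g.calls[:, 0].tolist() == [0, 1, MISSING, 2]


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "calls, expected",
        [([0, 1, 2], 0.5), ([2, 2, 2], 1.0), ([0, MISSING, 1], 0.25)],
    )
    def test_known_values(self, calls, expected):
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(3)],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=np.array(calls, dtype=np.int8)[:, None],
        )
        assert allele_frequencies(g)[0] == pytest.approx(expected)

    def test_all_missing_raises(self):
        g = GenotypeMatrix(
            samples=[Sample("f", "i1"), Sample("f", "i2")],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=np.full((2, 1), MISSING, dtype=np.int8),
        )
        with pytest.raises(ValueError, match="rs1"):
            allele_frequencies(g)


def _hwe_bruteforce(n_hom1, n_het, n_hom2):
    """Enumeration oracle with exact integer factorials: the conditional
    probability of h heterozygotes given the allele counts is
    n! / (h! r! c!) * 2^h * n_rare! (2n - n_rare)! / (2n)!."""
    import math

    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het

    def p_exact(h):
        r = (n_rare - h) // 2
        c = n - h - r
        return (
            math.factorial(n)
            // (math.factorial(h) * math.factorial(r) * math.factorial(c))
            * 2**h
            * math.factorial(n_rare)
            * math.factorial(2 * n - n_rare)
            / math.factorial(2 * n)
        )

    probs = {h: p_exact(h) for h in range(n_rare % 2, n_rare + 1, 2)}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHweExactTest:
    @pytest.mark.parametrize(
        "counts", [(81, 18, 1), (25, 50, 25), (40, 10, 50), (5, 0, 5), (0, 10, 0)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_bruteforce(*counts), rel=1e-10
        )

    def test_equilibrium_counts_not_significant(self):
        assert hwe_exact_test(25, 50, 25) > 0.05

    def test_extreme_departure_significant(self):
        # no heterozygotes at intermediate frequency
        assert hwe_exact_test(50, 0, 50) < 1e-10


class TestApplyQc:
    def test_low_maf_removed_with_reason(self):
        n = 200
        calls = np.zeros((n, 1), dtype=np.int8)
        calls[0, 0] = 1  # f = 1/400 = 0.0025 < 0.01
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(n)],
            snps=[SnpRecord("rare", 1, 1, "A", "G")],
            calls=calls,
        )
        kept, report = apply_qc(g, QcThresholds(min_maf=0.01, min_call_rate=0,
                                                min_hwe_p=0))
        assert kept.p == 0
        assert report.iloc[0]["snp_id"] == "rare"
        assert "maf" in report.iloc[0]["reasons"]

    def test_disabled_thresholds_keep_everything(self, sim_cohort):
        g, _ = sim_cohort
        kept, report = apply_qc(g, QcThresholds(0, 0, 0))
        assert kept.p == g.p
        assert report.empty

    def test_idempotent(self, sim_cohort):
        g, _ = sim_cohort
        thr = QcThresholds(min_maf=0.05, min_call_rate=0.9, min_hwe_p=0.01)
        once, _ = apply_qc(g, thr)
        twice, report2 = apply_qc(once, thr)
        assert twice.p == once.p
        assert report2.empty

    def test_exact_hwe_counts_not_removed(self):
        # (81, 18, 1) sits exactly at Hardy-Weinberg proportions for f = 0.1
        assert hwe_exact_test(81, 18, 1) == pytest.approx(1.0)

    def test_hwe_filter_retains_iff_p_at_least_threshold(self):
        n = 100
        calls = np.array([0] * 85 + [1] * 10 + [2] * 5, dtype=np.int8)[:, None]
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(n)],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=calls,
        )
        p = hwe_exact_test(85, 10, 5)  # heterozygote deficit
        kept_low, _ = apply_qc(g, QcThresholds(0, 0, min_hwe_p=p * 0.99))
        kept_high, rep = apply_qc(g, QcThresholds(0, 0, min_hwe_p=p * 1.01))
        assert kept_low.p == 1
        assert kept_high.p == 0 and "hwe" in rep.iloc[0]["reasons"]

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QcThresholds(min_maf=0.7)


class TestNormalize:
    def test_closed_form_f_half(self):
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(3)],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=np.array([[0], [1], [2]], dtype=np.int8),
        )
        x = normalize(g)
        assert x.matrix[:, 0] == pytest.approx(
            [-np.sqrt(2), 0.0, np.sqrt(2)]
        )

    def test_missing_imputes_to_zero(self):
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(4)],
            snps=[SnpRecord("rs1", 1, 1, "A", "G")],
            calls=np.array([[0], [MISSING], [1], [1]], dtype=np.int8),
        )
        x = normalize(g)  # f = 0.25
        assert x.matrix[1, 0] == 0.0

    def test_monomorphic_rejected(self):
        g = GenotypeMatrix(
            samples=[Sample("f", f"i{k}") for k in range(3)],
            snps=[SnpRecord("mono", 1, 1, "A", "G")],
            calls=np.zeros((3, 1), dtype=np.int8),
        )
        with pytest.raises(ValueError, match="mono"):
            normalize(g)

    def test_columns_centred_unit_scale(self, sim_cohort):
        _, x = sim_cohort
        assert np.abs(x.matrix.mean(axis=0)).max() < 1e-10
        # variance close to 1 on average under the binomial scaling
        assert np.mean(x.matrix.var(axis=0)) == pytest.approx(1.0, abs=0.05)


class TestResidualize:
    def test_no_covariates_centres(self, rng):
        y = rng.standard_normal(30) + 5
        r = residualize_phenotype(y)
        assert r == pytest.approx(y - y.mean())

    def test_exact_linear_gives_zero(self, rng):
        c = rng.standard_normal(40)
        y = 2.0 + 3.0 * c
        assert np.abs(residualize_phenotype(y, c)).max() < 1e-10

    def test_matches_normal_equations(self, rng):
        n = 50
        C = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), C])
        expected = y - design @ np.linalg.solve(design.T @ design, design.T @ y)
        got = residualize_phenotype(y, C)
        assert got == pytest.approx(expected, abs=1e-10)
        # residuals orthogonal to every design column
        assert np.abs(design.T @ got).max() < 1e-8 * n

    def test_collinear_rejected(self, rng):
        c = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank"):
            residualize_phenotype(rng.standard_normal(20),
                                  np.column_stack([c, 2 * c]))
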