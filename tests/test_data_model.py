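import numpy as np
import pytest

from cdascan.data_model import (DOMINANT, GENOTYPIC, GenotypeMatrix,
                                PhenotypeVector, StratifiedCohort, ld_prune,
                                load_genotypes, recode, round_dosages,
                                stratify, transform_phenotype)


def _gm(values, chrom=None, pos=None):
    values = np.asarray(values, float)
    n, m = values.shape
    return GenotypeMatrix(values,
                          snp_ids=[f"s{i}" for i in range(m)],
                          chrom=chrom if chrom is not None else ["1"] * m,
                          pos=pos if pos is not None else np.arange(m) + 1,
                          sample_ids=[f"i{k}" for k in range(n)])


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1
1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/0
"""


class TestLoaders:
    def test_vcf_gt_to_allele_counts(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_TEXT)
        g = load_genotypes(p, format="vcf")
        assert g.values.shape == (2, 3)
        np.testing.assert_array_equal(g.values[0], [0, 1, 2])
        np.testing.assert_array_equal(g.values[1], [1, 2, 0])
        assert list(g.pos) == [100, 200, 300]
        assert not g.fractional

    def test_dosage_tsv_keeps_fractions_flagged(self, tmp_path):
        p = tmp_path / "dos.tsv"
        p.write_text("sample_id\tsnp1\tsnp2\nA\t1.4\t0\nB\t2\t1\n")
        g = load_genotypes(p, format="dosage-tsv")
        assert g.fractional
        assert g.values[0, 0] == pytest.approx(1.4)

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("sample_id\n")
        with pytest.raises(ValueError):
            load_genotypes(p, format="dosage-tsv")


class TestPreprocessing:
    @pytest.mark.parametrize("raw,expected", [(1.4, 1.0), (1.5, 2.0),
                                              (0.0, 0.0), (0.5, 1.0)])
    def test_rounding_half_away_from_zero(self, raw, expected):
        g = round_dosages(_gm([[raw]]))
        assert g.values[0, 0] == expected

    def test_rounding_idempotent(self, rng):
        g = _gm(rng.uniform(0, 2, size=(20, 5)))
        once = round_dosages(g)
        twice = round_dosages(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_rounding_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            round_dosages(_gm([[2.3]]))

    def test_log_transform_and_marginal(self):
        y = np.array([0.5, 0.25, 0.75])
        pv = transform_phenotype(y, kind="log_eps", eps=0.0)
        np.testing.assert_allclose(pv.y, np.log(y))
        assert pv.mu_hat == pytest.approx(np.mean(np.log(y)), abs=1e-12)
        assert pv.sigma2_hat == pytest.approx(np.var(np.log(y)), abs=1e-12)

    def test_log_transform_rejects_singularity(self):
        with pytest.raises(ValueError):
            transform_phenotype(np.array([0.0, 0.5]), kind="log_eps", eps=0.0)

    def test_identity_transform(self):
        pv = transform_phenotype([1.0, 2.0, 3.0], kind="none")
        assert pv.mu_hat == pytest.approx(2.0)
        assert pv.transform == "none"

    def test_recode_dominant_collapses_two(self):
        g = recode(_gm([[0, 1, 2]]), DOMINANT)
        np.testing.assert_array_equal(g.values, [[0, 1, 1]])
        g2 = recode(_gm([[0, 1, 2]]), GENOTYPIC)
        np.testing.assert_array_equal(g2.values, [[0, 1, 2]])


class TestLdPrune:
    def test_identical_columns_second_removed(self, rng):
        col = rng.integers(0, 3, size=50).astype(float)
        other = rng.integers(0, 3, size=50).astype(float)
        g = _gm(np.column_stack([col, col, other]))
        pruned = ld_prune(g, window=10, step=2, r2_threshold=0.9)
        assert list(pruned.snp_ids) == ["s0", "s2"]

    def test_independent_columns_retained(self, rng):
        g = _gm(rng.integers(0, 3, size=(400, 4)).astype(float))
        pruned = ld_prune(g, window=10, step=2, r2_threshold=0.9)
        assert pruned.n_snps == 4

    def test_no_retained_pair_exceeds_threshold(self, rng):
        # correlated blocks: exhaustive post-check of the pruning contract
        base = rng.integers(0, 2, size=(120, 3)).astype(float)
        noisy = base.copy()
        flip = rng.random(base.shape) < 0.02
        noisy[flip] = 1 - noisy[flip]
        g = _gm(np.column_stack([base, noisy]))
        thr = 0.8
        pruned = ld_prune(g, window=6, step=1, r2_threshold=thr)
        v = pruned.values
        r2 = np.corrcoef(v, rowvar=False) ** 2
        iu = np.triu_indices(pruned.n_snps, k=1)
        assert np.all(r2[iu] <= thr + 1e-12)

    def test_monomorphic_retained_with_warning(self, rng):
        g = _gm(np.column_stack([np.ones(30),
                                 rng.integers(0, 3, 30).astype(float)]))
        with pytest.warns(UserWarning):
            pruned = ld_prune(g, window=5, step=1, r2_threshold=0.5)
        assert "s0" in list(pruned.snp_ids)

    def test_per_chromosome_independence(self, rng):
        col = rng.integers(0, 3, size=60).astype(float)
        g = _gm(np.column_stack([col, col]), chrom=["1", "2"], pos=[10, 10])
        pruned = ld_prune(g, window=5, step=1, r2_threshold=0.9)
        assert pruned.n_snps == 2  # duplicates live on different chromosomes


class TestStratify:
    def test_binary_labels(self, rng):
        g = _gm(rng.integers(0, 3, size=(4, 2)).astype(float))
        pv = PhenotypeVector(rng.normal(size=4))
        cohort = stratify(g, pv, ["M", "F", "M", "F"], rule="binary-label")
        assert cohort.sizes == [2, 2]
        joined = sorted(np.concatenate([s[0].sample_ids
                                        for s in cohort.strata]))
        assert joined == sorted(g.sample_ids)

    def test_median_split_ties_to_first(self, rng):
        g = _gm(rng.integers(0, 3, size=(4, 2)).astype(float))
        pv = PhenotypeVector(rng.normal(size=4))
        cohort = stratify(g, pv, [1.0, 2.0, 3.0, 4.0], rule="median-split")
        assert cohort.sizes == [2, 2]

    def test_constant_covariate_rejected(self, rng):
        g = _gm(rng.integers(0, 3, size=(4, 2)).astype(float))
        pv = PhenotypeVector(rng.normal(size=4))
        with pytest.raises(ValueError):
            stratify(g, pv, [1.0, 1.0, 1.0, 1.0], rule="median-split")

    def test_three_labels_rejected(self, rng):
        g = _gm(rng.integers(0, 3, size=(3, 2)).astype(float))
        pv = PhenotypeVector(rng.normal(size=3))
        with pytest.raises(ValueError):
            stratify(g, pv, ["a", "b", "c"], rule="binary-label")


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=2.0), min_size=1,
                max_size=12))
def test_rounding_lands_on_valid_counts_and_is_idempotent(values):
    g = _gm([values])
    once = round_dosages(g)
    assert np.all(np.isin(once.values, (0.0, 1.0, 2.0)))
    np.testing.assert_array_equal(once.values, round_dosages(once).values)


class TestMissingGenotypes:
    def test_mode_imputation_fills_with_per_snp_mode(self):
        from cdascan.data_model import impute_missing
        vals = np.array([[0.0, 1.0], [np.nan, 1.0], [0.0, np.nan],
                         [2.0, 0.0], [0.0, 0.0]])
        g = impute_missing(_gm(vals), strategy="mode")
        assert g.values[1, 0] == 0.0  # SNP 0 mode
        assert g.values[2, 1] in (0.0, 1.0)
        assert not np.isnan(g.values).any()

    def test_drop_strategy_removes_samples(self):
        from cdascan.data_model import impute_missing
        vals = np.array([[0.0, 1.0], [np.nan, 1.0], [2.0, 2.0]])
        g = impute_missing(_gm(vals), strategy="drop")
        assert g.n_samples == 2

    def test_rounding_refuses_missing(self):
        with pytest.raises(ValueError):
            round_dosages(_gm([[np.nan]]))
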