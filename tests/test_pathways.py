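import numpy as np
import pytest

from cdascan import DOMINANT, GenotypeMatrix, PhenotypeVector
from cdascan.pathways import (GeneSpan, ScanConfig, heritability_split_half,
                              map_snps_to_pathways, pathway_scan,
                              read_gene_spans, read_gmt)
from cdascan.simulate import preset_spec, sample_cohort


def _geno(pos, chrom=None, n=4, rng=None):
    pos = np.asarray(pos)
    m = len(pos)
    rng = rng or np.random.default_rng(0)
    return GenotypeMatrix(rng.integers(0, 2, (n, m)).astype(float),
                          [f"s{i}" for i in range(m)],
                          chrom if chrom is not None else ["1"] * m, pos,
                          [f"i{k}" for k in range(n)])


class TestMapping:
    def test_window_boundary_arithmetic(self):
        spans = [GeneSpan("G1", "1", 100_000, 105_000)]
        g = _geno([60_000, 49_999, 155_000, 155_001, 102_000])
        sets = {"pw": ["G1"]}
        out = map_snps_to_pathways(g, spans, sets, window_bp=50_000,
                                   min_snps=1)
        # 60000 (40kb away), 155000 (50kb exactly) and 102000 (inside) map;
        # 49999 (50001 away) and 155001 are out
        assert list(out[0].snp_indices) == [0, 2, 4]

    def test_small_pathways_dropped(self):
        spans = [GeneSpan("G1", "1", 1000, 2000)]
        g = _geno([1500, 1600, 1700, 1800])  # only 4 SNPs map
        out = map_snps_to_pathways(g, spans, {"pw": ["G1"]}, min_snps=5)
        assert out == []

    def test_gene_order_irrelevant_and_union_semantics(self):
        spans = [GeneSpan("A", "1", 1000, 2000), GeneSpan("B", "1", 5000, 6000)]
        g = _geno([1500, 5500, 1600, 5600, 9_000_000], n=3)
        a = map_snps_to_pathways(g, spans, {"pw": ["A", "B"]}, min_snps=1)
        b = map_snps_to_pathways(g, spans, {"pw": ["B", "A", "A"]}, min_snps=1)
        assert list(a[0].snp_indices) == list(b[0].snp_indices) == [0, 1, 2, 3]

    def test_missing_gene_skipped(self, caplog):
        spans = [GeneSpan("A", "1", 1000, 2000)]
        g = _geno([1500, 1600, 1700, 1800, 1900], n=3)
        out = map_snps_to_pathways(g, spans, {"pw": ["A", "UNKNOWN"]},
                                   min_snps=5)
        assert len(out) == 1

    def test_bed_and_gmt_readers(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999\t2000\tA\n2\t10\t20\tB\n")
        spans = read_gene_spans(bed)
        assert spans[0].start == 1000 and spans[0].end == 2000  # 1-based incl
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw1\tdesc\tA\tB\npw2\tdesc\tB\n")
        sets = read_gmt(gmt)
        assert sets == {"pw1": ["A", "B"], "pw2": ["B"]}


@pytest.fixture(scope="module")
def planted_scan_data():
    """Cohort where the first 6 SNPs carry interaction signal and the rest
    are pure noise, plus pathway structure mapping onto both groups."""
    rng = np.random.default_rng(77)
    sig_spec = preset_spec("interaction", m=6, n=240, seed=31)
    sig_spec.parameter_dists["J1"] = (0.25, 0.05)
    g_sig, pheno, _ = sample_cohort(sig_spec)
    noise = rng.integers(0, 2, (240, 8)).astype(float)
    values = np.hstack([g_sig.values, noise])
    m = values.shape[1]
    g = GenotypeMatrix(values, [f"s{i}" for i in range(m)], ["1"] * m,
                       (np.arange(m) + 1) * 10_000,
                       [f"i{k}" for k in range(240)])
    covariate = rng.integers(0, 2, 240)  # non-informative stratifier
    spans = [GeneSpan(f"G{i}", "1", int(g.pos[i]) - 100, int(g.pos[i]) + 100)
             for i in range(m)]
    sets = {"signal": [f"G{i}" for i in range(6)],
            "noise": [f"G{i}" for i in range(6, 14)]}
    return g, pheno, covariate, spans, sets


class TestScan:
    def test_planted_pathway_ranks_first(self, planted_scan_data):
        g, pheno, cov, spans, sets = planted_scan_data
        pathways = map_snps_to_pathways(g, spans, sets, window_bp=1000)
        cfg = ScanConfig(encoding=DOMINANT, prune=False,
                         grid1=np.array([0.01, 1.0, 100.0]),
                         grid2=np.array([0.01, 1.0, 100.0]), seed=5)
        table = pathway_scan(g, pheno, cov, pathways, cfg)
        table = table.set_index("pathway")
        assert table.loc["signal", "p"] < table.loc["noise", "p"]
        assert table.loc["signal", "p"] < 0.01
        assert table.loc["noise", "status"] == "ok"

    def test_rerun_is_identical(self, planted_scan_data):
        g, pheno, cov, spans, sets = planted_scan_data
        pathways = map_snps_to_pathways(g, spans, sets, window_bp=1000)
        cfg = ScanConfig(encoding=DOMINANT, prune=False,
                         grid1=np.array([1.0]), grid2=np.array([1.0]), seed=5)
        a = pathway_scan(g, pheno, cov, pathways, cfg)
        b = pathway_scan(g, pheno, cov, pathways[::-1], cfg)
        a = a.sort_values("pathway").reset_index(drop=True)
        b = b.sort_values("pathway").reset_index(drop=True)
        assert a.equals(b)


class TestHeritability:
    def test_deterministic_and_affine_invariant(self):
        spec = preset_spec("strong", m=5, n=240, seed=41)
        g, pheno, _ = sample_cohort(spec)
        grids = dict(grid1=np.array([0.1, 10.0]), grid2=np.array([0.1, 10.0]))
        a = heritability_split_half(g, pheno, encoding=DOMINANT, seed=2,
                                    **grids)
        b = heritability_split_half(g, pheno, encoding=DOMINANT, seed=2,
                                    **grids)
        assert a.r2 == b.r2
        scaled = PhenotypeVector(3.0 * pheno.y - 7.0)
        c = heritability_split_half(g, scaled, encoding=DOMINANT, seed=2,
                                    **grids)
        assert c.r2 == pytest.approx(a.r2, abs=1e-9)
        assert 0.0 <= a.r2 <= 1.0
        assert a.ci95[0] <= a.r2 <= a.ci95[1] or a.r2 == 0.0

    def test_small_cohort_rejected(self):
        g, pheno, _ = sample_cohort(preset_spec("null", m=3, n=30, seed=1))
        with pytest.raises(ValueError):
            heritability_split_half(g, pheno, encoding=DOMINANT)
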