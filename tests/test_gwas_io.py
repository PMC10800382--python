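"""Summary-statistics I/O, harmonization, LD computation, pruning, gene maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from pleioscan import gwas_io


# ---------------------------------------------------------------------------
# read_sumstats
# ---------------------------------------------------------------------------

def _write(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_well_formed_ingestion(self, tmp_path):
        path = _write(tmp_path, (
            "SNP CHR BP A1 A2 Z N\n"
            "rs1 1 100 A G 1.0 5000\n"
            "rs2 1 200 C T -0.5 5000\n"
            "rs3 2 50 G A 2.2 5000\n"))
        ss, audit = gwas_io.read_sumstats(path, trait_id="x")
        assert ss.n_snps == 3 and audit.empty
        assert list(ss.table["SNP"]) == ["rs1", "rs2", "rs3"]

    def test_z_from_beta_se(self, tmp_path):
        path = _write(tmp_path, (
            "SNP CHR BP A1 A2 BETA SE N\n"
            "rs1 1 100 A G 0.2 0.1 5000\n"))
        ss, _ = gwas_io.read_sumstats(path)
        assert ss.table["Z"].iloc[0] == pytest.approx(2.0)

    def test_inconsistent_p_dropped(self, tmp_path):
        # two-sided tail of |z| = 1.96 is ~0.05, checked against an
        # independent numerical integration of the normal density
        tail, _ = integrate.quad(stats.norm.pdf, 1.96, np.inf)
        assert abs(2 * tail - 0.05) < 1e-3
        path = _write(tmp_path, (
            "SNP CHR BP A1 A2 Z N P\n"
            "rs1 1 100 A G 1.96 5000 0.5\n"
            f"rs2 1 200 C T 1.96 5000 {2 * tail:.10f}\n"))
        ss, audit = gwas_io.read_sumstats(path)
        assert ss.n_snps == 1 and list(ss.table["SNP"]) == ["rs2"]
        assert audit["reason"].iloc[0] == "p inconsistent with z"

    def test_missing_column_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "SNP CHR BP A1 Z N\nrs1 1 100 A 1.0 5000\n")
        with pytest.raises(gwas_io.SumstatsError, match="A2"):
            gwas_io.read_sumstats(path)

    def test_no_valid_rows_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "SNP CHR BP A1 A2 Z N\nrs1 1 100 A A 1.0 5000\n")
        with pytest.raises(gwas_io.SumstatsError, match="no valid rows"):
            gwas_io.read_sumstats(path)

    def test_write_round_trip(self, tmp_path):
        path = _write(tmp_path, (
            "SNP CHR BP A1 A2 Z N\nrs1 1 100 A G 1.25 5000\n"))
        ss, _ = gwas_io.read_sumstats(path, trait_id="x")
        out = tmp_path / "out.tsv"
        gwas_io.write_sumstats(ss, out)
        ss2, _ = gwas_io.read_sumstats(out, trait_id="x")
        pd.testing.assert_frame_equal(ss.table, ss2.table)


# ---------------------------------------------------------------------------
# harmonize
# ---------------------------------------------------------------------------

def _trait(rows, trait_id="t"):
    tab = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "Z", "N"])
    tab["P"] = 2.0 * stats.norm.sf(np.abs(tab["Z"]))
    return gwas_io.SummaryStats(trait_id, tab)


PANEL_META = pd.DataFrame({
    "SNP": ["rs1", "rs2", "rs3"],
    "CHR": "1", "BP": [100, 200, 300],
    "A1": ["C", "A", "T"], "A2": ["G", "G", "C"],
})


class TestHarmonize:
    def test_palindromic_removed(self):
        t = _trait([("rs1", "1", 100, "G", "C", 1.5, 1e4),
                    ("rs2", "1", 200, "A", "G", 1.0, 1e4),
                    ("rs3", "1", 300, "T", "C", 0.5, 1e4)])
        z, uni, audit = gwas_io.harmonize([t], PANEL_META)
        assert "rs1" not in set(uni["SNP"])
        assert audit.set_index("SNP")["disposition"]["rs1"] == "palindromic"

    def test_swapped_alleles_flip_sign(self):
        t = _trait([("rs2", "1", 200, "G", "A", 2.0, 1e4),
                    ("rs3", "1", 300, "T", "C", 0.5, 1e4)])
        z, uni, _ = gwas_io.harmonize([t], PANEL_META)
        assert z[0, list(uni["SNP"]).index("rs2")] == pytest.approx(-2.0)

    def test_strand_complement_match(self):
        # panel rs3 is T/C; trait on the other strand reports A/G
        t = _trait([("rs3", "1", 300, "A", "G", 1.2, 1e4)])
        z, uni, _ = gwas_io.harmonize([t], PANEL_META)
        assert z[0, 0] == pytest.approx(1.2)

    def test_intersection_shape(self):
        rows = [("rs2", "1", 200, "A", "G", 1.0, 1e4),
                ("rs3", "1", 300, "T", "C", 0.5, 1e4)]
        traits = [_trait(rows, f"t{i}") for i in range(3)]
        z, uni, _ = gwas_io.harmonize(traits, PANEL_META)
        assert z.shape == (3, 2)

    def test_irreconcilable_removed(self):
        t = _trait([("rs2", "1", 200, "A", "C", 1.0, 1e4),
                    ("rs3", "1", 300, "T", "C", 0.5, 1e4)])
        z, uni, audit = gwas_io.harmonize([t], PANEL_META)
        assert list(uni["SNP"]) == ["rs3"]
        assert "irreconcilable" in audit.set_index("SNP")["disposition"]["rs2"]

    def test_idempotent(self):
        t = _trait([("rs2", "1", 200, "G", "A", 2.0, 1e4),
                    ("rs3", "1", 300, "T", "C", 0.5, 1e4)])
        z1, uni1, _ = gwas_io.harmonize([t], PANEL_META)
        # re-harmonizing the harmonized table against the panel changes nothing
        t2 = gwas_io.SummaryStats("t", uni1.assign(Z=z1[0], N=1e4, P=0.5)[
            ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P"]])
        z2, uni2, audit2 = gwas_io.harmonize([t2], PANEL_META)
        np.testing.assert_array_equal(z1, z2)
        pd.testing.assert_frame_equal(uni1[["SNP", "A1", "A2"]], uni2[["SNP", "A1", "A2"]])

    def test_empty_intersection_is_hard_error(self):
        t = _trait([("rs99", "1", 900, "A", "G", 1.0, 1e4)])
        with pytest.raises(ValueError, match="no SNPs shared"):
            gwas_io.harmonize([t], PANEL_META)


# ---------------------------------------------------------------------------
# compute_ld
# ---------------------------------------------------------------------------

class TestComputeLd:
    def test_duplicated_column_r_is_one(self):
        dos = np.array([[0, 0, 2.], [1, 1, 0], [2, 2, 1], [1, 1, 2], [0, 0, 0]])
        meta = pd.DataFrame({"SNP": ["a", "b", "c"], "CHR": "1",
                             "BP": [1, 2, 3], "A1": "A", "A2": "G"})
        ld = gwas_io.compute_ld(gwas_io.GenotypePanel(meta, dos), window_snps=5)
        assert ld.r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_columns_ld_score_one(self):
        dos = np.array([[0, 1.], [2, 1], [1, 0], [1, 2]])  # centered orthogonal
        meta = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1",
                             "BP": [1, 2], "A1": "A", "A2": "G"})
        ld = gwas_io.compute_ld(gwas_io.GenotypePanel(meta, dos), window_snps=5)
        np.testing.assert_allclose(ld.ld_scores, [1.0, 1.0], atol=1e-12)

    def test_matches_hand_pearson(self):
        dos = np.array([[0, 2.], [1, 1], [2, 2], [1, 0]])
        meta = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1",
                             "BP": [1, 2], "A1": "A", "A2": "G"})
        ld = gwas_io.compute_ld(gwas_io.GenotypePanel(meta, dos), window_snps=5)
        x, y = dos[:, 0], dos[:, 1]
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert ld.r[0, 1] == pytest.approx(r_hand)
        assert ld.ld_scores[0] == pytest.approx(1 + r_hand ** 2)
        assert ld.r2_hist[0].sum() == 1  # one neighbour

    def test_sample_permutation_invariance(self, small_panel):
        ld1 = gwas_io.compute_ld(small_panel, window_snps=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_panel.n_samples)
        shuffled = gwas_io.GenotypePanel(small_panel.snp_meta,
                                         small_panel.dosages[perm])
        ld2 = gwas_io.compute_ld(shuffled, window_snps=6)
        np.testing.assert_allclose(ld1.ld_scores, ld2.ld_scores, atol=1e-12)
        np.testing.assert_allclose(ld1.r.toarray(), ld2.r.toarray(), atol=1e-12)

    def test_ld_scores_at_least_one(self, small_panel):
        ld = gwas_io.compute_ld(small_panel, window_snps=4)
        assert (ld.ld_scores >= 1.0 - 1e-12).all()

    def test_bias_correction_floors_at_zero(self, small_panel):
        ld = gwas_io.compute_ld(small_panel, window_snps=4, bias_correct=True)
        ld0 = gwas_io.compute_ld(small_panel, window_snps=4, bias_correct=False)
        assert (ld.ld_scores <= ld0.ld_scores + 1e-12).all()
        assert (ld.ld_scores >= 1.0 - 1e-12).all()

    def test_bias_correction_needs_three_samples(self):
        meta = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "BP": [1, 2],
                             "A1": "A", "A2": "G"})
        panel = gwas_io.GenotypePanel(meta, np.array([[0, 1.], [2, 0]]))
        with pytest.raises(ValueError, match="3 samples"):
            gwas_io.compute_ld(panel, window_snps=2, bias_correct=True)

    def test_monomorphic_rejected(self):
        meta = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "BP": [1, 2],
                             "A1": "A", "A2": "G"})
        with pytest.raises(ValueError, match="monomorphic"):
            gwas_io.GenotypePanel(meta, np.array([[1, 1.], [2, 1], [0, 1]]))


# ---------------------------------------------------------------------------
# ld_prune
# ---------------------------------------------------------------------------

def _ld_from_r(r: np.ndarray) -> gwas_io.LdInfo:
    from scipy import sparse
    m = len(r)
    ids = np.array([f"rs{i+1}" for i in range(m)])
    edges = gwas_io.DEFAULT_R2_BIN_EDGES
    ld_scores = 1.0 + (r ** 2).sum(axis=1) - 1.0
    hist = np.zeros((m, len(edges) - 1))
    return gwas_io.LdInfo(ids, sparse.csr_matrix(r), ld_scores, hist, edges)


def brute_force_prune(r: np.ndarray, window: int, step: int, thr: float) -> list[int]:
    """Literal pair-by-pair re-implementation of the stated greedy rule."""
    m = len(r)
    keep = [True] * m
    start = 0
    while True:
        stop = min(start + window, m)
        for j in range(start, stop):
            for k in range(j + 1, stop):
                if keep[j] and keep[k] and r[j, k] ** 2 > thr:
                    keep[k] = False  # drop the later-position SNP
        if stop >= m:
            break
        start += step
    return [i for i in range(m) if keep[i]]


class TestLdPrune:
    def test_all_below_threshold_kept(self):
        r = np.eye(5) + 0.2 * (np.ones((5, 5)) - np.eye(5))  # r2 = 0.04
        ld = _ld_from_r(r)
        assert list(gwas_io.ld_prune(ld)) == list(ld.snp_ids)

    def test_perfect_pair_keeps_earlier(self):
        r = np.eye(2); r[0, 1] = r[1, 0] = 1.0
        kept = gwas_io.ld_prune(_ld_from_r(r))
        assert list(kept) == ["rs1"]

    def test_chain_matches_brute_force(self):
        m = 6
        r = np.eye(m)
        for j in range(m - 1):
            r[j, j + 1] = r[j + 1, j] = np.sqrt(0.5)
        ld = _ld_from_r(r)
        kept = gwas_io.ld_prune(ld, window_snps=50, step_snps=5, r2_threshold=0.1)
        expected = [ld.snp_ids[i] for i in brute_force_prune(r, 50, 5, 0.1)]
        assert list(kept) == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 30), st.integers(1, 10),
           st.integers(1, 8))
    def test_matches_oracle_and_no_violating_pairs(self, seed, m, window, step):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((m + 3, m))
        r = np.corrcoef(a, rowvar=False)
        ld = _ld_from_r(r)
        kept = gwas_io.ld_prune(ld, window_snps=window, step_snps=step,
                                r2_threshold=0.1)
        oracle = [ld.snp_ids[i] for i in brute_force_prune(r, window, step, 0.1)]
        assert list(kept) == oracle
        # exhaustive post-check: no surviving pair sharing a scanned window
        # exceeds the threshold
        kept_set = {i for i, s in enumerate(ld.snp_ids) if s in set(kept)}
        start = 0
        while True:
            stop = min(start + window, m)
            inside = sorted(kept_set & set(range(start, stop)))
            for a_, i in enumerate(inside):
                for j in inside[a_ + 1:]:
                    assert r[i, j] ** 2 <= 0.1 + 1e-12
            if stop >= m:
                break
            start += step

    def test_parameter_validation(self):
        ld = _ld_from_r(np.eye(2))
        with pytest.raises(ValueError):
            gwas_io.ld_prune(ld, window_snps=0)
        with pytest.raises(ValueError):
            gwas_io.ld_prune(ld, r2_threshold=0.0)


# ---------------------------------------------------------------------------
# map_snps_to_genes
# ---------------------------------------------------------------------------

class TestGeneMapping:
    universe = pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3"], "CHR": ["1", "1", "1"],
        "BP": [100, 201, 150],
    })

    def test_inclusive_boundaries_and_flank(self):
        g = gwas_io.GeneModel("g1", "1", 100, 200)
        m0 = gwas_io.map_snps_to_genes(self.universe, [g], flank_bp=0)
        assert list(m0["g1"]) == [0, 2]  # rs1 at start included, rs2 one past end excluded
        m1 = gwas_io.map_snps_to_genes(self.universe, [g], flank_bp=1)
        assert list(m1["g1"]) == [0, 2, 1]  # sorted by position: 100, 150, 201

    def test_overlapping_genes_share_snps(self):
        g1 = gwas_io.GeneModel("g1", "1", 100, 200)
        g2 = gwas_io.GeneModel("g2", "1", 140, 260)
        mapping = gwas_io.map_snps_to_genes(self.universe, [g1, g2])
        assert 2 in mapping["g1"] and 2 in mapping["g2"]

    def test_empty_genes_omitted(self):
        g = gwas_io.GeneModel("g1", "2", 100, 200)
        assert gwas_io.map_snps_to_genes(self.universe, [g]) == {}

    def test_bed_reader_converts_coordinates(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t200\tg1\t0\t+\n")
        genes = gwas_io.read_gene_models(bed, bed=True)
        assert genes[0].start == 100 and genes[0].end == 200 and genes[0].strand == "+"

    def test_one_based_interval_reader(self, tmp_path):
        tab = tmp_path / "genes.tsv"
        tab.write_text("gene\tchrom\tstart\tend\ng1\t1\t100\t200\n")
        genes = gwas_io.read_gene_models(tab)
        assert genes[0].start == 100 and genes[0].end == 200


class TestPanelAndAnnotationReaders:
    def test_panel_round_trip_with_missing(self, tmp_path):
        (tmp_path / "meta.tsv").write_text(
            "SNP CHR BP A1 A2\nrs1 1 100 A G\nrs2 1 200 C T\n")
        (tmp_path / "dos.tsv").write_text("0 2\n1 NA\n2 0\n1 1\n")
        panel = gwas_io.read_panel(tmp_path / "dos.tsv", tmp_path / "meta.tsv")
        assert panel.n_samples == 4 and panel.n_snps == 2
        assert np.isnan(panel.dosages[1, 1])
        # mean imputation happens inside compute_ld
        ld = gwas_io.compute_ld(panel, window_snps=2)
        assert np.isfinite(ld.ld_scores).all()

    def test_annotation_reader(self, tmp_path):
        (tmp_path / "annot.tsv").write_text("SNP cat1 cat2\nrs1 1 0\nrs2 0 1\n")
        annot = gwas_io.read_annotations(tmp_path / "annot.tsv")
        assert list(annot.columns) == ["cat1", "cat2"]
        assert annot.loc["rs1", "cat1"] == 1
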