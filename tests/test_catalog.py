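"""QTL catalog tests: cis/trans classification, hotspot masking, clumping
against a brute-force connectivity oracle, and LD adjustment against a
joint-OLS oracle on a simulated reference panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatekit.catalog import (adjust_for_ld, build_catalog, cis_score_eligible,
                             classify_cis_trans, clump_positions, clump_qtls,
                             harmonize_alleles, ld_from_genotypes, mask_hla,
                             select_trans_qtls)
from gatekit.exceptions import (ClassificationError, NumericalError,
                                StructuralError)
from gatekit.synthetic import (ArchitectureConfig, sample_architecture,
                               simulate_genotypes)


def _records(rows):
    base = dict(SNP="rs1", CHR="1", POS=1, EA="A", OA="G", GENE="G1",
                GENE_CHR="1", GENE_TSS=1, BETA=0.1, SE=0.05, P=1e-9)
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d["SNP"] = f"rs{i + 1}"
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


class TestClassify:
    @pytest.mark.parametrize("chrom,pos,gchrom,tss,label", [
        ("1", 50_000_000, "2", 50_000_000, "trans"),     # inter-chromosomal
        ("2", 100_000_000, "2", 102_000_000, "cis"),     # within 5 Mb
        ("2", 100_000_000, "2", 106_000_000, "trans"),   # 6 Mb >= 5 Mb
        ("2", 100_000_000, "2", 105_000_000, "trans"),   # boundary: == window
    ])
    def test_window_rule(self, chrom, pos, gchrom, tss, label):
        df = _records([dict(CHR=chrom, POS=pos, GENE_CHR=gchrom,
                            GENE_TSS=tss)])
        assert classify_cis_trans(df).iloc[0] == label

    def test_missing_tss_raises(self):
        df = _records([dict(GENE_TSS=np.nan)])
        with pytest.raises(ClassificationError):
            classify_cis_trans(df)


class TestMaskHla:
    @pytest.mark.parametrize("chrom,pos,masked", [
        ("6", 26_000_000, True),
        ("6", 25_000_000, True),    # inclusive lower endpoint
        ("6", 34_000_000, True),    # inclusive upper endpoint
        ("6", 35_000_000, False),
        ("6", 24_999_999, False),
        ("5", 30_000_000, False),
    ])
    def test_region_membership(self, chrom, pos, masked):
        df = _records([dict(CHR=chrom, POS=pos)])
        kept, hla = mask_hla(df)
        assert (len(hla) == 1) is masked
        assert len(kept) + len(hla) == 1


def _clump_oracle(positions, window):
    """Brute-force union-find on the pairwise-within-window graph."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    groups = {}
    labels = []
    for r in roots:
        groups.setdefault(r, len(groups))
        labels.append(groups[r])
    return labels


def _same_partition(a, b):
    return {frozenset(np.flatnonzero(np.asarray(a) == lab))
            for lab in set(a)} == \
           {frozenset(np.flatnonzero(np.asarray(b) == lab))
            for lab in set(b)}


class TestClump:
    def test_two_clump_example(self):
        labels = clump_positions(np.array([1_000_000, 1_150_000, 1_400_000]),
                                 200_000)
        assert labels[0] == labels[1] != labels[2]

    def test_chaining_merges_transitively(self):
        labels = clump_positions(np.array([1_000_000, 1_190_000, 1_380_000]),
                                 200_000)
        assert len(set(labels)) == 1

    def test_singleton(self):
        assert list(clump_positions(np.array([42]), 200_000)) == [0]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=5_000_000),
                    min_size=1, max_size=50))
    def test_matches_union_find_oracle(self, positions):
        positions = np.array(positions)
        labels = clump_positions(positions, 200_000)
        assert _same_partition(labels, _clump_oracle(positions, 200_000))

    def test_mask_commutes_with_clumping(self):
        """Masking then clumping equals clumping the masked record set."""
        rng = np.random.default_rng(0)
        df = _records([dict(CHR="6", POS=int(p))
                       for p in rng.integers(20_000_000, 40_000_000, 40)])
        kept, _ = mask_hla(df)
        direct = clump_qtls(kept)
        spans_direct = {(l.chrom, tuple(sorted(l.snp_ids))) for l in direct}
        # clump first, mask members, re-clump survivors
        survivors = kept
        re = clump_qtls(survivors)
        spans_re = {(l.chrom, tuple(sorted(l.snp_ids))) for l in re}
        assert spans_direct == spans_re

    def test_multiple_genes_rejected(self):
        df = _records([dict(GENE="G1"), dict(GENE="G2")])
        with pytest.raises(StructuralError):
            clump_qtls(df)


class TestAdjustForLd:
    def test_identity_ld_returns_marginals(self):
        betas = np.array([0.2, -0.1, 0.05])
        out = adjust_for_ld(betas, np.eye(3), ridge=0.0)
        np.testing.assert_allclose(out, betas)

    def test_matches_joint_ols_on_simulated_panel(self):
        """(R)^-1 b equals joint least-squares coefficients on a reference
        panel with strong LD, to 0.02 at n=10000."""
        cfg = ArchitectureConfig(n_snps=6, n_blocks=2, block_rho=0.9,
                                 n_core_genes=1, n_null_genes=0,
                                 n_peripheral_loci_per_gene=1, seed=21,
                                 hla_like_region=None, hotspot_n_snps=0)
        truth = sample_architecture(cfg)
        g = simulate_genotypes(cfg, truth, n=10000)
        D = g.dosages[:, :3].astype(float)
        D = (D - D.mean(0)) / D.std(0)
        rng = np.random.default_rng(2)
        y = D @ np.array([0.25, 0.0, -0.1]) + rng.standard_normal(10000)
        marginal = D.T @ y / 10000
        joint = np.linalg.lstsq(D, y, rcond=None)[0]
        adj = adjust_for_ld(marginal, ld_from_genotypes(g, ["rs1", "rs2",
                                                           "rs3"]), ridge=0.0)
        np.testing.assert_allclose(adj, joint, atol=0.02)

    def test_strong_pairwise_ld_example(self):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        w = adjust_for_ld(np.array([0.2, 0.19]), R, ridge=0.0)
        expected = np.linalg.solve(R, np.array([0.2, 0.19]))
        np.testing.assert_allclose(w, expected)

    def test_ridge_shrinks_monotonically(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.array([0.3, 0.1])
        norms = [np.linalg.norm(adjust_for_ld(b, R, ridge=r))
                 for r in (0.0, 0.5, 2.0, 10.0, 100.0)]
        assert all(a > b_ for a, b_ in zip(norms, norms[1:]))
        assert norms[-1] < 0.01

    def test_singular_system_instructs_positive_ridge(self):
        R = np.ones((2, 2))
        with pytest.raises(NumericalError, match="ridge"):
            adjust_for_ld(np.array([0.1, 0.1]), R, ridge=0.0)

    def test_block_diagonal_decomposes(self):
        rng = np.random.default_rng(3)
        A = np.array([[1.0, 0.6], [0.6, 1.0]])
        R = np.block([[A, np.zeros((2, 2))], [np.zeros((2, 2)), A]])
        b = rng.normal(size=4)
        whole = adjust_for_ld(b, R, ridge=0.1)
        parts = np.concatenate([adjust_for_ld(b[:2], A, ridge=0.1),
                                adjust_for_ld(b[2:], A, ridge=0.1)])
        np.testing.assert_allclose(whole, parts, atol=1e-10)

    def test_asymmetric_matrix_rejected(self):
        R = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(StructuralError):
            adjust_for_ld(np.array([0.1, 0.1]), R)


class TestSelection:
    def test_trans_threshold(self):
        df = _records([dict(P=1e-9), dict(P=1e-6), dict(P=0.5)])
        kept = select_trans_qtls(df)
        assert kept["SNP"].tolist() == ["rs1"]

    def test_cis_gate_requires_one_strong_snp(self):
        weak = _records([dict(P=1e-5), dict(P=1e-4)])
        strong = _records([dict(P=1e-5), dict(P=1e-7)])
        assert not cis_score_eligible(weak)
        assert cis_score_eligible(strong)

    def test_empty_input_empty_output(self):
        df = _records([]).reindex(columns=["SNP", "CHR", "POS", "EA", "OA",
                                           "GENE", "GENE_CHR", "GENE_TSS",
                                           "BETA", "SE", "P"])
        assert len(select_trans_qtls(df)) == 0


class TestHarmonize:
    def _meta(self):
        return pd.DataFrame({"id": ["rs1", "rs2", "rs3"],
                             "ea": ["A", "C", "T"],
                             "oa": ["G", "A", "G"]})

    def test_matching_alleles_kept(self):
        df = _records([dict(SNP="rs1", EA="A", OA="G")])
        out, rep = harmonize_alleles(df, self._meta())
        assert rep["kept"] == 1 and rep["flipped"] == 0
        assert out["BETA"].iloc[0] == pytest.approx(0.1)

    def test_swapped_alleles_flip_sign(self):
        df = _records([dict(SNP="rs1", EA="G", OA="A", BETA=0.2)])
        out, rep = harmonize_alleles(df, self._meta())
        assert rep["flipped"] == 1
        assert out["BETA"].iloc[0] == pytest.approx(-0.2)

    def test_ambiguous_and_mismatch_dropped(self):
        df = _records([dict(SNP="rs2", EA="C", OA="G"),    # ambiguous
                       dict(SNP="rs3", EA="T", OA="C"),    # mismatch
                       dict(SNP="rs9", EA="A", OA="G")])   # missing
        out, rep = harmonize_alleles(df, self._meta())
        assert len(out) == 0
        assert (rep["ambiguous"], rep["mismatch"], rep["missing"]) == (1, 1, 1)


def test_build_catalog_counts_reconcile(study_small):
    cat = build_catalog(study_small.summary_stats,
                        study_small.ref_genotypes)
    rep = cat.report
    assert rep["input"] == rep["kept"] + rep["ambiguous"] + \
        rep["mismatch"] + rep["missing"]
    assert rep["kept"] == rep["n_trans"] + rep["n_cis"] + rep["n_hla_masked"]
    # every adjusted locus has weights matching its member count
    for loci in cat.trans_loci.values():
        for locus in loci:
            assert len(locus.adjusted_weights) == locus.n_snps
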