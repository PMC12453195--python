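import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from mycophylo import (
    Alignment,
    association_matrix,
    cailliez_constant,
    cluster_otus,
    cophylogeny_scan,
    dereplicate,
    dual_test_fdr,
    fpr_validation,
    genus_scan,
    jc_distance,
    neighbor_joining,
    p_distance,
    paco,
    parafit,
    patristic_distances,
    pcoa_cailliez,
    quasiswap_null,
    read_alignment_fasta,
    write_alignment_fasta,
)
from mycophylo.cophylogeny import HOMINIDS

from conftest import merge_genus_alignment, random_binary_tree


def _aln(seqs, hosts=None, genus="G", otus=None):
    ids = [f"q{i}" for i in range(len(seqs))]
    hosts = hosts or ["Homo_sapiens"] * len(seqs)
    return Alignment(ids, seqs, hosts, genus, otus or [])


class TestAlignment:
    def test_validation(self):
        with pytest.raises(ValueError, match="lengths"):
            _aln(["ACGT", "ACG"])
        with pytest.raises(ValueError, match="characters"):
            _aln(["ACGT", "ACXT"])
        with pytest.raises(ValueError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"], ["h", "h"])
        with pytest.raises(ValueError, match=">= 2"):
            Alignment(["a"], ["ACGT"], ["h"])

    def test_fasta_round_trip(self, tmp_path):
        aln = Alignment(["s1", "s2"], ["ACGT", "AC-T"],
                        ["Homo_sapiens", "Pan_troglodytes"], "Pichia",
                        ["otu1", "otu1"])
        p = tmp_path / "a.fasta"
        write_alignment_fasta(aln, p)
        back = read_alignment_fasta(p)
        assert len(back) == 1
        b = back[0]
        assert (b.ids, b.seqs, b.hosts, b.genus, b.otus) == (
            aln.ids, aln.seqs, aln.hosts, aln.genus, aln.otus)

    def test_fasta_multiple_genera_split(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a|host=h1|genus=G1\nACGT\n>b|host=h1|genus=G1\nACGA\n"
                     ">c|host=h2|genus=G2\nTTTT\n>d|host=h2|genus=G2\nTTTA\n")
        out = read_alignment_fasta(p)
        assert sorted(a.genus for a in out) == ["G1", "G2"]


class TestDistances:
    def test_p_distance_hand_value(self):
        dm = p_distance(_aln(["ACGT", "ACGA"]))
        assert dm[("q0", "q1")] == pytest.approx(0.25)

    def test_gap_sites_excluded_pairwise(self):
        # comparable sites: positions 2,3 -> 1 difference of 2
        dm = p_distance(_aln(["--GT", "ACGA"]))
        assert dm[("q0", "q1")] == pytest.approx(0.5)

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(_aln(["AC--", "--GT"]))

    def test_jc_hand_value(self):
        # p = 0.1 -> d = -(3/4) ln(1 - 4*0.1/3) = 0.107326
        seq1 = "A" * 10
        seq2 = "A" * 9 + "C"
        dm = jc_distance(_aln([seq1, seq2]))
        assert dm[("q0", "q1")] == pytest.approx(0.1073256, abs=1e-5)

    def test_jc_saturation_is_error(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance(_aln(["AAAA", "CCCC"]))

    def test_jc_at_least_p(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        # force moderate similarity to stay below saturation
        base = seqs[0]
        seqs = [base[:40] + s[40:] for s in seqs]
        pdm, jdm = p_distance(_aln(seqs)), jc_distance(_aln(seqs))
        assert (jdm.data >= pdm.data - 1e-12).all()


class TestTrees:
    def test_nj_recovers_additive_distances(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            tree = random_binary_tree(rng, 7)
            dm = tree.tip_tip_distances()
            rebuilt = neighbor_joining(dm)
            dm2 = patristic_distances(rebuilt)
            ids = list(dm.ids)
            assert np.allclose(dm2.filter(ids).data, dm.data, atol=1e-8)

    def test_nj_nan_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 1.0
        d[0, 2] = d[2, 0] = np.nan
        with pytest.raises(Exception):
            neighbor_joining(DistanceMatrix(np.nan_to_num(d) * np.nan,
                                            ids=list("abcd")))

    def test_patristic_two_leaf_sum(self):
        from skbio import TreeNode

        t = TreeNode.read(["(a:1,b:2);"])
        assert patristic_distances(t)[("a", "b")] == pytest.approx(3.0)

    def test_patristic_missing_length_is_error(self):
        from skbio import TreeNode

        t = TreeNode.read(["((a:1,b:2),c:1);"])
        with pytest.raises(ValueError, match="missing"):
            patristic_distances(t)


class TestDereplicateCluster:
    def test_dereplicate_merges_and_keeps_hosts(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "ACGT", "TTTT"],
                        ["h1", "h2", "h1"], "G")
        out = dereplicate(aln)
        assert out.ids == ["a", "c"]
        assert out.provenance[0] == [("a", "h1"), ("b", "h2")]

    def test_dereplicate_no_duplicates_identity(self):
        aln = _aln(["ACGT", "ACGA", "TTTT"])
        out = dereplicate(aln)
        assert out.ids == aln.ids

    def test_cluster_otus_threshold(self):
        # q0/q1 identical at 99%, q2 only 50% identical
        base = "A" * 100
        seqs = [base, base[:-1] + "C", "A" * 50 + "C" * 50]
        assign = cluster_otus(_aln(seqs), identity=0.97)
        assert assign[0] == assign[1] != assign[2]

    def test_cluster_otus_identity_one_exact_only(self):
        base = "A" * 100
        assign = cluster_otus(_aln([base, base, base[:-1] + "C"]),
                              identity=1.0)
        assert assign[0] == assign[1] != assign[2]

    def test_cluster_otus_bad_identity(self):
        with pytest.raises(ValueError):
            cluster_otus(_aln(["AC", "AG"]), identity=0.0)


class TestGenusScan:
    def test_blacklisted_genus_excluded(self, cospeciating_otus):
        aln = merge_genus_alignment(cospeciating_otus, genus="Aspergillus")
        assert genus_scan([aln]) == []

    def test_genus_missing_a_hominid_excluded(self, cospeciating_otus):
        aln = merge_genus_alignment(cospeciating_otus)
        keep = [i for i, h in enumerate(aln.hosts) if h != "Homo_sapiens"]
        assert genus_scan([aln.subset(keep)]) == []

    def test_cospeciating_fixture_yields_eligible_otus(self, cospeciating_otus):
        aln = merge_genus_alignment(cospeciating_otus)
        otus = genus_scan([aln])
        assert len(otus) >= 1
        for otu in otus:
            a = association_matrix(otu)
            assert (a.sum(axis=1) >= 1).all()  # every hominid linked

    def test_otu_not_spanning_hominids_excluded(self, cospeciating_otus):
        # keep one OTU complete, restrict the other to two hominids
        keys = sorted(cospeciating_otus)
        full = cospeciating_otus[keys[0]]
        partial = cospeciating_otus[keys[1]]
        keep = [i for i, h in enumerate(partial.hosts)
                if h in ("Homo_sapiens", "Pan_troglodytes")]
        merged = merge_genus_alignment({"a": full, "b": partial.subset(keep)})
        otus = genus_scan([merged])
        assert {o.otu_id for o in otus} <= set(full.otus)


class TestCailliezPcoa:
    # Frozen reference: ape::pcoa(correction="cailliez") on this matrix
    # reports the additive constant 1.4142135623731.
    D = np.array([[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]],
                 dtype=float)

    def test_constant_matches_ape(self):
        assert cailliez_constant(self.D) == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_euclidean_matrix_zero_constant(self):
        pts = np.random.default_rng(2).normal(size=(5, 3))
        from scipy.spatial.distance import pdist, squareform

        assert cailliez_constant(squareform(pdist(pts))) == 0.0

    def test_embedding_reproduces_corrected_dissimilarities(self):
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(self.D, ids=list("abcd"))
        x = pcoa_cailliez(dm).to_numpy()
        emb = squareform(pdist(x))
        c = cailliez_constant(self.D)
        expected = (self.D + c) * (1 - np.eye(4))
        assert np.allclose(emb, expected, atol=1e-10)

    def test_euclidean_embedding_exact(self):
        from scipy.spatial.distance import pdist, squareform

        pts = np.random.default_rng(3).normal(size=(6, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"p{i}" for i in range(6)])
        x = pcoa_cailliez(dm).to_numpy()
        assert np.allclose(squareform(pdist(x)), d, atol=1e-10)


class TestQuasiswap:
    def test_margins_preserved_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = (rng.random((5, 8)) < 0.4).astype(np.int8)
            b = quasiswap_null(a, seed=int(rng.integers(2**31)))
            assert (a.sum(axis=0) == b.sum(axis=0)).all()
            assert (a.sum(axis=1) == b.sum(axis=1)).all()
            assert np.isin(b, (0, 1)).all()

    def test_reaches_multiple_states(self):
        a = np.eye(3, dtype=np.int8)
        seen = set()
        for s in range(100):
            seen.add(quasiswap_null(a, seed=s).tobytes())
        assert len(seen) > 1

    def test_all_permutation_matrices_reachable(self):
        # 3x3 with unit margins admits exactly the 6 permutation matrices
        a = np.eye(3, dtype=np.int8)
        seen = set()
        for s in range(400):
            b = quasiswap_null(a, seed=s)
            assert (b.sum(axis=0) == 1).all() and (b.sum(axis=1) == 1).all()
            seen.add(b.tobytes())
        assert len(seen) == 6

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            quasiswap_null(np.array([[0, 2], [1, 0]]))

    def test_dataframe_io_preserves_labels(self):
        df = pd.DataFrame(np.eye(3, dtype=np.int8), index=list("xyz"),
                          columns=list("abc"))
        out = quasiswap_null(df, seed=0)
        assert list(out.index) == list("xyz")
        assert list(out.columns) == list("abc")


def _toy_host_dm():
    d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
    return DistanceMatrix(d, ids=["H1", "H2", "H3"])


def _toy_para_dm():
    d = np.array([[0, 1, 4, 5], [1, 0, 4, 5], [4, 4, 0, 2], [5, 5, 2, 0]],
                 dtype=float)
    return DistanceMatrix(d, ids=["P1", "P2", "P3", "P4"])


def _toy_assoc():
    return pd.DataFrame([[1, 0, 0, 1], [0, 1, 0, 0], [0, 0, 1, 1]],
                        index=["H1", "H2", "H3"],
                        columns=["P1", "P2", "P3", "P4"])


class TestPacoParafit:
    def test_parafit_matches_ape_reference(self):
        # Frozen reference: ape::parafit with cailliez correction on these
        # inputs gives ParaFitGlobal = 437.0833.
        res = parafit(_toy_host_dm(), _toy_para_dm(), _toy_assoc(),
                      nperm=9, seed=0)
        assert res.stat == pytest.approx(437.0833, abs=1e-3)

    def test_paco_identical_trees_perfect_fit(self, host_tree):
        sheared = host_tree.shear(list(HOMINIDS))
        hdm = patristic_distances(sheared)
        fdm = DistanceMatrix(hdm.data, ids=[f"f_{h}" for h in hdm.ids])
        assoc = pd.DataFrame(np.eye(4, dtype=int), index=list(hdm.ids),
                             columns=list(fdm.ids))
        res = paco(hdm, fdm, assoc, nperm=99, seed=5)
        assert res.m2 == pytest.approx(0.0, abs=1e-10)
        assert res.R2 == pytest.approx(1.0, abs=1e-10)
        # the ultrametric host distances make (Homo, Pan) and the two
        # gorillas exchangeable, so some null permutations tie at m2 = 0
        # and p cannot saturate; it should still lean significant
        assert res.p_value <= 0.5

    def test_paco_m2_in_unit_interval(self):
        res = paco(_toy_host_dm(), _toy_para_dm(), _toy_assoc(),
                   nperm=19, seed=6)
        assert 0 <= res.m2 <= 1
        assert res.R2 == pytest.approx(1 - res.m2)

    def test_paco_empty_column_rejected(self):
        assoc = _toy_assoc()
        assoc["P2"] = 0
        with pytest.raises(ValueError, match="no links"):
            paco(_toy_host_dm(), _toy_para_dm(), assoc, nperm=9)

    def test_bad_nperm_rejected(self):
        with pytest.raises(ValueError):
            paco(_toy_host_dm(), _toy_para_dm(), _toy_assoc(), nperm=0)
        with pytest.raises(ValueError):
            parafit(_toy_host_dm(), _toy_para_dm(), _toy_assoc(), nperm=0)

    def test_paco_reproducible(self):
        a = paco(_toy_host_dm(), _toy_para_dm(), _toy_assoc(), nperm=49, seed=7)
        b = paco(_toy_host_dm(), _toy_para_dm(), _toy_assoc(), nperm=49, seed=7)
        assert (a.m2, a.p_value) == (b.m2, b.p_value)

    def test_parafit_p_valid_under_shuffled_columns(self):
        # shuffling host assignments per fungal tip is the ParaFit null,
        # so p-values must be valid: P(p <= alpha) <= alpha (+ MC slack)
        rng = np.random.default_rng(8)
        a0 = _toy_assoc().to_numpy()
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = a0.copy()
            for j in range(a.shape[1]):
                a[:, j] = rng.permutation(a[:, j])
            assoc = pd.DataFrame(a, index=["H1", "H2", "H3"],
                                 columns=["P1", "P2", "P3", "P4"])
            res = parafit(_toy_host_dm(), _toy_para_dm(), assoc, nperm=99,
                          seed=int(rng.integers(2**31)))
            hits += res.p_value <= 0.05
        assert hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestDualGateAndScan:
    def test_dual_gate_requires_both(self):
        df = pd.DataFrame({
            "paco_p": [0.01, 0.01, 0.8],
            "parafit_p": [0.01, 0.9, 0.01],
        })
        out = dual_test_fdr(df, alpha=0.05)
        assert list(out["pass"]) == [True, False, False]

    def test_dual_gate_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        df = pd.DataFrame({"paco_p": rng.uniform(size=12),
                           "parafit_p": rng.uniform(size=12)})
        out = dual_test_fdr(df)
        assert np.allclose(out["q_paco"],
                           multipletests(df["paco_p"], method="fdr_bh")[1])

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            dual_test_fdr(pd.DataFrame({"paco_p": [], "parafit_p": []}))

    def test_scan_detects_cospeciation(self, host_tree, cospeciating_otus):
        aln = merge_genus_alignment(cospeciating_otus)
        otus = genus_scan([aln])
        table = cophylogeny_scan(otus, host_tree, nperm=99, seed=10)
        assert len(table) == len(otus)
        # perfectly cospeciating sequences should mostly pass the dual gate
        assert table["pass"].mean() >= 0.5
        assert ((table["paco_R2"] > 0) & (table["paco_R2"] <= 1)).all()

    def test_fpr_validation_shapes_and_gate(self, host_tree, cospeciating_otus):
        aln = merge_genus_alignment(cospeciating_otus)
        otus = genus_scan([aln])[:2]
        fpr_raw, fpr_fdr, table = fpr_validation(
            otus, host_tree, n_shuffles=10, nperm=49, seed=11)
        assert len(table) == 10 * len(otus)
        assert 0 <= fpr_fdr <= fpr_raw <= 1
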