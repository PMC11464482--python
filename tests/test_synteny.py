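import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import make_genes
from mantlescreen.formats import FormatError, GeneModel, HitRecord
from mantlescreen.synteny import (
    AnchorPair,
    SyntenyParams,
    align_proteins,
    all_vs_all_hits,
    call_anchors,
    chain_collinear,
    find_conserved_modules,
)
from mantlescreen.cismap import pair_within_window

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a, b, open_cost=12, extend_cost=1):
    """Brute-force Gotoh local alignment score (gap of length k costs
    open_cost + (k-1)*extend_cost), independent of the library path."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestAlignProteins:
    def test_identical_sequence_scores_sum_of_self_scores(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        out = align_proteins(seq, seq)
        assert out["percent_identity"] == 100.0
        assert out["score"] == sum(BLOSUM62[c, c] for c in seq)

    def test_matches_independent_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert align_proteins(a, b)["score"] == sw_affine_oracle(a, b)

    @pytest.mark.parametrize(
        "a,b", [("MKVLA", "MKVLA"), ("WWWWHHHH", "HHWWH"), ("ACDEFG", "GFEDCA")]
    )
    def test_oracle_agreement_more_cases(self, a, b):
        assert align_proteins(a, b)["score"] == sw_affine_oracle(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(FormatError):
            align_proteins("", "MKV")

    def test_unrelated_sequences_fail_evalue_ceiling(self):
        """Random 50-mers almost never reach e <= 1e-5."""
        rng = np.random.default_rng(123)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        n_pass = 0
        trials = 200
        for _ in range(trials):
            a = "".join(rng.choice(aa, 50))
            b = "".join(rng.choice(aa, 50))
            if align_proteins(a, b)["evalue"] <= 1e-5:
                n_pass += 1
        assert n_pass <= trials * 0.01


def hit(q, s, ev=1e-10, bits=100.0, ident=90.0):
    return HitRecord(q, s, ident, 100, ev, bits)


def genes_on(chrom, ids, biotype="coding", spacing=10_000, length=2_000):
    spec = [
        (gid, chrom, 1 + i * spacing, 1 + i * spacing + length, "+", biotype)
        for i, gid in enumerate(ids)
    ]
    return make_genes(spec)


class TestCallAnchors:
    def setup_method(self):
        self.ga = genes_on("a1", ["A1", "A2"])
        self.gb = genes_on("b1", ["B1", "B2"])

    def test_reciprocal_best_hit_becomes_anchor(self):
        anchors = call_anchors([hit("A1", "B1")], self.ga, self.gb)
        assert [(a.gene_a.gene_id, a.gene_b.gene_id) for a in anchors] == [("A1", "B1")]

    def test_non_reciprocal_best_is_dropped(self):
        hits = [
            hit("A1", "B1", bits=100),
            hit("A2", "B1", bits=200),  # B1's best is A2
            hit("A2", "B2", bits=50),
        ]
        anchors = call_anchors(hits, self.ga, self.gb)
        pairs = {(a.gene_a.gene_id, a.gene_b.gene_id) for a in anchors}
        assert ("A1", "B1") not in pairs and ("A2", "B1") in pairs

    def test_evalue_above_ceiling_excluded(self):
        anchors = call_anchors([hit("A1", "B1", ev=1e-4)], self.ga, self.gb)
        assert anchors == []

    def test_gene_missing_from_annotation_is_error(self):
        with pytest.raises(FormatError, match="ZZ"):
            call_anchors([hit("ZZ", "B1")], self.ga, self.gb)


def anchors_from_rank_pairs(pairs, chrom_a="a1", chrom_b="b1"):
    out = []
    for i, (ra, rb) in enumerate(pairs):
        ga = GeneModel(f"A{i}", chrom_a, 1 + ra * 1000, 500 + ra * 1000, "+",
                       "coding", rank=ra)
        gb = GeneModel(f"B{i}", chrom_b, 1 + rb * 1000, 500 + rb * 1000, "+",
                       "coding", rank=rb)
        out.append(AnchorPair(ga, gb, score=100.0, evalue=1e-20))
    return out


def chain_oracle(pairs, params):
    """Exhaustive maximum-score collinear chain over both orientations.

    Enumerates every anchor subset (ordered by A rank, which any valid
    chain must follow), keeps those monotone on B with per-step rank gaps
    <= max_gap and at least min_anchors long, and returns (best score,
    list of best-chain membership sets)."""
    n = len(pairs)
    best_score = float("-inf")
    best_sets = []
    for r in range(params.min_anchors, n + 1):
        for combo in itertools.combinations(range(n), r):
            ordered = sorted(combo, key=lambda i: pairs[i][0])
            ras = [pairs[i][0] for i in ordered]
            rbs = [pairs[i][1] for i in ordered]
            diffs = [rbs[j + 1] - rbs[j] for j in range(r - 1)]
            if any(d == 0 for d in diffs):
                continue
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                continue
            score = params.match_score * r
            steps_ok = True
            for j in range(r - 1):
                ga = ras[j + 1] - ras[j] - 1
                gb = abs(rbs[j + 1] - rbs[j]) - 1
                if ga > params.max_gap or gb > params.max_gap:
                    steps_ok = False
                    break
                score -= params.gap_penalty * (ga + gb)
            if not steps_ok:
                continue
            if score > best_score + 1e-9:
                best_score = score
                best_sets = [frozenset(combo)]
            elif abs(score - best_score) <= 1e-9:
                best_sets.append(frozenset(combo))
    return best_score, best_sets


class TestChainCollinear:
    def test_perfect_diagonal_gives_one_block(self):
        anchors = anchors_from_rank_pairs([(i, i) for i in range(1, 6)])
        blocks = chain_collinear(anchors)
        assert len(blocks) == 1
        b = blocks[0]
        assert len(b.anchors) == 5 and b.orientation == "same"
        assert b.score == 5 * 50.0

    def test_four_anchors_below_minimum_no_block(self):
        anchors = anchors_from_rank_pairs([(i, i) for i in range(1, 5)])
        assert chain_collinear(anchors) == []

    def test_large_rank_gap_breaks_chain(self):
        pairs = [(1, 1), (2, 30), (3, 31), (4, 32), (5, 33), (6, 34)]
        blocks = chain_collinear(anchors_from_rank_pairs(pairs))
        assert len(blocks) == 1
        members = {a.gene_b.rank for a in blocks[0].anchors}
        assert members == {30, 31, 32, 33, 34}  # (1,1) excluded by the 28-rank gap

    def test_inverted_block_detected(self):
        pairs = [(i, 10 - i) for i in range(1, 6)]
        blocks = chain_collinear(anchors_from_rank_pairs(pairs))
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_reversing_b_axis_swaps_orientation_same_score(self):
        pairs = [(i, i) for i in range(1, 7)]
        fwd = chain_collinear(anchors_from_rank_pairs(pairs))
        rev = chain_collinear(anchors_from_rank_pairs([(a, 20 - b) for a, b in pairs]))
        assert fwd[0].orientation == "same" and rev[0].orientation == "inverted"
        assert fwd[0].score == rev[0].score

    def test_blocks_are_anchor_disjoint(self):
        rng = np.random.default_rng(5)
        pairs = [tuple(x) for x in rng.integers(0, 40, size=(60, 2))]
        pairs = list({p for p in pairs})
        blocks = chain_collinear(anchors_from_rank_pairs(pairs),
                                 SyntenyParams(min_anchors=3))
        seen = set()
        for b in blocks:
            for a in b.anchors:
                key = (a.gene_a.gene_id, a.gene_b.gene_id)
                assert key not in seen
                seen.add(key)

    def test_matches_exhaustive_oracle_on_small_instances(self):
        """DP chain score and membership equal brute-force enumeration."""
        params = SyntenyParams(min_anchors=2, max_gap=4, match_score=10.0)
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            ras = rng.permutation(12)[:n]
            rbs = rng.permutation(12)[:n]
            pairs = list(zip(ras.tolist(), rbs.tolist()))
            best, best_sets = chain_oracle(pairs, params)
            blocks = chain_collinear(anchors_from_rank_pairs(pairs), params)
            if not best_sets:
                assert blocks == []
                continue
            assert blocks, f"oracle found a chain of score {best}, DP found none"
            top = max(blocks, key=lambda b: b.score)
            assert top.score == pytest.approx(best)
            idx = {(p[0], p[1]): i for i, p in enumerate(pairs)}
            members = frozenset(
                idx[(a.gene_a.rank, a.gene_b.rank)] for a in top.anchors
            )
            assert members in best_sets

    def test_self_comparison_full_length_blocks(self):
        genes = genes_on("c1", [f"G{i}" for i in range(8)])
        anchors = [AnchorPair(g, g, 200.0, 1e-30) for g in genes]
        blocks = chain_collinear(anchors)
        assert len(blocks) == 1 and len(blocks[0].anchors) == 8


class TestConservedModules:
    def fixture(self, with_target_lnc=True):
        src_coding = genes_on("chr1", [f"s{i}" for i in range(8)], spacing=20_000)
        lnc = GeneModel("lncA", "chr1", 85_000, 86_000, "+", "lncRNA", rank=0)
        modules = pair_within_window([lnc], src_coding, window=100_000)
        assert modules
        tgt_ids = [f"t{i}" for i in range(8)]
        tgt_genes = genes_on("chrT", tgt_ids, spacing=20_000)
        anchors = [
            AnchorPair(sa, tb, 300.0, 1e-40)
            for sa, tb in zip(src_coding, tgt_genes)
        ]
        blocks = chain_collinear(anchors)
        lnc_seq = (
            "TAAATAAATAAATTTATTTATTTA" * 20
        )[:400] + "ACGT" * 25  # > 200 nt, ORF-free
        transcripts = {}
        genes = list(tgt_genes)
        if with_target_lnc:
            tlnc = GeneModel("t_lncA", "chrT", 90_000, 91_000, "+", "lncRNA", rank=0)
            genes.append(tlnc)
            transcripts["t_lncA"] = lnc_seq
        return modules, blocks, genes, transcripts, {"lncA": lnc_seq}, anchors

    def test_planted_collinear_module_is_conserved(self):
        mods, blocks, genes, tx, lseq, anchors = self.fixture()
        out = find_conserved_modules(mods, blocks, "spT", genes, tx, lseq,
                                     anchors=anchors)
        assert out[0].status == "conserved"
        assert out[0].lnc_orthologue == "t_lncA"
        assert out[0].identity == pytest.approx(100.0)

    def test_missing_lnc_locus_reported(self):
        mods, blocks, genes, tx, lseq, anchors = self.fixture(with_target_lnc=False)
        out = find_conserved_modules(mods, blocks, "spT", genes, tx, lseq,
                                     anchors=anchors)
        assert out[0].status == "no_lncRNA_orthologue"

    def test_partner_without_anchor_reported(self):
        mods, blocks, genes, tx, lseq, _ = self.fixture()
        out = find_conserved_modules(mods, blocks, "spT", genes, tx, lseq,
                                     anchors=[])
        assert out[0].status == "no_anchor"

    def test_anchor_outside_any_block_reported(self):
        mods, _, genes, tx, lseq, anchors = self.fixture()
        out = find_conserved_modules(mods, [], "spT", genes, tx, lseq,
                                     anchors=anchors)
        assert out[0].status == "not_in_block"


def test_all_vs_all_hits_finds_diverged_orthologues():
    """90 %-identical orthologues pass the seed filter and e-value ceiling."""
    rng = np.random.default_rng(8)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    prots_a = {f"a{i}": "".join(rng.choice(aa, 200)) for i in range(10)}
    prots_b = {}
    for i, (k, seq) in enumerate(prots_a.items()):
        arr = np.array(list(seq))
        mask = rng.random(len(arr)) < 0.10
        arr[mask] = rng.choice(aa, int(mask.sum()))
        prots_b[f"b{i}"] = "".join(arr)
    hits = all_vs_all_hits(prots_a, prots_b)
    pairs = {(h.query_id, h.subject_id) for h in hits}
    assert all((f"a{i}", f"b{i}") in pairs for i in range(10))
    by_pair = {(h.query_id, h.subject_id): h for h in hits}
    idents = [by_pair[(f"a{i}", f"b{i}")].percent_identity for i in range(10)]
    assert all(80.0 <= x <= 100.0 for x in idents)
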