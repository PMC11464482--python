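import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mantlescreen.formats import ExpressionPanel, FormatError, SampleMeta
from mantlescreen.screen import (
    asym_stage_fraction,
    asym_stage_fraction_table,
    combine_candidacy,
    damage_response,
    longest_orf_codons,
    mantle_fraction,
    mantle_fraction_table,
    motif_enrichment,
    shared_domain_sets,
    smp_crossref,
    verify_lncrna,
)

RNG = np.random.default_rng(77)
BASES = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_dna(n, rng=RNG):
    return "".join(rng.choice(BASES, n))


def orf_free_dna(n):
    """DNA with stop codons phased so no strand carries an ORF >= ~8 codons."""
    unit = "TAAATAAATAAATTTATTTATTTA"
    return (unit * (n // len(unit) + 1))[:n]


class TestVerifyLncrna:
    def test_short_transcript_fails_length_rule(self):
        v = verify_lncrna("t1", orf_free_dna(150))
        assert v.length_nt == 150 and not v.verdict

    def test_long_orf_fails(self):
        # 116-codon ORF (ATG + 115 codons + stop = 351 nt) inside 500 nt
        orf = "ATG" + "GCT" * 115 + "TAA"
        seq = orf_free_dna(80) + orf + orf_free_dna(69)
        v = verify_lncrna("t2", seq)
        assert v.longest_orf_codons == 116 and not v.verdict

    def test_clean_long_transcript_passes(self):
        v = verify_lncrna("t3", orf_free_dna(500))
        assert v.verdict and v.longest_orf_codons < 10

    def test_domain_hit_vetoes(self):
        assert not verify_lncrna("t4", orf_free_dna(500), has_domain_hit=True).verdict

    def test_empty_sequence_is_error(self):
        with pytest.raises(FormatError):
            verify_lncrna("t5", "")

    def test_orf_found_on_reverse_strand(self):
        orf = "ATG" + "GAA" * 30 + "TGA"
        fwd = orf_free_dna(60) + orf + orf_free_dna(60)
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert longest_orf_codons(rc) == 31


def tissue_panel(values_by_tissue, reps=1):
    """FPKM panel: {tissue: per-gene value} with identical replicates."""
    metas, cols = [], {}
    for tissue, vals in values_by_tissue.items():
        for r in range(1, reps + 1):
            sid = f"{tissue}_r{r}"
            metas.append(SampleMeta(sample_id=sid, tissue=tissue, replicate=r))
            cols[sid] = vals
    n = len(next(iter(values_by_tissue.values())))
    df = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)], dtype=float)
    return ExpressionPanel(df, metas, unit="FPKM")


def stage_panel(values_by_stage):
    metas, cols = {}, []
    data = {}
    metas = []
    for stage, vals in values_by_stage.items():
        sid = f"{stage}_r1"
        metas.append(SampleMeta(sample_id=sid, stage=stage, tissue="larva"))
        data[sid] = vals
    n = len(next(iter(values_by_stage.values())))
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(n)], dtype=float)
    return ExpressionPanel(df, metas, unit="FPKM")


class TestMantleFraction:
    def test_dominant_mantle_share_passes(self):
        panel = tissue_panel({"mantle": [80.0], "gill": [10.0], "muscle": [10.0]})
        frac, passed = mantle_fraction(panel, "g0")
        assert frac == pytest.approx(0.8) and passed

    def test_uniform_expression_fails(self):
        panel = tissue_panel({t: [5.0] for t in ("mantle", "gill", "muscle", "gonad", "dg")})
        frac, passed = mantle_fraction(panel, "g0")
        assert frac == pytest.approx(0.2) and not passed

    def test_silent_gene_flagged_and_fails(self):
        panel = tissue_panel({"mantle": [0.0], "gill": [0.0]})
        tab = mantle_fraction_table(panel)
        assert not tab.loc["g0", "defined"] and not tab.loc["g0", "passes"]

    def test_unequal_replicates_use_per_tissue_means(self):
        # 3 mantle replicates vs 1 gill replicate: denominator is the sum of
        # per-tissue means, not per-sample values
        metas = [
            SampleMeta(sample_id="m1", tissue="mantle"),
            SampleMeta(sample_id="m2", tissue="mantle"),
            SampleMeta(sample_id="m3", tissue="mantle"),
            SampleMeta(sample_id="g1", tissue="gill"),
        ]
        df = pd.DataFrame(
            {"m1": [60.0], "m2": [80.0], "m3": [100.0], "g1": [20.0]}, index=["g0"]
        )
        panel = ExpressionPanel(df, metas, unit="FPKM")
        frac, _ = mantle_fraction(panel, "g0")
        assert frac == pytest.approx(80.0 / 100.0)


class TestAsymStageFraction:
    def test_asymmetric_dominance_passes(self):
        panel = stage_panel({"pediveliger": [90.0], "veliger": [10.0]})
        frac, passed = asym_stage_fraction(panel, "g0")
        assert frac == pytest.approx(0.9) and passed

    def test_even_split_fails(self):
        panel = stage_panel({"spat": [50.0], "d_larva": [50.0]})
        frac, passed = asym_stage_fraction(panel, "g0")
        assert frac == pytest.approx(0.5) and not passed

    def test_symmetric_only_expression_is_zero(self):
        panel = stage_panel({"juvenile": [0.0], "trochophore": [30.0]})
        frac, passed = asym_stage_fraction(panel, "g0")
        assert frac == 0.0 and not passed


class TestCandidacy:
    def crit(self, rows):
        return pd.DataFrame(
            rows, columns=["crit_mantle", "crit_stage", "crit_damage"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_all_three_criteria_make_a_candidate(self):
        cands, venn = combine_candidacy(self.crit([[True, True, True]]))
        assert cands[0].is_candidate
        assert venn["mantle&stage&damage"] == 1

    def test_two_of_three_fails_default_rule(self):
        cands, venn = combine_candidacy(self.crit([[True, False, True]]))
        assert not cands[0].is_candidate
        assert venn["mantle&damage"] == 1

    def test_union_rule(self):
        cands, _ = combine_candidacy(self.crit([[True, False, False]]), rule="union")
        assert cands[0].is_candidate

    def test_empty_input_empty_venn(self):
        cands, venn = combine_candidacy(self.crit([]))
        assert cands == [] and sum(venn.values()) == 0

    def test_venn_counts_sum_to_genes_with_any_criterion(self):
        rng = np.random.default_rng(3)
        rows = rng.random((40, 3)) < 0.5
        cands, venn = combine_candidacy(self.crit(rows.tolist()))
        assert sum(venn.values()) == int(rows.any(axis=1).sum())

    def test_lowering_tau_never_removes_candidates(self):
        """Candidacy is monotone in the abundance thresholds."""
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 100, (30, 5))
        panel = tissue_panel(
            {t: vals[:, i] for i, t in enumerate(["mantle", "gill", "muscle", "gonad", "dg"])}
        )
        prev = None
        for tau in (0.9, 0.7, 0.5, 0.3, 0.1):
            passing = set(
                mantle_fraction_table(panel, tau=tau).query("passes").index
            )
            if prev is not None:
                assert prev <= passing
            prev = passing


class TestSharedDomains:
    def test_pairwise_intersection(self):
        got = shared_domain_sets(
            {"A": {"WAP", "EGF_CA"}, "B": {"EGF_CA", "CLECT"}}, shared_in=["A", "B"]
        )
        assert got == {"EGF_CA"}

    def test_shell_proteome_domain_overlap(self):
        # Of the twelve shell-matrix-protein domains seen in the oyster
        # mantle, only EGF_CA and PHA03247 recur in the scallop DE set
        mgigas_smp = {
            "WAP", "Tyrosinase", "GH20_hexosaminidase", "GH20_hydro_20b",
            "CHB_HEX", "EFh", "VWC", "EGF_CA", "LPMO_10", "PHA03247",
            "PRK10263", "PAT1",
        }
        other = {"EGF_CA", "PHA03247", "CLECT", "Carb_anhydrase"}
        got = shared_domain_sets(
            {"mg": mgigas_smp, "my": other}, shared_in=["mg", "my"]
        )
        assert got == {"EGF_CA", "PHA03247"}

    def test_disjoint_sets_empty(self):
        assert (
            shared_domain_sets({"A": {"x"}, "B": {"y"}}, shared_in=["A", "B"]) == set()
        )

    def test_absent_from_subtracts(self):
        got = shared_domain_sets(
            {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"y"}},
            shared_in=["A", "B"], absent_from=["C"],
        )
        assert got == {"x"}


def random_protein(n, rng):
    return "".join(rng.choice(AA, n))


class TestMotifEnrichment:
    def test_perfect_separation_matches_hypergeometric(self):
        """10/10 vs 0/10 motif: one-sided hypergeometric p = 1/C(20,10)."""
        rng = np.random.default_rng(4)
        flat = {f"f{i}": random_protein(60, rng) + "LGAAGAAG" for i in range(10)}
        rnd = {f"r{i}": random_protein(68, rng) for i in range(10)}
        results = motif_enrichment(flat, rnd)
        by_pat = {r.pattern: r for r in results}
        hit = by_pat["LGXXGXXG"]
        assert (hit.count_flat, hit.count_round) == (10, 0)
        one_sided = 1.0 / 184_756  # = 1/C(20,10), exact hypergeometric
        assert hit.p >= one_sided
        assert hit.p == pytest.approx(stats.fisher_exact([[10, 0], [0, 10]])[1])
        # and the planted gapped pattern ranks at the top padj
        assert hit.padj == min(r.padj for r in results)

    def test_identical_groups_show_no_enrichment(self):
        rng = np.random.default_rng(12)
        prots = {f"p{i}": random_protein(120, rng) for i in range(8)}
        flat = {f"f{i}": s for i, s in enumerate(prots.values())}
        rnd = {f"r{i}": s for i, s in enumerate(prots.values())}
        results = motif_enrichment(flat, rnd)
        assert all(r.padj > 0.05 for r in results)

    def test_fisher_matches_hypergeometric_oracle_small_margins(self):
        """Two-sided Fisher p equals the sum of hypergeometric point masses
        no larger than the observed one, for all margins <= 12."""
        for n1 in (3, 7, 12):
            for n2 in (4, 9):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        k = a + c
                        pmf = stats.hypergeom.pmf(
                            np.arange(0, k + 1), n1 + n2, n1, k
                        )
                        obs = stats.hypergeom.pmf(a, n1 + n2, n1, k)
                        oracle = pmf[pmf <= obs * (1 + 1e-9)].sum()
                        p = stats.fisher_exact([[a, n1 - a], [c, n2 - c]])[1]
                        assert p == pytest.approx(min(oracle, 1.0), rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(FormatError):
            motif_enrichment({}, {"r": "ACDEF"})


class TestSmpCrossref:
    def test_flags_and_regions(self):
        df, venn = smp_crossref(
            ["g1", "g2", "g3"],
            shell_proteome_ids=["g1"],
            secreted_genes=["g1", "g2"],
            asym_domain_genes=[],
        )
        assert bool(df.loc["g1", "SMP"]) and bool(df.loc["g2", "secreted"])
        assert venn["secreted&SMP"] == 1 and venn["secreted"] == 1

    def test_stray_proteome_id_warns(self):
        with pytest.warns(UserWarning, match="gX"):
            smp_crossref(["g1"], ["gX"], [], [])

    def test_empty_proteome_all_false(self):
        df, _ = smp_crossref(["g1", "g2"], [], [], [])
        assert not df["SMP"].any()
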