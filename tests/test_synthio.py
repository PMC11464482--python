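import numpy as np
import pandas as pd
import pytest

from mantlescreen.cismap import edge_distance
from mantlescreen.formats import FormatError
from mantlescreen.screen import longest_orf_codons
from mantlescreen.synthio import (
    SimConfig,
    _nb_draw,
    invert_segment,
    plant_cis_modules,
    read_truth,
    simulate,
    simulate_expression,
    simulate_genomes,
    write_truth,
)

SMALL = dict(n_chroms=2, genes_per_chrom=150, n_planted_modules=4,
             n_conserved_modules=3)


class TestConfigValidation:
    def test_too_many_modules_rejected(self):
        with pytest.raises(FormatError):
            SimConfig(genes_per_chrom=10, n_planted_modules=6)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(FormatError):
            SimConfig(nb_dispersion=0.0)

    def test_module_span_must_stay_below_window(self):
        with pytest.raises(FormatError):
            SimConfig(module_span=150_000)

    def test_conserved_in_bounded_by_targets(self):
        with pytest.raises(FormatError):
            SimConfig(n_species=2, conserved_in=2)


class TestRearrangements:
    def test_no_rearrangement_no_loss_keeps_ancestor_order(self):
        cfg = SimConfig(seed=3, n_rearrangements=0, gene_loss_frac=0.0, **SMALL)
        sim = simulate_genomes(cfg)
        src, der = sim.genomes["sp0"], sim.genomes["sp1"]
        for chrom in src.chroms:
            assert [e["aid"] for e in src.chroms[chrom]] == [
                e["aid"] for e in der.chroms[chrom]
            ]

    def test_invert_segment_reverses_order_and_strands(self):
        entries = [
            {"aid": f"g{i}", "gid": f"g{i}", "length": 100, "strand": "+",
             "biotype": "coding", "gap": 50}
            for i in range(30)
        ]
        out = invert_segment(entries, 10, 11)
        assert [e["aid"] for e in out[10:21]] == [f"g{i}" for i in range(20, 9, -1)]
        assert all(e["strand"] == "-" for e in out[10:21])
        assert [e["aid"] for e in out[:10]] == [f"g{i}" for i in range(10)]


class TestDeterminism:
    def test_identical_seed_gives_identical_genomes_and_truth(self):
        cfg = SimConfig(seed=9, **SMALL)
        r1, r2 = simulate(cfg), simulate(cfg)
        for sp in r1.genomes.genomes:
            g1, g2 = r1.genomes.genomes[sp], r2.genomes.genomes[sp]
            assert g1.transcripts == g2.transcripts
            assert g1.proteins == g2.proteins
            assert g1.annotation() == g2.annotation()
        pd.testing.assert_frame_equal(r1.truth.genes, r2.truth.genes)
        for name in r1.panels:
            pd.testing.assert_frame_equal(
                r1.panels[name].values, r2.panels[name].values
            )

    def test_different_seeds_differ(self):
        a = simulate_genomes(SimConfig(seed=1, **SMALL))
        b = simulate_genomes(SimConfig(seed=2, **SMALL))
        assert a.genomes["sp0"].transcripts != b.genomes["sp0"].transcripts


class TestNegativeBinomial:
    def test_poisson_limit_variance_matches_mean(self):
        """dispersion -> 0: sample variance approaches the mean."""
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(10_000, 50.0), alpha=1e-6)
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(0)
        mu, alpha = 100.0, 0.2
        draws = _nb_draw(rng, np.full(20_000, mu), alpha)
        assert draws.var() == pytest.approx(mu + alpha * mu**2, rel=0.1)

    def test_planted_bias_ratio_matches_effect_size(self):
        """bias_log2fc = 3 gives an empirical flat/round mean ratio near 8."""
        cfg = SimConfig(seed=6, bias_log2fc=3.0, replicates=40,
                        library_size_sigma=0.0, **SMALL)
        sim = simulate_genomes(cfg)
        sim, truth = plant_cis_modules(cfg, sim)
        panels = simulate_expression(cfg, sim, truth)
        panel = panels["mantle"]
        flat = panel.values[panel.select(valve="flat")]
        rnd = panel.values[panel.select(valve="round")]
        biased = truth.genes.query(
            "bias_class == 'flat_biased' and not is_module_gene"
        ).index
        ratios = flat.loc[biased].mean(axis=1) / rnd.loc[biased].mean(axis=1)
        assert np.median(ratios) == pytest.approx(8.0, rel=0.25)


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=5, **SMALL)
    sim = simulate_genomes(cfg)
    return cfg, *plant_cis_modules(cfg, sim)


class TestPlanting:
    def test_lnc_partner_distance_within_span(self, planted):
        cfg, sim, truth = planted
        genes = {g.gene_id: g for g in sim.genomes[sim.source].annotation()}
        for _, row in truth.modules.iterrows():
            lnc = genes[row["lnc_source"]]
            for pid in row["partners"].split(";"):
                assert abs(edge_distance(lnc, genes[pid])) <= cfg.module_span

    def test_species_specific_modules_absent_from_targets(self, planted):
        cfg, sim, truth = planted
        for _, row in truth.modules.iterrows():
            carried = {
                kv.split("=")[0] for kv in row["lnc_by_species"].split(";")
            }
            conserved = set(row["conserved_in"].split(";")) - {""}
            assert carried == conserved | {sim.source}
            for sp in sim.genomes:
                gid = f"{sp}_{row['lnc_source'].split('_', 1)[1]}"
                present = gid in sim.genomes[sp].transcripts
                assert present == (sp in carried)

    def test_planted_lncrnas_pass_noncoding_checks(self, planted):
        cfg, sim, truth = planted
        for _, row in truth.modules.iterrows():
            for kv in row["lnc_by_species"].split(";"):
                sp, gid = kv.split("=")
                seq = sim.genomes[sp].transcripts[gid]
                assert len(seq) > 200
                assert longest_orf_codons(seq) < 100

    def test_zero_modules_gives_empty_truth(self):
        cfg = SimConfig(seed=5, n_chroms=2, genes_per_chrom=150,
                        n_planted_modules=0, n_conserved_modules=0)
        sim = simulate_genomes(cfg)
        _, truth = plant_cis_modules(cfg, sim)
        assert len(truth.modules) == 0
        assert not truth.genes["is_module_gene"].any()


class TestExpressionTruth:
    def test_planted_candidates_satisfy_screening_margins(self, small_sim):
        """Planted candidate lncRNAs carry >= 80 % of tissue expression in
        mantle and >= 80 % of stage expression post-metamorphosis."""
        truth = small_sim.truth
        cands = truth.genes.query("is_candidate_lnc").index
        tissue = small_sim.panels["tissue"]
        by_tissue = {}
        for s in tissue.samples:
            by_tissue.setdefault(s.tissue, []).append(s.sample_id)
        means = pd.DataFrame(
            {t: tissue.values[ids].mean(axis=1) for t, ids in by_tissue.items()}
        )
        frac = means["mantle"] / means.sum(axis=1)
        assert (frac.loc[cands] > 0.7).all()

    def test_truth_round_trip(self, small_sim, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(small_sim.truth, path)
        again = read_truth(path)
        pd.testing.assert_frame_equal(
            small_sim.truth.genes, again.genes, check_dtype=False
        )
        pd.testing.assert_frame_equal(
            small_sim.truth.modules, again.modules, check_dtype=False
        )
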