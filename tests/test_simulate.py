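"""Generators: exact counts, truth-table consistency, determinism."""

import numpy as np
import pandas as pd
import pytest

from egmosaic import (SupportTree, classify_tree, classify_trees,
                      filter_by_replicates, filter_homologs, load_config,
                      pair_and_correlate, summarize_bins)
from egmosaic.ancestry import filter_alignments
from egmosaic.expression import compute_log_ratios, extract_single_state
from egmosaic.genome import compute_stats, derive_introns
from egmosaic.organelle import (call_mitochondrial, call_plastid_preliminary,
                                finalize_plastid)
from egmosaic.simulate import (gen_expression_tables, gen_gene_trees,
                               gen_homolog_table, gen_toolscore_table,
                               gen_toy_genome, write_genome, write_trees)

SMALL_TREES = {
    "focal_taxon": "EGRACILIS",
    "taxa_per_group": 4,
    "support_planted": 95,
    "support_background": [20, 74],
    "groups": ["Kinetoplastida", "Viridiplantae", "Metazoa", "Rhodophyta"],
    "bins": {"Kinetoplastida": 10, "Viridiplantae": 5},
}

SMALL_OMICS = {
    "protein": {"n_features": 60, "patterns": {
        "full_full": 20, "full_light_partial_dark": 5,
        "full_dark_partial_light": 5, "light_only": 6, "dark_only": 4,
        "partial_partial": 10, "sparse": 10}},
    "transcript": {"n_features": 80, "patterns": {
        "full_full": 40, "full_light_partial_dark": 5,
        "full_dark_partial_light": 5, "light_only": 5, "dark_only": 5,
        "partial_partial": 10, "sparse": 10}},
    "n_plastid_encoded": 10,
    "effects": {"effect_sd": 0.5, "noise_sd": 0.02, "shared": "plastid"},
}

SMALL_GENOME = {
    "n_contigs": 12, "total_contig_bases": 400_000, "contigs_with_cds": 4,
    "n_cds": 8, "n_introns": 16, "total_intron_length": 8_000,
    "total_exon_length": 3_200,
    "splice_counts": {"conventional": 10, "intermediate": 4,
                      "nonconventional": 2},
    "gene_contig_length": 20_000, "n_small_contigs": 3,
    "small_contig_length": 5_000,
}


class TestHomologTable:
    def test_exact_funnel_counts(self):
        cfg = {"n_retained": 40, "n_excluded": 25}
        table, truth = gen_homolog_table(cfg, seed=3)
        retained = filter_homologs(table)
        assert len(retained) == 40
        assert retained == set(truth.loc[truth["retained"], "protein_id"])


class TestGeneTrees:
    def test_clean_planted_trees_are_fully_recovered(self, tmp_path):
        trees, taxmap, truth = gen_gene_trees(SMALL_TREES, seed=5)
        path = write_trees(trees, tmp_path)
        parsed = [SupportTree.from_newick(line, f"tree{i:05d}")
                  for i, line in enumerate(path.read_text().splitlines())]
        calls = classify_trees(parsed, taxmap)
        by_name = dict(zip(truth["tree"], truth["planted_group"]))
        for c in calls:
            assert c.status == "classified"
            assert c.bins == {by_name[c.protein_id]}  # no dual bins
        s = summarize_bins(calls)
        assert s.counts == SMALL_TREES["bins"] and s.n_dual == 0

    def test_subthreshold_support_recovers_nothing(self):
        cfg = dict(SMALL_TREES, support_planted=60)
        trees, taxmap, _ = gen_gene_trees(cfg, seed=5)
        calls = [classify_tree(SupportTree.from_newick(n, m), taxmap)
                 for m, n in trees]
        assert all(c.status == "unclassified" for c in calls)

    def test_noise_trees_are_unclassifiable_in_truth(self):
        cfg = dict(SMALL_TREES, noise={"low_support": 4, "mixed_clan": 4})
        trees, taxmap, truth = gen_gene_trees(cfg, seed=5)
        noise = truth[truth["kind"] != "planted"]
        assert len(noise) == 8 and noise["planted_group"].isna().all()
        for name, nwk in trees:
            call = classify_tree(SupportTree.from_newick(nwk, name), taxmap)
            kind = truth.set_index("tree").loc[name, "kind"]
            assert (call.status == "classified") == (kind == "planted")

    def test_unknown_planted_group_is_error(self):
        with pytest.raises(ValueError):
            gen_gene_trees(dict(SMALL_TREES, bins={"Nope": 3}), seed=1)

    def test_determinism_byte_identical(self):
        a, _, ta = gen_gene_trees(SMALL_TREES, seed=9)
        b, _, tb = gen_gene_trees(SMALL_TREES, seed=9)
        assert a == b and ta.equals(tb)
        c, _, _ = gen_gene_trees(SMALL_TREES, seed=10)
        assert a != c


class TestToolScores:
    CFG = {
        "n_proteins": 300,
        "mito": {"targetp": 30, "ortholog": 20, "blast2go": 10, "manual": 5,
                 "mterf": 4, "non_mito_ortholog": 6, "boundary_score": 3},
        "plastid": {"signalp_chlorop": 6, "predisi_chlorop": 10,
                    "both_chlorop": 8, "signalp_only": 12, "predisi_only": 15,
                    "both_no_chlorop": 5, "atchloro_new": 7, "manual_new": 4},
    }

    def test_mito_truth_matches_calls(self):
        table, truth = gen_toolscore_table(self.CFG, seed=2)
        calls, breakdown = call_mitochondrial(table)
        assert breakdown == {"targetp": 30, "ortholog": 20, "blast2go": 10,
                             "manual": 5}
        expected = set(truth.loc[truth["mito_category"].isin(
            ["targetp", "ortholog", "blast2go", "manual"]), "protein_id"])
        assert {c.protein_id for c in calls} == expected

    def test_plastid_truth_matches_calls(self):
        table, truth = gen_toolscore_table(self.CFG, seed=2)
        prelim = call_plastid_preliminary(table)
        final = finalize_plastid(prelim, table)
        assert len(prelim) == 6 + 10 + 8
        assert len(final) == len(prelim) + 7 + 4

    def test_all_zero_config_gives_no_calls(self):
        table, _ = gen_toolscore_table({"n_proteins": 50}, seed=1)
        assert call_mitochondrial(table)[0] == []
        assert call_plastid_preliminary(table) == []

    def test_overfull_config_is_error(self):
        with pytest.raises(ValueError):
            gen_toolscore_table({"n_proteins": 10, "mito": {"targetp": 11}},
                                seed=1)

    def test_cleavage_present_iff_signal_positive(self):
        table, _ = gen_toolscore_table(self.CFG, seed=2)
        sp = table["signalp_positive"].astype(bool)
        assert table.loc[sp, "signalp_cleavage"].notna().all()
        assert table.loc[~sp, "signalp_cleavage"].isna().all()
        ok = table["signalp_cleavage"].dropna() < \
            table.loc[sp, "sequence_length"]
        assert ok.all()


class TestExpressionTables:
    def test_exact_pattern_counts_and_partition(self):
        sim = gen_expression_tables(SMALL_OMICS, seed=4)
        retained = filter_by_replicates(sim["protein"])
        assert len(retained) == 20 + 5 + 5 + 6 + 4
        parts = extract_single_state(retained, sim["protein"])
        assert len(parts["light_only"]) == 6 and len(parts["dark_only"]) == 4
        assert len(filter_by_replicates(sim["transcript"])) == 60

    def test_truth_patterns_cover_every_feature(self):
        sim = gen_expression_tables(SMALL_OMICS, seed=4)
        assert len(sim["truth"]) == 60
        assert sim["truth"]["pattern"].value_counts().to_dict() == \
            SMALL_OMICS["protein"]["patterns"]

    def test_shared_plastid_effects_yield_high_subset_correlation(self):
        cfg = {
            "protein": {"n_features": 400, "patterns": {"full_full": 400}},
            "transcript": {"n_features": 400, "patterns": {"full_full": 400}},
            "n_plastid_encoded": 100,
            "effects": {"effect_sd": 0.5, "noise_sd": 0.02,
                        "shared": "plastid"},
        }
        sim = gen_expression_tables(cfg, seed=8)
        pr = compute_log_ratios(sim["protein"])
        rr = compute_log_ratios(sim["transcript"])
        res = pair_and_correlate(pr, rr, sim["id_map"],
                                 sim["plastid_encoded"])
        assert res.n_plastid == 100
        assert res.rho_plastid > 0.8
        assert abs(res.rho_overall) < 0.6  # diluted by independent features

    def test_mismatched_pattern_total_is_error(self):
        bad = dict(SMALL_OMICS)
        bad["protein"] = {"n_features": 61,
                          "patterns": SMALL_OMICS["protein"]["patterns"]}
        with pytest.raises(ValueError):
            gen_expression_tables(bad, seed=1)

    def test_determinism(self):
        a = gen_expression_tables(SMALL_OMICS, seed=6)
        b = gen_expression_tables(SMALL_OMICS, seed=6)
        assert a["protein"].equals(b["protein"])
        assert a["transcript"].equals(b["transcript"])


class TestToyGenome:
    def test_exact_mode_counts_and_truth(self):
        contigs, models, truth = gen_toy_genome(SMALL_GENOME, seed=7)
        assert len(contigs) == 12 + 3
        introns = derive_introns(models, contigs)
        assert len(introns) == 16 == len(truth)
        assert sum(i.length for i in introns) == 8_000
        stats = compute_stats(models, contigs)
        assert stats.n_contigs == 12
        assert stats.n_contigs_with_cds == 4 and stats.n_cds == 8
        assert stats.splice_counts["conventional"] == 10
        assert stats.splice_counts["intermediate"] == 4
        assert stats.splice_counts["nonconventional"] == 2
        assert stats.total_exon_length == 3_200
        assert stats.total_contig_bases == 400_000

    def test_planted_classes_match_truth_per_intron(self):
        contigs, models, truth = gen_toy_genome(SMALL_GENOME, seed=7)
        from egmosaic import classify_splice
        introns = derive_introns(models, contigs)
        # derive_introns walks models in generation order, so the intron
        # sequence lines up with the truth rows one-to-one
        assert [i.transcript_id for i in introns] == \
            list(truth["transcript_id"])
        assert [i.length for i in introns] == list(truth["intron_length"])
        assert [classify_splice(i.donor, i.acceptor) for i in introns] == \
            list(truth["splice_class"])

    def test_round_trip_through_files(self, tmp_path):
        contigs, models, _ = gen_toy_genome(SMALL_GENOME, seed=7)
        paths = write_genome(contigs, models, tmp_path)
        from egmosaic.genome import read_gff3
        from egmosaic.simulate import contigs_from_lengths_tsv
        back_c = contigs_from_lengths_tsv(paths["lengths"], paths["fasta"])
        back_m = read_gff3(paths["gff3"])
        s1 = compute_stats(models, contigs)
        s2 = compute_stats(back_m, back_c)
        assert s1 == s2

    def test_determinism_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            contigs, models, _ = gen_toy_genome(SMALL_GENOME, seed=11)
            write_genome(contigs, models, tmp_path / sub)
        for f in ("contigs.fasta", "contig_lengths.tsv", "models.gff3"):
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes()

    def test_inconsistent_splice_total_is_error(self):
        bad = dict(SMALL_GENOME, splice_counts={"conventional": 1})
        with pytest.raises(ValueError):
            gen_toy_genome(bad, seed=1)
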