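import numpy as np
import pytest

from jumbophage.config import RunConfig
from jumbophage.features import find_orfs
from jumbophage.synthetic import (GenerationError, generate_abundance_matrix,
                                  generate_community,
                                  generate_proteome_families,
                                  generate_recoded_genome,
                                  plant_crispr_targeting)


class TestCommunity:
    def test_label_bookkeeping(self, config):
        genomes, annots, truth = generate_community(3, 2, seed=1,
                                                    config=config)
        assert len(genomes) == 5
        assert sum(truth.is_phage.values()) == 3
        assert sum(1 for v in truth.is_phage.values() if not v) == 2
        assert all(200_000 < g.length_bp <= 300_000 for g in genomes)

    def test_empty_community(self, config):
        genomes, annots, truth = generate_community(0, 0, seed=1,
                                                    config=config)
        assert genomes == [] and annots == [] and truth.is_phage == {}

    def test_determinism(self, config):
        a = generate_community(2, 1, seed=42, config=config)
        b = generate_community(2, 1, seed=42, config=config)
        assert [g.sequence for g in a[0]] == [g.sequence for g in b[0]]
        assert a[1] == b[1]

    def test_gene_tables_consistent_with_sequences(self, config):
        from Bio.Seq import Seq
        genomes, annots, _ = generate_community(1, 0, seed=7, config=config)
        seq = genomes[0].sequence
        for g in annots[:20]:
            cds = seq[g.start - 1:g.end]
            if g.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            assert str(Seq(cds[:-3]).translate()) == g.protein

    def test_contaminants_exceed_busco_threshold(self, config):
        _, annots, truth = generate_community(0, 2, seed=3, config=config)
        for gid, ratio in truth.busco_ratio_planted.items():
            genes = [a for a in annots if a.genome_id == gid]
            measured = sum(a.busco_hit for a in genes) / len(genes)
            assert measured == pytest.approx(ratio)
            assert measured > 0.067


class TestRecodedGenomes:
    def test_determinism(self, config):
        a = generate_recoded_genome(15, 30_000, seed=5, config=config)
        b = generate_recoded_genome(15, 30_000, seed=5, config=config)
        assert a.sequence == b.sequence

    def test_generator_self_check_margin(self, config):
        """The generator's own guarantee, re-verified here independently:
        planted-code density ≥ 1.10 × code-11 density."""
        genome = generate_recoded_genome(90, 50_000, seed=2, config=config)
        d = {c: find_orfs(genome, c).coded_fraction for c in (11, 90)}
        assert d[90] >= 1.10 * d[11]

    def test_unknown_code_rejected(self, config):
        with pytest.raises(ValueError):
            generate_recoded_genome(4, 30_000, seed=1, config=config)


class TestCrisprPlanting:
    def test_planted_mismatch_count_exact(self, config):
        genomes, _, _ = generate_community(2, 0, seed=8, config=config)
        planted, truth = plant_crispr_targeting(
            genomes, [("phage_000", "phage_001", 1, 2)], seed=2,
            config=config)
        # independent recomputation: minimum Hamming distance of the spacer
        # to any window of the target is exactly 2
        from jumbophage.crispr import detect_crispr_arrays
        arrays = detect_crispr_arrays(planted[0], config)
        spacer = arrays[0].spacers[1]       # planted between the fillers
        t = np.frombuffer(planted[1].sequence.encode(), np.uint8)
        s = np.frombuffer(spacer.encode(), np.uint8)
        win = np.lib.stride_tricks.sliding_window_view(t, s.size)
        assert (win != s).sum(axis=1).min() == 2

    def test_empty_edge_spec_leaves_genomes_unchanged(self, config):
        genomes, _, _ = generate_community(1, 0, seed=9, config=config)
        planted, truth = plant_crispr_targeting(genomes, [], seed=1,
                                                config=config)
        assert planted[0].sequence == genomes[0].sequence
        assert truth.spacer_edges == []

    def test_excessive_mismatches_rejected(self, config):
        genomes, _, _ = generate_community(1, 1, seed=9, config=config)
        with pytest.raises(ValueError):
            plant_crispr_targeting(
                genomes, [("phage_000", "contam_000", 1, 40)], seed=1,
                config=config)


class TestProteomeFamilies:
    def test_sharing_fractions_respected(self, config):
        proteomes, truth = generate_proteome_families(
            [3, 3], within=0.6, between=0.0, seed=5, n_proteins=20,
            config=config)
        assert len(proteomes) == 6
        # measured sharing by construction key, recomputed here
        import itertools
        for a, b in itertools.combinations(sorted(proteomes), 2):
            ka = {k.split("|", 1)[1] for k in proteomes[a] if "uniq" not in k}
            kb = {k.split("|", 1)[1] for k in proteomes[b] if "uniq" not in k}
            shared = len(ka & kb) / 20
            if truth.family_planted[a] == truth.family_planted[b]:
                assert shared >= 0.6
            else:
                assert shared == 0.0

    def test_identical_pair_shares_everything(self, config):
        proteomes, _ = generate_proteome_families(
            [2], within=1.0, between=0.0, seed=1, n_proteins=10,
            config=config)
        a, b = sorted(proteomes)
        assert len(proteomes[a]) == len(proteomes[b]) == 10

    def test_within_not_above_between_rejected(self, config):
        with pytest.raises(GenerationError):
            generate_proteome_families([2, 2], within=0.1, between=0.5,
                                       seed=1, config=config)


class TestAbundanceGeneration:
    def test_planted_latent_correlation(self, config):
        counts, truth = generate_abundance_matrix(
            10, 200, [(0, 1, 1)], seed=3, config=config)
        r = np.corrcoef(truth.latent_log_basis, rowvar=False)[0, 1]
        assert r > 0.8
        assert counts.shape == (10, 200)
        assert (counts >= 0).all()

    def test_no_planted_pairs_low_background(self, config):
        _, truth = generate_abundance_matrix(10, 200, [], seed=4,
                                             config=config)
        c = np.corrcoef(truth.latent_log_basis, rowvar=False)
        off = np.abs(c - np.eye(10))
        assert off.max() < 0.3

    def test_overlapping_pairs_rejected(self, config):
        with pytest.raises(ValueError):
            generate_abundance_matrix(5, 50, [(0, 1, 1), (1, 2, 1)],
                                      seed=1, config=config)

    def test_determinism(self, config):
        a, _ = generate_abundance_matrix(5, 50, [(0, 1, -1)], seed=6,
                                         config=config)
        b, _ = generate_abundance_matrix(5, 50, [(0, 1, -1)], seed=6,
                                         config=config)
        assert (a == b).all()
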