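"""The synthetic-data generator: determinism, codon-evolution postconditions,
gene-model layout, and the expression/qPCR table models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abcsurvey._codons import SENSE_CODONS, STOP_CODONS, translate
from abcsurvey.kaks import kaks_pair
from abcsurvey.simulate import (
    GenomeSimConfig,
    PlantedDuplication,
    SizingError,
    evolve_cds_pair,
    generate_expression_matrix,
    generate_genome,
    generate_qpcr_table,
    write_simulated_genome,
)


def _random_cds(rng, n_codons=120):
    return "".join(SENSE_CODONS[i] for i in rng.integers(61, size=n_codons))


class TestEvolveCdsPair:
    def test_zero_divergence_returns_identical_sequence(self, rng):
        anc = _random_cds(rng)
        desc, n_syn, n_non = evolve_cds_pair(anc, 0.0, 5.0, 1)
        assert desc == anc
        assert (n_syn, n_non) == (0, 0)

    def test_omega_zero_changes_are_all_silent(self, rng):
        anc = _random_cds(rng)
        desc, n_syn, n_non = evolve_cds_pair(anc, 0.5, 0.0, 2)
        assert n_non == 0
        assert translate(desc) == translate(anc)
        assert desc != anc  # synonymous changes did land

    def test_no_internal_stops_are_created(self, rng):
        for seed in range(5):
            anc = _random_cds(rng)
            desc, *_ = evolve_cds_pair(anc, 1.0, 1.0, seed)
            translate(desc)  # raises on any internal stop

    def test_frozen_codons_accept_no_amino_acid_change(self, rng):
        anc = _random_cds(rng)
        frozen = frozenset(range(0, 30))
        desc, *_ = evolve_cds_pair(anc, 0.8, 1.0, 3, frozen_codons=frozen)
        prot_a, prot_d = translate(anc), translate(desc)
        for i in frozen:
            assert prot_a[i] == prot_d[i]

    def test_terminal_stop_codon_is_preserved(self, rng):
        anc = _random_cds(rng) + "TAA"
        desc, *_ = evolve_cds_pair(anc, 0.4, 0.5, 4)
        assert desc[-3:] == "TAA"
        assert len(desc) == len(anc)

    def test_mean_estimated_ks_recovers_simulation_target(self, rng):
        """NG86 on simulated 300-codon pairs is unbiased within 10%."""
        target = 0.5
        estimates = []
        for _ in range(60):
            anc = _random_cds(rng, 300)
            desc, *_ = evolve_cds_pair(anc, target, 0.2, rng)
            estimates.append(kaks_pair(anc, desc, align=False).Ks)
        assert np.mean(estimates) == pytest.approx(target, rel=0.10)


class TestGenerateGenome:
    def test_no_planted_events_gives_background_only(self):
        cfg = GenomeSimConfig(n_background_genes=12, planted_events=(), seed=1)
        sim = generate_genome(cfg)
        assert len(sim.genome.genes) == 12
        assert sim.truth.empty

    def test_tandem_pair_is_adjacent_in_gene_rank(self):
        cfg = GenomeSimConfig(
            n_chromosomes=1,
            n_background_genes=20,
            planted_events=(PlantedDuplication("B", "tandem", 0.2, 0.2),),
            seed=5,
        )
        sim = generate_genome(cfg)
        a = sim.genome.genes["ev00_a"]
        b = sim.genome.genes["ev00_b"]
        assert a.chromosome == b.chromosome
        assert abs(a.gene_rank - b.gene_rank) == 1

    def test_proximal_pair_separated_by_requested_intervening_genes(self):
        cfg = GenomeSimConfig(
            n_chromosomes=1,
            n_background_genes=15,
            planted_events=(
                PlantedDuplication("C", "proximal", 0.2, 0.2, intervening_genes=4),
            ),
            seed=5,
        )
        sim = generate_genome(cfg)
        a = sim.genome.genes["ev00_a"]
        b = sim.genome.genes["ev00_b"]
        assert abs(a.gene_rank - b.gene_rank) == 5

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = GenomeSimConfig(
            n_background_genes=15,
            planted_events=(PlantedDuplication("G", "dispersed", 0.3, 0.2),),
            seed=7,
        )
        p1 = write_simulated_genome(generate_genome(cfg), tmp_path / "a")
        p2 = write_simulated_genome(generate_genome(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_chromosome_too_short_raises_sizing_error(self):
        cfg = GenomeSimConfig(
            n_chromosomes=1, chrom_length=30_000, n_background_genes=40, seed=1
        )
        with pytest.raises(SizingError):
            generate_genome(cfg)

    def test_truth_table_lists_every_planted_gene_with_partner(self, sim_genome):
        truth = sim_genome.truth
        assert set(truth["true_type"]) <= {
            "tandem", "proximal", "dispersed", "wgd_segmental",
        }
        genes = set(truth["gene_id"])
        for partner in truth["partner"]:
            assert partner in genes
        for gid in truth["gene_id"]:
            assert gid in sim_genome.genome.genes

    def test_cds_and_protein_are_consistent_in_every_gene(self, sim_genome):
        for g in sim_genome.genome.genes.values():
            assert len(g.cds) % 3 == 0
            assert g.cds[-3:] in STOP_CODONS
            assert translate(g.cds) == g.protein

    def test_utr_optout_count_is_respected(self):
        cfg = GenomeSimConfig(n_background_genes=30, n_no_utr=4, seed=3)
        sim = generate_genome(cfg)
        without = [g for g in sim.genome.genes.values() if not g.has_utr]
        assert len(without) == 4


class TestExpressionMatrixGenerator:
    def test_category_postconditions_hold_exactly(self):
        tissues = [f"t{i}" for i in range(15)]
        matrix, labels = generate_expression_matrix(5, 4, 3, 2, tissues, seed=1)
        assert matrix.shape == (14, 15)
        for gene, label in labels.items():
            row = matrix.loc[gene]
            if label == "ubiquitous":
                assert (row > 0).all()
            elif label == "silent":
                assert (row == 0).all()
            elif label == "tissue_specific":
                assert (row > 0).sum() == 1
            else:
                assert 2 <= (row > 0).sum() <= 14

    def test_silent_only_matrix_is_all_zero(self):
        matrix, _ = generate_expression_matrix(0, 6, 0, 0, ["a", "b"], seed=2)
        assert (matrix.values == 0).all()

    def test_fixed_seed_reproduces_matrix(self):
        m1, _ = generate_expression_matrix(3, 3, 3, 3, ["a", "b", "c"], seed=9)
        m2, _ = generate_expression_matrix(3, 3, 3, 3, ["a", "b", "c"], seed=9)
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_tissue_list_rejected(self):
        with pytest.raises(ValueError):
            generate_expression_matrix(1, 1, 1, 1, [], seed=1)


class TestQpcrGenerator:
    def test_reference_rows_exist_for_every_sample(self):
        table = generate_qpcr_table({"g1": {3: 2.0, 6: 4.0}}, 0.0, 3, seed=1)
        ref = table[table["gene"] == "beta_tubulin"]
        samples = table[table["gene"] != "beta_tubulin"]
        ref_keys = set(map(tuple, ref[["condition", "timepoint", "replicate"]].values))
        for key in map(tuple, samples[["condition", "timepoint", "replicate"]].values):
            assert key in ref_keys

    def test_noise_free_ct_encodes_fold_exactly(self):
        table = generate_qpcr_table({"g1": {3: 8.0}}, 0.0, 2, seed=1)
        by = table.set_index(["gene", "condition", "timepoint", "replicate"])["ct"]
        dct_treat = by[("g1", "treatment", 3, 1)] - by[("beta_tubulin", "treatment", 3, 1)]
        dct_ctrl = by[("g1", "control", 3, 1)] - by[("beta_tubulin", "control", 3, 1)]
        assert 2.0 ** -(dct_treat - dct_ctrl) == pytest.approx(8.0)

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ValueError):
            generate_qpcr_table({"g1": {3: 2.0}}, 0.1, 1, seed=1)
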