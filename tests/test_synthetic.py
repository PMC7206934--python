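import numpy as np
import pytest

from cpedit import (
    SimConfig,
    plant_edits,
    simulate_genes,
    simulate_species_sites,
    translate,
    write_fixture_bundle,
)
from cpedit.errors import FormatError, InfeasibleError, InputError
from cpedit.seqcore import codon_pos_of


class TestSimConfig:
    def test_bad_probs_rejected(self):
        with pytest.raises(InputError):
            SimConfig(seed=1, codon_pos_probs=(0.5, 0.6, 0.2))

    def test_too_short_genes_rejected(self):
        with pytest.raises(InputError):
            SimConfig(seed=1, gene_length_range=(2, 10))

    def test_json_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=5, n_edits=3)
        cfg.to_json(tmp_path / "sim.json")
        assert SimConfig.from_json(tmp_path / "sim.json") == cfg


class TestSimulateGenes:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_genes(SimConfig(seed=4))
        b = simulate_genes(SimConfig(seed=4))
        assert [(g.gene_id, g.seq) for g in a] == [(g.gene_id, g.seq) for g in b]

    def test_structure_of_generated_cds(self):
        genes = simulate_genes(SimConfig(seed=5, n_genes=20))
        assert len(genes) == 20
        for g in genes:
            assert g.seq.startswith("ATG")
            protein = translate(g.seq)
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_codon_usage_near_uniform(self):
        """Codon usage over a large sample is near-uniform over sense codons."""
        genes = simulate_genes(SimConfig(seed=6, n_genes=40, gene_length_range=(300, 300)))
        from collections import Counter

        counts = Counter()
        for g in genes:
            body = g.seq[3:-3]
            for i in range(0, len(body), 3):
                counts[body[i : i + 3]] += 1
        n = sum(counts.values())
        p = 1 / 61
        sd = (n * p * (1 - p)) ** 0.5
        for codon, c in counts.items():
            assert abs(c - n * p) < 4.5 * sd, codon


class TestPlantEdits:
    def test_zero_edits(self, small_sim):
        _, genes, _, _ = small_sim
        cfg = SimConfig(seed=2, n_edits=0)
        transcripts, truth = plant_edits(genes, cfg)
        assert [t.seq for t in transcripts] == [g.seq for g in genes]
        assert truth.edits == ()

    def test_edits_target_genomic_c_and_are_unique(self, small_sim):
        _, genes, transcripts, truth = small_sim
        gm = {g.gene_id: g for g in genes}
        tm = {t.gene_id: t for t in transcripts}
        seen = set()
        for e in truth.edits:
            assert gm[e.gene_id].seq[e.cds_pos - 1] == "C" == e.ref_base
            assert tm[e.gene_id].seq[e.cds_pos - 1] == "T" == e.alt_base
            assert codon_pos_of(e.cds_pos) == e.codon_pos
            key = (e.gene_id, e.cds_pos)
            assert key not in seen
            seen.add(key)

    def test_forced_context_constraint(self):
        cfg = SimConfig(seed=8, n_genes=10, n_edits=30, p_context_5U=1.0)
        genes = simulate_genes(cfg)
        _, truth = plant_edits(genes, cfg)
        gm = {g.gene_id: g for g in genes}
        for e in truth.edits:
            assert gm[e.gene_id].seq[e.cds_pos - 2] == "T"

    def test_reverse_edits_target_t(self):
        cfg = SimConfig(seed=12, n_genes=10, n_edits=30, p_reverse_edit=1.0)
        genes = simulate_genes(cfg)
        transcripts, truth = plant_edits(genes, cfg)
        tm = {t.gene_id: t for t in transcripts}
        for e in truth.edits:
            assert (e.ref_base, e.alt_base) == ("T", "C")
            assert tm[e.gene_id].seq[e.cds_pos - 1] == "C"

    def test_infeasible_count_fails_loudly(self):
        cfg = SimConfig(
            seed=3, n_genes=1, gene_length_range=(3, 3), n_edits=50, max_attempts=50
        )
        genes = simulate_genes(cfg)
        with pytest.raises(InfeasibleError):
            plant_edits(genes, cfg)

    def test_codon_position_fractions_converge(self):
        cfg = SimConfig(seed=10, n_genes=300, gene_length_range=(200, 400), n_edits=2000)
        genes = simulate_genes(cfg)
        _, truth = plant_edits(genes, cfg)
        counts = {1: 0, 2: 0, 3: 0}
        for e in truth.edits:
            counts[e.codon_pos] += 1
        for k, p in zip((1, 2, 3), cfg.codon_pos_probs):
            sd = (cfg.n_edits * p * (1 - p)) ** 0.5
            assert abs(counts[k] - cfg.n_edits * p) <= 3 * sd


class TestFixtureBundle:
    def test_bundle_files_written(self, tmp_path):
        cfg = SimConfig(seed=21, n_genes=4, n_edits=6, gene_length_range=(50, 80))
        genes, transcripts, truth = write_fixture_bundle(tmp_path, cfg)
        for name in ("genes.fasta", "transcripts.fasta", "truth.tsv", "config.json"):
            assert (tmp_path / name).exists()
        assert len(truth.edits) == 6


class TestSpeciesSites:
    TREE = "((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4);"

    def test_no_loss_all_present(self):
        m = simulate_species_sites(self.TREE, gain_rate=1.0, loss_rate=0.0, n_sites=200, seed=1)
        assert m.presence.all()

    def test_frozen_rates_copy_root(self):
        m = simulate_species_sites(
            self.TREE, gain_rate=0.0, loss_rate=0.0, n_sites=100, seed=2, root_present_prob=0.5
        )
        assert np.all(m.presence == m.presence[0])

    def test_rates_zero_without_root_prob_rejected(self):
        with pytest.raises(InputError):
            simulate_species_sites(self.TREE, 0.0, 0.0, 10, seed=1)

    def test_malformed_newick(self):
        with pytest.raises(FormatError):
            simulate_species_sites("((A:0.1,B", 1.0, 1.0, 10, seed=1)

    def test_two_leaf_change_frequency_matches_closed_form(self):
        g, l, t = 0.6, 0.9, 0.8
        n = 10_000
        m = simulate_species_sites(
            f"(X:{t},Y:0.0);", gain_rate=g, loss_rate=l, n_sites=n, seed=33
        )
        x = m.presence[m.species.index("X")]
        y = m.presence[m.species.index("Y")]  # zero branch: equals the root
        changed = np.mean(x != y)
        total = g + l
        factor = 1 - np.exp(-total * t)
        pi1 = g / total
        expected = pi1 * (l / total) * factor + (1 - pi1) * (g / total) * factor
        sd = (expected * (1 - expected) / n) ** 0.5
        assert abs(changed - expected) <= 3 * sd

    def test_sisters_share_more_than_distant(self):
        diffs = []
        for seed in range(20):
            m = simulate_species_sites(
                self.TREE, gain_rate=0.5, loss_rate=0.5, n_sites=300, seed=seed
            )
            a = m.presence[m.species.index("A")]
            b = m.presence[m.species.index("B")]
            c = m.presence[m.species.index("C")]
            sister = np.mean(a & b)
            distant = np.mean(a & c)
            diffs.append(sister - distant)
        assert np.mean(diffs) > 0
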