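import numpy as np
import pytest

from triggerscan import simulate as sim
from triggerscan.io import ScoringParams, TranscriptRegion
from triggerscan.scoring import best_pairing, extract_window
from triggerscan.sites import SeedMatch, find_seed_matches


def _rescore(mirna, spec, rng, params=ScoringParams()):
    up, seed_site, intended = sim.build_trigger_site(mirna, spec, rng, params)
    region = TranscriptRegion("t", "G" + up + seed_site + "G")
    seed = SeedMatch("t", mirna.mirna_id, "8mer", 1 + len(up), 9 + len(up))
    ts = best_pairing(mirna, extract_window(region, seed, params), seed,
                      params)
    return intended, ts


class TestTriggerConstruction:
    def test_reference_architecture_rescores_exactly(self):
        """10 contiguous scored matches, no wobble/bulge, offset 0."""
        m = sim.make_mirnas(sim.SimConfig(seed=1, n_mirnas=1),
                            np.random.default_rng(1))[0]
        spec = sim.TriggerSpec(m.mirna_id, 10)
        intended, ts = _rescore(m, spec, np.random.default_rng(2))
        assert ts.match_points == 10.0
        assert ts.config.offset == 0
        assert ts.total == intended["total"]

    @pytest.mark.parametrize("trial", range(100))
    def test_contiguous_architectures_label_exactly(self, trial):
        """Truth labels are exact across the contiguous-helix spec space."""
        rng = np.random.default_rng(50_000 + trial)
        m = sim.make_mirnas(sim.SimConfig(n_mirnas=1),
                            np.random.default_rng(trial))[0]
        spec = sim.TriggerSpec(m.mirna_id,
                               n_scored_matches=int(rng.integers(6, 11)),
                               offset=int(rng.integers(0, 6)))
        intended, ts = _rescore(m, spec, rng)
        assert ts.total == pytest.approx(intended["total"])
        assert ts.match_points == intended["match_points"]
        assert ts.config.offset == intended["offset"]
        assert ts.end_bonus == intended["end_bonus"]

    @pytest.mark.parametrize("trial", range(60))
    def test_intended_score_is_a_lower_bound(self, trial):
        """With wobbles/bulges the optimizer may beat the implant, never lag it."""
        rng = np.random.default_rng(70_000 + trial)
        m = sim.make_mirnas(sim.SimConfig(n_mirnas=1),
                            np.random.default_rng(trial))[0]
        n_sc = int(rng.integers(6, 10))
        elig = [p for p in range(13, 13 + n_sc)
                if m.sequence[p - 1] in "GU" and p != len(m.sequence)]
        spec = sim.TriggerSpec(
            m.mirna_id, n_scored_matches=n_sc,
            n_wobbles=int(rng.integers(0, min(2, len(elig)) + 1)),
            bulge_nts=int(rng.integers(0, 3)),
            offset=int(rng.integers(0, 6)))
        try:
            intended, ts = _rescore(m, spec, rng)
        except ValueError:  # architecture not constructible for this miRNA
            return
        assert ts.total >= intended["total"] - 1e-9

    def test_oversized_architecture_rejected(self):
        m = sim.make_mirnas(sim.SimConfig(seed=2, n_mirnas=1),
                            np.random.default_rng(2))[0]
        with pytest.raises(ValueError):
            sim.build_trigger_site(m, sim.TriggerSpec(m.mirna_id, 15),
                                   np.random.default_rng(0))


class TestTranscriptome:
    def test_seeded_determinism(self):
        cfg = sim.SimConfig(seed=9, n_regions=50,
                            trigger_specs=(sim.TriggerSpec("miR-s1", 10),))
        a = sim.make_transcriptome(cfg)
        b = sim.make_transcriptome(cfg)
        assert [r.sequence for r in a.regions] == [r.sequence for r in b.regions]
        assert a.tpm.equals(b.tpm) and a.truth.equals(b.truth)

    def test_truth_coordinates_locate_a_seed_match(self):
        cfg = sim.SimConfig(seed=10, n_regions=40,
                            trigger_specs=(sim.TriggerSpec("miR-s1", 10),))
        tx = sim.make_transcriptome(cfg)
        truth = tx.truth.iloc[0]
        region = next(r for r in tx.regions
                      if r.transcript_id == truth.transcript_id)
        mirna = tx.mirnas[0]
        found = find_seed_matches(mirna, region)
        assert any(m.start == truth.seed_start and m.site_type == "8mer"
                   for m in found)

    def test_decoy_rate_zero_leaves_background_only(self):
        cfg = sim.SimConfig(seed=11, n_regions=200, decoy_seed_rate=0.0)
        tx = sim.make_transcriptome(cfg)
        mirna = tx.mirnas[0]
        n_sites = sum(len(find_seed_matches(mirna, r, {"8mer"}))
                      for r in tx.regions)
        # chance 8mers only: ~ n_positions * (1/4)^8 expected
        n_pos = sum(len(r) - 7 for r in tx.regions)
        expected = n_pos * 0.25 ** 8
        assert n_sites <= expected + 4 * np.sqrt(expected) + 1

    def test_trigger_longer_than_host_rejected(self):
        cfg = sim.SimConfig(seed=12, n_regions=3, region_len_log10_mean=1.0,
                            region_len_log10_sd=0.0,
                            trigger_specs=(sim.TriggerSpec("miR-s1", 10),))
        # minimum region length (60) still accommodates window+site; force
        # an oversized construct instead
        with pytest.raises(ValueError):
            sim.build_trigger_site(
                sim.make_mirnas(cfg, np.random.default_rng(0))[0],
                sim.TriggerSpec("miR-s1", 10, bulge_nts=25),
                np.random.default_rng(0))


class TestDeTable:
    def test_null_shift_gives_equal_distributions(self):
        cfg = sim.SimConfig(seed=13, n_genes=20000, de_shift=0.0)
        df = sim.simulate_de_table(cfg)
        t = df[df.is_predicted_target].log2fc
        n = df[~df.is_predicted_target].log2fc
        assert abs(t.mean() - n.mean()) < 0.02

    def test_target_shift_applied(self):
        cfg = sim.SimConfig(seed=14, n_genes=20000, de_shift=0.25)
        df = sim.simulate_de_table(cfg)
        t = df[df.is_predicted_target].log2fc
        n = df[~df.is_predicted_target].log2fc
        assert t.mean() - n.mean() == pytest.approx(-0.25, abs=0.02)

    def test_seeded_determinism(self):
        cfg = sim.SimConfig(seed=15)
        assert sim.simulate_de_table(cfg).equals(sim.simulate_de_table(cfg))

    def test_context_coupling_strengthens_top_targets(self):
        cfg = sim.SimConfig(seed=16, n_genes=20000, de_shift=0.3,
                            context_effect=0.5)
        df = sim.simulate_de_table(cfg)
        t = df[df.is_predicted_target]
        strong = t[t.context_score <= t.context_score.quantile(0.1)]
        assert strong.log2fc.mean() < t.log2fc.mean()


class TestReads:
    def test_zero_count_mirna_yields_no_reads(self):
        rng = np.random.default_rng(17)
        mirnas = sim.make_mirnas(sim.SimConfig(seed=17, n_mirnas=3), rng)
        reads, truth = sim.simulate_reads(
            mirnas, {mirnas[0].mirna_id: 5, mirnas[1].mirna_id: 0,
                     mirnas[2].mirna_id: 2}, rng)
        assert len(reads) == 7
        assert not any(r.startswith(mirnas[1].sequence[:19]) for r in reads)

    def test_jitter_preserves_prefix(self):
        rng = np.random.default_rng(18)
        mirnas = sim.make_mirnas(sim.SimConfig(seed=18, n_mirnas=1), rng)
        reads, _ = sim.simulate_reads(mirnas, {mirnas[0].mirna_id: 200}, rng)
        assert all(r[:19] == mirnas[0].sequence[:19] for r in reads)
        assert all(len(r) >= 19 for r in reads)


class TestAlignmentSim:
    def test_zero_rate_gives_identity(self):
        rng = np.random.default_rng(19)
        m = sim.make_mirnas(sim.SimConfig(seed=19, n_mirnas=1), rng)[0]
        site = sim.random_rna(rng, 30) + "GCGCGCGC" + sim.random_rna(rng, 5)
        seed = SeedMatch("s", m.mirna_id, "8mer", 30, 38)
        cfg = sim.SimConfig(seed=19, n_species=5, substitution_rate=0.0)
        aln, hairpins = sim.simulate_species_alignment(cfg, site, m, seed, rng)
        assert all(row == site for row in aln.rows.values())
        assert all(hp == hairpins["ref"] for hp in hairpins.values())

    def test_seeded_determinism(self):
        m = sim.make_mirnas(sim.SimConfig(seed=20, n_mirnas=1),
                            np.random.default_rng(20))[0]
        site = sim.random_rna(np.random.default_rng(1), 40)
        seed = SeedMatch("s", m.mirna_id, "8mer", 30, 38)
        cfg = sim.SimConfig(seed=20, n_species=5, substitution_rate=0.1)
        a = sim.simulate_species_alignment(cfg, site, m, seed,
                                           np.random.default_rng(2))
        b = sim.simulate_species_alignment(cfg, site, m, seed,
                                           np.random.default_rng(2))
        assert a[0].rows == b[0].rows and a[1] == b[1]
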