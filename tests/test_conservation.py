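import numpy as np
import pytest

from triggerscan import simulate as sim
from triggerscan.conservation import (SpeciesAlignment, covariation_report,
                                      infer_mature_mirna, score_species)
from triggerscan.io import MiRNA, revcomp
from triggerscan.scoring import best_pairing
from triggerscan.sites import SeedMatch

from .conftest import random_rna
from .oracles import oracle_mature_match


def _reference_site(mirna, rng):
    """An implanted trigger region plus its seed coordinates."""
    spec = sim.TriggerSpec(mirna.mirna_id, 10)
    up, seed_site, _ = sim.build_trigger_site(mirna, spec, rng)
    region = up + seed_site + random_rna(rng, 8)
    seed = SeedMatch("site", mirna.mirna_id, "8mer", len(up), len(up) + 8)
    return region, seed


@pytest.fixture
def sim_mirna():
    return sim.make_mirnas(sim.SimConfig(seed=42, n_mirnas=1),
                           np.random.default_rng(42))[0]


class TestInferMature:
    def test_exact_substring_recovered(self, mirna, rng):
        hairpin = random_rna(rng, 30) + mirna.sequence + random_rna(rng, 30)
        assert infer_mature_mirna(mirna, hairpin) == mirna.sequence

    def test_single_substitution_recovered(self, mirna, rng):
        mutated = "G" + mirna.sequence[1:] if mirna.sequence[0] != "G" \
            else "C" + mirna.sequence[1:]
        hairpin = random_rna(rng, 25) + mutated + random_rna(rng, 25)
        assert infer_mature_mirna(mirna, hairpin, 0.25) == mutated

    def test_unrelated_sequence_gives_none(self, mirna):
        rng = np.random.default_rng(9)
        nulls = 0
        for _ in range(20):
            hairpin = random_rna(rng, 72)
            got = infer_mature_mirna(mirna, hairpin, 0.25)
            nulls += got is None
            # whatever is returned must agree with the exhaustive scan
            d, s = oracle_mature_match(mirna.sequence, hairpin)
            if got is not None:
                assert got == hairpin[s:s + len(mirna.sequence)]
        assert nulls == 20  # random 22-mers are far beyond 25% divergence

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_all_substrings_oracle(self, mirna, trial):
        rng = np.random.default_rng(300 + trial)
        hairpin = random_rna(rng, 60)
        # mutate a planted copy so distances are non-trivial
        k = len(mirna.sequence)
        copy = list(mirna.sequence)
        for pos in rng.choice(k, size=int(rng.integers(0, 6)), replace=False):
            copy[pos] = str(rng.choice([c for c in "ACGU"
                                        if c != copy[pos]]))
        hairpin = hairpin[:20] + "".join(copy) + hairpin[20:]
        d, s = oracle_mature_match(mirna.sequence, hairpin)
        got = infer_mature_mirna(mirna, hairpin, 0.25)
        if d > 0.25 * k:
            assert got is None
        else:
            assert got is not None
            assert sum(a != b for a, b in zip(got, mirna.sequence)) == d

    def test_hairpin_shorter_than_mature(self, mirna):
        with pytest.raises(ValueError):
            infer_mature_mirna(mirna, "ACGU")


class TestScoreSpecies:
    def test_identity_alignment_reproduces_reference(self, sim_mirna):
        rng = np.random.default_rng(1)
        region, seed = _reference_site(sim_mirna, rng)
        ref_total = best_pairing(sim_mirna, region[:seed.start], seed).total
        rows = {sp: region for sp in ("ref", "sp01", "sp02", "sp03")}
        aln = SpeciesAlignment(rows, "ref", seed)
        scores = score_species(aln, {sp: sim_mirna for sp in rows})
        assert all(s.status == "scored" for s in scores)
        assert all(s.trigger_score.total == ref_total for s in scores)

    def test_seed_deletion_marks_site_lost(self, sim_mirna):
        rng = np.random.default_rng(2)
        region, seed = _reference_site(sim_mirna, rng)
        lost = (region[:seed.start + 1] + "---"
                + region[seed.start + 4:])
        rows = {"ref": region, "spX": lost}
        scores = score_species(SpeciesAlignment(rows, "ref", seed),
                               {"ref": sim_mirna, "spX": sim_mirna})
        by = {s.species: s for s in scores}
        assert by["ref"].status == "scored"
        assert by["spX"].status == "site_lost"

    def test_missing_mirna_is_unresolved(self, sim_mirna):
        rng = np.random.default_rng(3)
        region, seed = _reference_site(sim_mirna, rng)
        scores = score_species(
            SpeciesAlignment({"ref": region, "spY": region}, "ref", seed),
            {"ref": sim_mirna, "spY": None})
        assert {s.species: s.status for s in scores} == \
            {"ref": "scored", "spY": "mirna_unresolved"}

    def test_projection_equals_direct_extraction_without_gaps(self, sim_mirna):
        rng = np.random.default_rng(4)
        region, seed = _reference_site(sim_mirna, rng)
        scores = score_species(
            SpeciesAlignment({"ref": region, "spZ": region}, "ref", seed),
            {"ref": sim_mirna, "spZ": sim_mirna})
        sp = next(s for s in scores if s.species == "spZ")
        assert sp.trigger_score.window == region[seed.start - 30:seed.start]

    def test_mean_score_non_increasing_in_divergence(self, sim_mirna):
        rng_site = np.random.default_rng(5)
        region, seed = _reference_site(sim_mirna, rng_site)
        means = []
        for rate in (0.0, 0.05, 0.2):
            vals = []
            for rep in range(15):
                cfg = sim.SimConfig(seed=5, n_species=8,
                                    substitution_rate=rate)
                aln, hairpins = sim.simulate_species_alignment(
                    cfg, region, sim_mirna, seed,
                    np.random.default_rng(1000 + rep))
                per = {sp: infer_mature_mirna(sim_mirna, hp)
                       for sp, hp in hairpins.items()}
                scores = score_species(aln, per)
                vals.extend(s.trigger_score.total if s.status == "scored"
                            else 0.0 for s in scores)
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestCovariation:
    def test_identity_gives_no_rows(self, sim_mirna):
        rng = np.random.default_rng(6)
        region, seed = _reference_site(sim_mirna, rng)
        scores = score_species(
            SpeciesAlignment({"ref": region, "sp": region}, "ref", seed),
            {"ref": sim_mirna, "sp": sim_mirna})
        ref_ts = next(s for s in scores if s.species == "ref").trigger_score
        assert covariation_report(scores, ref_ts, sim_mirna).empty

    def test_compensatory_double_substitution_preserved(self, sim_mirna):
        rng = np.random.default_rng(7)
        region, seed = _reference_site(sim_mirna, rng)
        m = sim_mirna.sequence
        # change miRNA position 17 and its paired target nt compatibly
        p = 17
        new_m_nt = "C" if m[p - 1] != "C" else "G"
        sp_mirna = m[:p - 1] + new_m_nt + m[p:]
        ref_scores = score_species(
            SpeciesAlignment({"ref": region}, "ref", seed),
            {"ref": sim_mirna})
        ref_ts = ref_scores[0].trigger_score
        t_pos = {pp: t for pp, t, _ in ref_ts.config.pairs}[p]
        win_start = seed.start - len(ref_ts.window)
        abs_pos = win_start + t_pos
        sp_region = (region[:abs_pos] + revcomp(new_m_nt)
                     + region[abs_pos + 1:])
        scores = score_species(
            SpeciesAlignment({"ref": region, "sp": sp_region}, "ref", seed),
            {"ref": sim_mirna, "sp": sp_mirna})
        rep = covariation_report(scores, ref_ts, sim_mirna)
        row = rep[(rep.species == "sp") & (rep.mirna_pos == p)]
        assert len(row) == 1 and row.pairing.iloc[0] == "preserved"

    def test_single_sided_substitution_lost(self, sim_mirna):
        rng = np.random.default_rng(8)
        region, seed = _reference_site(sim_mirna, rng)
        ref_scores = score_species(
            SpeciesAlignment({"ref": region}, "ref", seed),
            {"ref": sim_mirna})
        ref_ts = ref_scores[0].trigger_score
        p, t_pos, _ = sorted(ref_ts.config.pairs)[2]
        win_start = seed.start - len(ref_ts.window)
        abs_pos = win_start + t_pos
        # replace the target nt with one that can pair neither WC nor wobble
        m_nt = sim_mirna.sequence[p - 1]
        broken = "C" if m_nt == "U" else "A"
        sp_region = region[:abs_pos] + broken + region[abs_pos + 1:]
        scores = score_species(
            SpeciesAlignment({"ref": region, "sp": sp_region}, "ref", seed),
            {"ref": sim_mirna, "sp": sim_mirna})
        rep = covariation_report(scores, ref_ts, sim_mirna)
        row = rep[(rep.species == "sp") & (rep.mirna_pos == p)]
        assert len(row) == 1 and row.pairing.iloc[0] == "lost"


class TestAlignmentValidation:
    def test_unequal_row_lengths_rejected(self, mirna):
        seed = SeedMatch("s", mirna.mirna_id, "8mer", 0, 8)
        with pytest.raises(ValueError):
            SpeciesAlignment({"a": "ACGU", "b": "ACG"}, "a", seed)

    def test_missing_reference_rejected(self, mirna):
        seed = SeedMatch("s", mirna.mirna_id, "8mer", 0, 8)
        with pytest.raises(ValueError):
            SpeciesAlignment({"a": "ACGU"}, "zz", seed)
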