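"""Seed construction, profile estimation and the empirical-significance search."""

import math

import numpy as np
import pytest

from mimscout.motif_scan import MotifHit, get_pattern, scan
from mimscout.profile_search import (
    NEUTRAL, build_seed, database_background, estimate_profile, flank_sweep,
    score_windows, search, uniform_background,
)
from mimscout.sequence_io import SequenceRecord
from mimscout.synthetic_data import ContextSpec, make_proteome


def _record(identifier, residues, taxon=None):
    return SequenceRecord(identifier=identifier, residues=residues, taxon=taxon)


def _core_hit(rec):
    (hit,) = scan(rec, get_pattern("core"))
    return hit


class TestBuildSeed:
    MYB29 = _record("myb29", "SSTSKLLNKVAARASS")

    def test_flank_five_spans_whole_peptide(self):
        seed = build_seed([self.MYB29], [_core_hit(self.MYB29)], flank=5)
        assert seed.members == ("SSTSKLLNKVAARASS",)
        assert seed.width == 16
        assert seed.motif_offset == 6

    def test_flank_zero_is_motif_only(self):
        seed = build_seed([self.MYB29], [_core_hit(self.MYB29)], flank=0)
        assert seed.members == ("LLNKVA",)

    def test_terminal_truncation_padded_with_neutral(self):
        rec = _record("short", "KLNAVAKRES")
        hit = MotifHit("short", 2, 7, "LNAVAK", "core")
        seed = build_seed([rec], [hit], flank=5)
        member = seed.members[0]
        assert member.startswith(NEUTRAL * 4)
        assert len(member) == 16

    def test_flank_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_seed([self.MYB29], [_core_hit(self.MYB29)], flank=21)

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ValueError):
            build_seed([self.MYB29], [], flank=5)


class TestEstimateProfile:
    def test_single_member_point_mass_limit(self):
        """As pseudocount -> 0, a 1-member seed scores its own window at
        6*log2(20) bits under a uniform background."""
        rec = _record("m", "LLNKVA")
        seed = build_seed([rec], [MotifHit("m", 1, 6, "LLNKVA", "core")], flank=0)
        model = estimate_profile(seed, pseudocount=1e-9,
                                 background=uniform_background())
        (score,) = score_windows(model, "LLNKVA")
        assert score == pytest.approx(6 * math.log2(20), abs=1e-4)

    def test_uniform_column_has_zero_log_odds(self):
        members = tuple(aa * 6 for aa in "ACDEFGHIKLMNPQRSTVWY")
        from mimscout.profile_search import SeedAlignment
        seed = SeedAlignment(members=members, flank=0, motif_offset=1)
        model = estimate_profile(seed, background=uniform_background())
        assert np.allclose(model.log_odds, 0.0, atol=1e-12)

    def test_column_probabilities_sum_to_one(self):
        rec = _record("m", "SSTSKLLNKVAARASS")
        seed = build_seed([rec], [_core_hit(rec)], flank=5)
        model = estimate_profile(seed, background=uniform_background())
        assert np.allclose(model.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_padded_columns_sum_to_one_too(self):
        rec = _record("short", "KLNAVAKRES")
        seed = build_seed([rec], [MotifHit("short", 2, 7, "LNAVAK", "core")],
                          flank=5)
        model = estimate_profile(seed, background=uniform_background())
        assert np.allclose(model.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_background_rejected(self):
        rec = _record("m", "LLNKVA")
        seed = build_seed([rec], [MotifHit("m", 1, 6, "LLNKVA", "core")], flank=0)
        bad = np.zeros(20)
        bad[0] = 1.0
        with pytest.raises(ValueError):
            estimate_profile(seed, background=bad)

    def test_score_additivity_against_per_column_lookup(self, rng):
        """Window scores equal an independent per-position log-odds sum."""
        from mimscout.sequence_io import CANONICAL_RESIDUES
        rec = _record("m", "SSTSKLLNKVAARASS")
        seed = build_seed([rec], [_core_hit(rec)], flank=5)
        model = estimate_profile(seed, background=uniform_background())
        alphabet = np.array(list(CANONICAL_RESIDUES))
        seq = "".join(alphabet[rng.integers(20, size=60)])
        scores = score_windows(model, seq)
        for w in range(len(seq) - 15):
            expected = sum(
                model.log_odds[col, CANONICAL_RESIDUES.index(seq[w + col])]
                for col in range(16))
            assert scores[w] == pytest.approx(expected, abs=1e-9)


@pytest.fixture(scope="module")
def planted_db():
    seed_recs, seed_truth = make_proteome([ContextSpec(kind="r2r3_like")], 5, 777)
    db, truth = make_proteome(
        [ContextSpec(kind="r2r3_like"), ContextSpec(kind="negative")], 20, 999)
    by_id = {r.identifier: r.residues for r in seed_recs}
    hits = [MotifHit(r.identifier, r.start, r.end,
                     by_id[r.identifier][r.start - 1:r.end], "strict")
            for r in seed_truth.itertuples()]
    return seed_recs, hits, db, truth


class TestSearch:
    def _model(self, seed_recs, hits, db, flank=5):
        seed = build_seed(seed_recs, hits, flank)
        return estimate_profile(seed, background=database_background(db))

    def test_recovers_planted_instances_without_false_positives(self, planted_db):
        seed_recs, hits, db, truth = planted_db
        model = self._model(seed_recs, hits, db)
        found = search(db, model, evalue_cutoff=1e-3, max_iterations=3,
                       seed_rng=42, null_windows=20000)
        planted = list(truth.itertuples())
        recovered = sum(
            1 for r in planted
            if any(h.sequence_id == r.identifier and h.start <= r.start
                   and r.end <= h.start + 15 for h in found))
        assert recovered == len(planted)
        assert not any(h.sequence_id.startswith("negative") for h in found)

    def test_deterministic_for_fixed_seed(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        model = self._model(seed_recs, hits, db)
        a = search(db, model, seed_rng=7, max_iterations=2, null_windows=5000)
        b = search(db, model, seed_rng=7, max_iterations=2, null_windows=5000)
        assert a == b

    def test_evalue_monotone_in_score(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        model = self._model(seed_recs, hits, db)
        found = search(db, model, evalue_cutoff=10.0, max_iterations=1,
                       seed_rng=3, null_windows=5000)
        ordered = sorted(found, key=lambda h: h.score)
        for lo, hi in zip(ordered, ordered[1:]):
            assert lo.evalue >= hi.evalue - 1e-12

    def test_taxonomy_exclusion_can_empty_database(self):
        db = [_record("a", "SSTSKLLNKVAARASS", taxon="Brassicales")]
        rec = _record("m", "SSTSKLLNKVAARASS")
        model = self._model([rec], [_core_hit(rec)], db, flank=0)
        with pytest.raises(ValueError, match="empty"):
            search(db, model, exclude_taxa={"Brassicales"})

    def test_single_iteration_is_plain_pssm_pass(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        model = self._model(seed_recs, hits, db)
        found = search(db, model, max_iterations=1, seed_rng=5,
                       null_windows=5000)
        assert all(h.iteration_found == 1 for h in found)

    def test_termination_within_max_iterations(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        model = self._model(seed_recs, hits, db)
        found = search(db, model, max_iterations=4, seed_rng=5,
                       null_windows=5000)
        assert all(h.iteration_found <= 4 for h in found)

    def test_invalid_cutoff_rejected(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        model = self._model(seed_recs, hits, db)
        with pytest.raises(ValueError):
            search(db, model, evalue_cutoff=0.0)


class TestFlankSweep:
    def test_union_contains_each_row(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        result = flank_sweep(seed_recs, hits, db, [0, 5],
                             max_iterations=1, seed_rng=1, null_windows=5000)
        assert len(result.rows) == 2
        for _, _, row_hits in result.rows:
            assert {(h.sequence_id, h.start) for h in row_hits} <= result.union
        assert result.intersection <= result.union

    def test_flank_zero_still_recovers_planted(self, planted_db):
        seed_recs, hits, db, truth = planted_db
        result = flank_sweep(seed_recs, hits, db, [0], max_iterations=1,
                             seed_rng=1, null_windows=20000)
        _, _, row_hits = result.rows[0]
        planted = list(truth.itertuples())
        recovered = sum(
            1 for r in planted
            if any(h.sequence_id == r.identifier and h.start <= r.start
                   and r.end <= h.start + 5 for h in row_hits))
        assert recovered >= 0.9 * len(planted)

    def test_out_of_range_flank_rejected(self, planted_db):
        seed_recs, hits, db, _ = planted_db
        with pytest.raises(ValueError):
            flank_sweep(seed_recs, hits, db, [21])
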