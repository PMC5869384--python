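"""Smith-Waterman search, Karlin-Altschul statistics, family assignment."""

import math

import numpy as np
import pytest

from toxannot.homology import (DatabaseEntry, HomologyHit, annotate_dataset,
                               assign_families, evalue, search, sw_align,
                               sw_score)
from toxannot.scoring import DEFAULT_SCHEME, ScoringScheme
from toxannot.sequence import extract_orfs
from toxannot.simulate import SimulationConfig, simulate_dataset

from oracles import local_affine_score

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def _random_peptide(rng, lo, hi):
    return "".join(rng.choice(AAS, size=rng.integers(lo, hi + 1)))


class TestSwAlign:
    def test_identical_short_peptide(self):
        score, qspan, sspan = sw_align("ACDE", "ACDE")
        assert score == 24  # 4 + 9 + 6 + 5 on the BLOSUM62 diagonal
        assert qspan == (0, 4) and sspan == (0, 4)

    def test_trailing_mismatch_dropped(self):
        score, qspan, sspan = sw_align("ACDE", "ACDF")
        assert score == 19  # local optimum excludes the E:F column
        assert qspan == (0, 3) and sspan == (0, 3)

    def test_matches_gotoh_oracle(self, rng):
        for _ in range(500):
            a = _random_peptide(rng, 1, 12)
            b = _random_peptide(rng, 1, 12)
            assert sw_score(a, b) == local_affine_score(a, b)

    def test_symmetry(self, rng):
        for _ in range(100):
            a = _random_peptide(rng, 3, 25)
            b = _random_peptide(rng, 3, 25)
            assert sw_score(a, b) == sw_score(b, a)

    def test_unknown_residue_scored_as_x(self):
        # 'U' (selenocysteine) is outside BLOSUM62 and maps to X
        assert sw_score("UUU", "UUU") == sw_score("XXX", "XXX")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sw_align("", "ACDE")


class TestEvalue:
    def test_closed_form_example(self):
        # K*m*n*exp(-lambda*S) = 0.041 * 1e4 * e^(-10.68)
        assert evalue(40, 100, 100) == pytest.approx(9.43015e-3, rel=1e-4)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 80, 1000) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_linear_in_database_size(self):
        assert evalue(50, 80, 2000) == pytest.approx(2 * evalue(50, 80, 1000))

    def test_vanishes_for_large_scores(self):
        assert evalue(10_000, 100, 1e9) < 1e-300 or evalue(10_000, 100, 1e9) == 0.0

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            evalue(50, 0, 100)
        with pytest.raises(ValueError):
            evalue(50, 100, -1)


class TestSearch:
    def _db(self, rng, n=6, lo=40, hi=80):
        return [DatabaseEntry(family=f"F{i}", subject_id=f"F{i}|s{i}",
                              seq=_random_peptide(rng, lo, hi))
                for i in range(n)]

    def test_self_hit_passes_threshold(self, rng):
        db = self._db(rng)
        query = db[0].seq
        hits = search({"q": query}, db, e_threshold=1e-3)
        assert any(h.subject_id == db[0].subject_id for h in hits)
        self_hit = next(h for h in hits if h.subject_id == db[0].subject_id)
        assert self_hit.identity == 1.0
        assert self_hit.evalue < 1e-10

    def test_unrelated_query_no_hits(self, rng):
        db = self._db(rng)
        query = _random_peptide(rng, 40, 40)
        assert search({"q": query}, db, e_threshold=1e-3) == []

    def test_threshold_monotonicity(self, rng):
        db = self._db(rng)
        queries = {f"q{i}": _random_peptide(rng, 30, 60) for i in range(5)}
        loose = {(h.query_id, h.subject_id) for h in search(queries, db, 10.0)}
        strict = {(h.query_id, h.subject_id) for h in search(queries, db, 1e-3)}
        assert strict <= loose

    def test_infinite_threshold_returns_all_scoring_pairs(self, rng):
        db = self._db(rng, n=4)
        queries = {"q1": db[0].seq, "q2": db[1].seq}
        hits = search(queries, db, e_threshold=math.inf)
        assert {(h.query_id, h.subject_id) for h in hits} == {
            (q, e.subject_id) for q in queries for e in db}

    def test_empty_database(self):
        with pytest.raises(ValueError):
            search({"q": "ACDEACDE"}, [], 1e-3)


class TestAssignFamilies:
    def _hit(self, qid, sid, family, bitscore, ev):
        return HomologyHit(qid, sid, family, 0.0, bitscore, ev, 1.0, (0, 1), (0, 1))

    def test_single_hit(self):
        out = assign_families([self._hit("q", "s", "famZ", 50, 1e-9)])
        assert out[0].family == "famZ"

    def test_highest_bitscore_wins(self):
        hits = [self._hit("q", "s1", "famA", 40, 1e-7),
                self._hit("q", "s2", "famB", 50, 1e-9)]
        assert assign_families(hits)[0].family == "famB"

    def test_tie_break_lexicographic_subject(self):
        hits = [self._hit("q", "famB|x", "famB", 50, 1e-9),
                self._hit("q", "famA|y", "famA", 50, 1e-9)]
        out = assign_families(hits)
        assert out[0].best_hit.subject_id == "famA|y"
        assert out[0].family == "famA"

    def test_query_without_hits_excluded(self):
        assert assign_families([]) == []


@pytest.fixture(scope="module")
def fixture_dataset():
    cfg = SimulationConfig(seed=5, n_families=2, leaves_per_family=(5, 7))
    ds = simulate_dataset(cfg)
    cds = []
    for cid in sorted(ds.contigs):
        cds.extend(extract_orfs(cid, ds.contigs[cid]))
    return ds, cds


class TestAnnotateDataset:
    def test_empty_query_set(self, fixture_dataset):
        ds, _ = fixture_dataset
        res = annotate_dataset([], ds.databases["species"],
                               sp_truth_labels=ds.sp_truth_labels)
        assert res.assignments == [] and all(v == 0 for v in res.stage_counts.values())

    def test_stage_counts_match_independent_recomputation(self, fixture_dataset):
        ds, cds = fixture_dataset
        db = ds.databases["lineage"]
        res = annotate_dataset(cds, db, sp_truth_labels=ds.sp_truth_labels)
        # independent four-step recomputation from primitives
        n_total = sum(len(e.seq) for e in db)
        labels = ds.sp_truth_labels
        annotated = []
        for c in cds:
            best = None
            for e in db:
                s = sw_score(c.aa_seq, e.seq)
                if s <= 0:
                    continue
                ev = DEFAULT_SCHEME.k * len(c.aa_seq) * n_total * math.exp(
                    -DEFAULT_SCHEME.lam * s)
                if ev <= 1e-3:
                    bit = DEFAULT_SCHEME.bitscore(s)
                    key = (-bit, ev, e.subject_id)
                    if best is None or key < best[0]:
                        best = (key, e.family)
            if best:
                annotated.append(c)
        sp_pos = [c for c in annotated
                  if labels.get(c.contig_id) and c.aa_seq.startswith(labels[c.contig_id])]
        assert res.stage_counts["unique_contigs"] == len({c.contig_id for c in annotated})
        assert res.stage_counts["unique_cds"] == len({c.aa_seq for c in annotated})
        assert res.stage_counts["unique_cds_signal_peptide"] == len({c.aa_seq for c in sp_pos})
        assert res.stage_counts["unique_full_length_cds"] == len(
            {c.aa_seq for c in sp_pos if c.is_complete})
        assert {c.aa_seq for c in res.survivors} == {c.aa_seq for c in sp_pos}

    def test_stage_counts_non_increasing(self, fixture_dataset):
        ds, cds = fixture_dataset
        for tier in ("species", "lineage", "distant"):
            res = annotate_dataset(cds, ds.databases[tier],
                                   sp_truth_labels=ds.sp_truth_labels)
            c = res.stage_counts
            assert c["unique_cds"] >= c["unique_cds_signal_peptide"] >= \
                c["unique_full_length_cds"]

    def test_exclusion_list_respected(self, fixture_dataset):
        ds, cds = fixture_dataset
        res = annotate_dataset(cds, ds.databases["species"],
                               sp_truth_labels=ds.sp_truth_labels)
        assert res.survivors
        drop = res.survivors[0].id
        res2 = annotate_dataset(cds, ds.databases["species"],
                                sp_truth_labels=ds.sp_truth_labels,
                                exclude_ids={drop})
        assert drop not in {c.id for c in res2.survivors}
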