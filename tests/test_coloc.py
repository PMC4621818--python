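"""Genetic-map and ortholog-physical co-localization, best-hit filtering."""

import numpy as np
import pandas as pd
import pytest

from drylysim import coloc


def _map(rows):
    return pd.DataFrame(rows, columns=["entity_id", "linkage_group", "position_cm"])


def _hit(qseqid, sseqid, length=300, evalue=1e-50, bitscore=400.0,
         sstart=1000, send=1299, pident=95.0):
    return {
        "qseqid": qseqid, "sseqid": sseqid, "pident": pident, "length": length,
        "mismatch": 5, "gapopen": 0, "qstart": 1, "qend": length,
        "sstart": sstart, "send": send, "evalue": evalue, "bitscore": bitscore,
    }


class TestGeneticColocalize:
    def test_coincident_pair_is_candidate_at_distance_zero(self):
        degs = _map([("UG1", 3, 44.93)])
        snps = _map([("1_0758", 3, 44.93)])
        out = coloc.genetic_colocalize(degs, snps)
        assert len(out) == 1
        assert out["distance"].iloc[0] == 0.0

    def test_same_position_different_group_not_candidate(self):
        degs = _map([("UG1", 3, 44.93)])
        snps = _map([("1_0758", 4, 44.93)])
        assert len(coloc.genetic_colocalize(degs, snps)) == 0

    def test_window_strict_below_two_cm(self):
        degs = _map([("UG1", 3, 10.0), ("UG2", 3, 20.0)])
        snps = _map([("s1", 3, 11.999), ("s2", 3, 22.0)])
        out = coloc.genetic_colocalize(degs, snps)
        assert list(out["unigene_id"]) == ["UG1"]  # 1.999 < 2 in, 2.0 out

    def test_matches_allpairs_bruteforce(self, rng):
        degs = _map(
            [(f"UG{i}", int(rng.integers(1, 12)), float(rng.uniform(0, 100)))
             for i in range(100)]
        )
        snps = _map(
            [(f"s{i}", int(rng.integers(1, 12)), float(rng.uniform(0, 100)))
             for i in range(39)]
        )
        out = coloc.genetic_colocalize(degs, snps)
        got = set(zip(out["unigene_id"], out["snp"]))
        expected = set()
        for d in degs.itertuples():
            for s in snps.itertuples():
                dist = abs(d.position_cm - s.position_cm)
                if d.linkage_group == s.linkage_group and (dist == 0 or dist < 2.0):
                    expected.add((d.entity_id, s.entity_id))
        assert got == expected

    def test_symmetric_in_roles(self, rng):
        a = _map([(f"x{i}", int(rng.integers(1, 4)), float(rng.uniform(0, 30)))
                  for i in range(25)])
        b = _map([(f"y{i}", int(rng.integers(1, 4)), float(rng.uniform(0, 30)))
                  for i in range(25)])
        ab = coloc.genetic_colocalize(a, b)
        ba = coloc.genetic_colocalize(b, a)
        assert set(zip(ab["unigene_id"], ab["snp"])) == set(
            zip(ba["snp"], ba["unigene_id"])
        )

    def test_enlarging_window_never_removes_candidates(self, rng):
        degs = _map([(f"UG{i}", 1, float(rng.uniform(0, 50))) for i in range(30)])
        snps = _map([(f"s{i}", 1, float(rng.uniform(0, 50))) for i in range(10)])
        small = coloc.genetic_colocalize(degs, snps, max_cm=1.0)
        large = coloc.genetic_colocalize(degs, snps, max_cm=3.0)
        assert set(zip(small["unigene_id"], small["snp"])) <= set(
            zip(large["unigene_id"], large["snp"])
        )

    def test_missing_positions_skipped_with_warning(self):
        degs = _map([("UG1", 3, 10.0), ("UG2", np.nan, np.nan)])
        snps = _map([("s1", 3, 10.5)])
        with pytest.warns(UserWarning, match="skipped"):
            out = coloc.genetic_colocalize(degs, snps)
        assert list(out["unigene_id"]) == ["UG1"]


class TestBestOrtholog:
    def test_short_alignment_rejected(self):
        hits = pd.DataFrame([_hit("q1", "Gm01", length=79)])
        assert len(coloc.best_ortholog(hits)) == 0

    def test_minimum_length_kept(self):
        hits = pd.DataFrame([_hit("q1", "Gm01", length=80)])
        assert len(coloc.best_ortholog(hits)) == 1

    def test_weak_evalue_rejected(self):
        hits = pd.DataFrame([_hit("q1", "Gm01", evalue=1e-9)])
        assert len(coloc.best_ortholog(hits)) == 0

    def test_single_passing_hit_selected(self):
        hits = pd.DataFrame([_hit("q1", "Gm05")])
        best = coloc.best_ortholog(hits)
        assert list(best["sseqid"]) == ["Gm05"]

    def test_selection_matches_sort_oracle(self):
        hits = pd.DataFrame(
            [
                _hit("q1", "GmA", evalue=1e-20, bitscore=100, length=100),
                _hit("q1", "GmB", evalue=1e-30, bitscore=90, length=100),
                _hit("q1", "GmC", evalue=1e-30, bitscore=95, length=100),
                _hit("q1", "GmD", evalue=1e-30, bitscore=95, length=200),
                _hit("q1", "GmE", evalue=1e-9, bitscore=500, length=500),
            ]
        )
        best = coloc.best_ortholog(hits)
        # lowest e-value 1e-30; tie on bitscore 95 > 90; tie broken by length
        assert list(best["sseqid"]) == ["GmD"]

    def test_reversed_subject_coordinates_normalized(self):
        hits = pd.DataFrame([_hit("q1", "Gm01", sstart=5000, send=4701)])
        best = coloc.best_ortholog(hits)
        assert best["sstart"].iloc[0] == 4701
        assert best["send"].iloc[0] == 5000


class TestPhysicalColocalize:
    @staticmethod
    def _best(rows):
        return pd.DataFrame(rows)[coloc.BLAST6_COLUMNS]

    def test_gap_under_threshold_is_candidate(self):
        degs = self._best([_hit("UG1", "Gm01", sstart=1, send=300)])
        snps = self._best([_hit("s1", "Gm01", sstart=1_700_300, send=1_700_599)])
        out = coloc.physical_colocalize(degs, snps)
        assert len(out) == 1
        assert out["distance"].iloc[0] == 1_700_000

    def test_threshold_inclusive_at_1_8_mb(self):
        degs = self._best([_hit("UG1", "Gm01", sstart=1, send=300)])
        at = self._best([_hit("s1", "Gm01", sstart=1_800_300, send=1_800_599)])
        over = self._best([_hit("s2", "Gm01", sstart=1_800_301, send=1_800_600)])
        assert len(coloc.physical_colocalize(degs, at)) == 1
        assert len(coloc.physical_colocalize(degs, over)) == 0

    def test_overlapping_intervals_gap_zero(self):
        degs = self._best([_hit("UG1", "Gm01", sstart=1000, send=2000)])
        snps = self._best([_hit("s1", "Gm01", sstart=1500, send=2500)])
        out = coloc.physical_colocalize(degs, snps)
        assert out["distance"].iloc[0] == 0

    def test_different_chromosome_excluded(self):
        degs = self._best([_hit("UG1", "Gm01")])
        snps = self._best([_hit("s1", "Gm02")])
        assert len(coloc.physical_colocalize(degs, snps)) == 0

    def test_matches_allpairs_bruteforce(self, rng):
        def rand_rows(prefix, n):
            rows = []
            for i in range(n):
                start = int(rng.integers(0, 10_000_000))
                rows.append(
                    _hit(f"{prefix}{i}", f"Gm{int(rng.integers(1, 4)):02d}",
                         sstart=start, send=start + 300)
                )
            return self._best(rows)

        degs, snps = rand_rows("UG", 60), rand_rows("s", 20)
        out = coloc.physical_colocalize(degs, snps)
        got = set(zip(out["unigene_id"], out["snp"]))
        expected = set()
        for d in degs.itertuples():
            for s in snps.itertuples():
                if d.sseqid != s.sseqid:
                    continue
                gap = max(0, max(s.sstart - d.send, d.sstart - s.send))
                if gap <= 1_800_000:
                    expected.add((d.qseqid, s.qseqid))
        assert got == expected


class TestCombine:
    def test_pairs_supported_by_both_routes_deduplicated(self):
        genetic = pd.DataFrame(
            [{"unigene_id": "UG1", "snp": "s1", "evidence": "genetic_map",
              "distance": 0.5}]
        )
        physical = pd.DataFrame(
            [
                {"unigene_id": "UG1", "snp": "s1", "evidence": "ortholog_physical",
                 "distance": 100},
                {"unigene_id": "UG2", "snp": "s1", "evidence": "ortholog_physical",
                 "distance": 500},
            ]
        )
        out = coloc.combine_candidates(genetic, physical)
        assert len(out) == 2
        row = out[out["unigene_id"] == "UG1"].iloc[0]
        assert row["evidence"] == "genetic_map+ortholog_physical"

    def test_trait_annotation(self):
        cand = pd.DataFrame([{"unigene_id": "UG1", "snp": "s1",
                              "evidence": "genetic_map", "distance": 0.5}])
        traits = pd.DataFrame({"snp": ["s1", "s1"], "trait": ["Scu", "Stg"]})
        out = coloc.annotate_traits(cand, traits)
        assert out["traits"].iloc[0] == "Scu, Stg"
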