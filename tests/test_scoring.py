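"""Empirical per-condition scores, class sums, normalisation, ranking."""

import numpy as np
import pytest

from heartenh.compendium import CompendiumCatalogue, CompendiumRegion, build_catalogue
from heartenh.intervals import GenomicInterval
from heartenh.peaks import Condition, Peak
from heartenh.scoring import (ConditionScoreTable, condition_score,
                              rank_catalogue, score_catalogue)


def brute_force_score(x, table):
    """Rank-enumeration oracle: fraction of peaks with equal-or-weaker enrichment."""
    return sum(1 for v in table if v <= x) / len(table)


def cond(cid, stage_class):
    return Condition(cid, "human", "s", stage_class, "H3K27ac")


def region(start, end, evidence, chrom="chr1"):
    return CompendiumRegion(GenomicInterval(chrom, start, end, "asmA"), evidence)


def make_catalogue(regions, conditions):
    return CompendiumCatalogue(sorted(regions, key=lambda r: r.interval),
                               sorted(conditions))


class TestConditionScore:
    def test_worked_example(self):
        table = [100, 50, 20, 10]
        assert condition_score(50, table) == pytest.approx(3 / 4)

    def test_top_and_bottom_rank(self):
        table = [100, 50, 20, 10]
        assert condition_score(100, table) == 1.0
        assert condition_score(10, table) == pytest.approx(1 / 4)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            table = list(np.round(rng.uniform(2, 60, size=int(rng.integers(1, 40))), 2))
            query = table[int(rng.integers(len(table)))]
            assert condition_score(query, table) == \
                pytest.approx(brute_force_score(query, table))

    def test_ties_share_score(self):
        table = [30, 20, 20, 10]
        assert condition_score(20, table) == pytest.approx(3 / 4)

    def test_monotone_in_evidence(self):
        rng = np.random.default_rng(19)
        table = rng.uniform(2, 60, size=50)
        qs = np.sort(rng.uniform(0, 70, size=30))
        scores = [condition_score(q, table) for q in qs]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_literal_variant_is_complementary_rank(self):
        table = [100, 50, 20, 10]
        # probability of equal-or-better enrichment
        assert condition_score(50, table, variant="literal") == pytest.approx(2 / 4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            condition_score(10, [])


class TestScoreCatalogue:
    def test_single_region_single_condition_self_normalises(self):
        cat = make_catalogue([region(0, 100, {"c1": 20.0})], ["c1"])
        tables = ConditionScoreTable({"c1": [20.0]})
        score_catalogue(cat, {"c1": cond("c1", "prenatal")}, tables)
        sc = cat.regions[0].scores
        assert sc.all == 1.0 and sc.prenatal == 1.0 and sc.postnatal == 0.0

    def test_hand_worked_sum_and_normalisation(self):
        # r1 holds the top peak of both conditions' tables -> per-condition
        # scores 1.0 and 0.75, raw 1.75; r2 only c1's top -> raw 1.0
        tables = ConditionScoreTable({"c1": [40.0, 30.0],
                                      "c2": [100, 50, 20, 10]})
        r1 = region(0, 100, {"c1": 40.0, "c2": 50.0})
        r2 = region(500, 600, {"c1": 40.0})
        cat = make_catalogue([r1, r2], ["c1", "c2"])
        score_catalogue(cat, {"c1": cond("c1", "prenatal"),
                              "c2": cond("c2", "postnatal")}, tables)
        assert r1.scores.raw_all == pytest.approx(1.75)
        assert r1.scores.all == 1.0
        assert r2.scores.all == pytest.approx(1.0 / 1.75)

    def test_prenatal_only_region_scores_zero_postnatal(self):
        tables = ConditionScoreTable({"c1": [20.0], "c2": [30.0]})
        r1 = region(0, 100, {"c1": 20.0})
        r2 = region(500, 700, {"c2": 30.0})
        cat = make_catalogue([r1, r2], ["c1", "c2"])
        score_catalogue(cat, {"c1": cond("c1", "prenatal"),
                              "c2": cond("c2", "postnatal")}, tables)
        assert r1.scores.postnatal == 0.0 and r1.scores.prenatal == 1.0
        assert r2.scores.prenatal == 0.0 and r2.scores.postnatal == 1.0

    def test_normalisation_max_is_one_per_nonempty_class(self):
        rng = np.random.default_rng(20)
        conds = {f"c{i}": cond(f"c{i}", "prenatal" if i % 2 else "postnatal")
                 for i in range(4)}
        tables = ConditionScoreTable(
            {cid: rng.uniform(5, 50, size=30) for cid in conds})
        regions = []
        for j in range(25):
            ev = {cid: float(rng.choice(tables.values[cid]))
                  for cid in conds if rng.random() < 0.6}
            if ev:
                regions.append(region(j * 1_000, j * 1_000 + 500, ev))
        cat = make_catalogue(regions, list(conds))
        score_catalogue(cat, conds, tables)
        for cls in ("all", "prenatal", "postnatal"):
            vals = [getattr(r.scores, cls) for r in cat.regions]
            assert all(0.0 <= v <= 1.0 for v in vals)
            if any(getattr(r.scores, "raw_" + cls) > 0 for r in cat.regions):
                assert max(vals) == pytest.approx(1.0)

    def test_breadth_criterion_linear_in_conditions(self):
        # a region at every condition's median evidence has raw_all ~ k * 0.5
        n_cond = 6
        conds = {f"c{i}": cond(f"c{i}", "prenatal") for i in range(n_cond)}
        table_vals = list(np.linspace(5, 50, 99))  # odd count: exact median
        tables = ConditionScoreTable({cid: table_vals for cid in conds})
        median = float(np.median(table_vals))
        for k in (1, 3, 6):
            ev = {f"c{i}": median for i in range(k)}
            r = region(0, 100, ev)
            cat = make_catalogue([r], list(conds))
            score_catalogue(cat, conds, tables)
            assert r.scores.raw_all == pytest.approx(k * (50 / 99))

    def test_added_evidence_never_decreases_raw_scores(self):
        tables = ConditionScoreTable({"c1": [10.0, 20.0, 30.0],
                                      "c2": [15.0, 25.0]})
        conds = {"c1": cond("c1", "prenatal"), "c2": cond("c2", "postnatal")}

        def raw(ev):
            r = region(0, 100, dict(ev))
            cat = make_catalogue([r], list(conds))
            score_catalogue(cat, conds, tables)
            return r.scores.raw_all

        base = raw({"c1": 10.0})
        assert raw({"c1": 20.0}) >= base  # stronger evidence, same condition
        assert raw({"c1": 10.0, "c2": 15.0}) > base  # new condition: strict

    def test_missing_stage_class_condition_rejected(self):
        cat = make_catalogue([region(0, 100, {"cX": 20.0})], ["cX"])
        tables = ConditionScoreTable({"cX": [20.0]})
        with pytest.raises(ValueError, match="cX"):
            score_catalogue(cat, {}, tables)


class TestRankCatalogue:
    def _scored_catalogue(self, rng, n=50):
        conds = {"c1": cond("c1", "prenatal")}
        tables = ConditionScoreTable({"c1": list(rng.uniform(5, 50, 200))})
        regions = [region(i * 1_000, i * 1_000 + 500,
                          {"c1": float(rng.choice(tables.values["c1"]))})
                   for i in range(n)]
        cat = make_catalogue(regions, ["c1"])
        score_catalogue(cat, conds, tables)
        return cat

    def test_descending_with_positional_tie_break(self):
        conds = {"c1": cond("c1", "prenatal")}
        tables = ConditionScoreTable({"c1": [10.0, 20.0]})
        r1 = region(5_000, 5_500, {"c1": 20.0})
        r2 = region(0, 500, {"c1": 20.0})
        r3 = region(9_000, 9_100, {"c1": 10.0})
        cat = make_catalogue([r1, r2, r3], ["c1"])
        score_catalogue(cat, conds, tables)
        ranked = rank_catalogue(cat)
        assert [r.interval.start for r in ranked] == [0, 5_000, 9_000]

    def test_order_invariance_and_sortedness(self):
        rng = np.random.default_rng(21)
        cat = self._scored_catalogue(rng)
        ranked = rank_catalogue(cat, "all")
        scores = [r.scores.all for r in ranked]
        assert scores == sorted(scores, reverse=True)
        cat.regions.reverse()
        assert rank_catalogue(cat, "all") == ranked

    def test_unknown_class_rejected(self):
        rng = np.random.default_rng(22)
        cat = self._scored_catalogue(rng, n=5)
        with pytest.raises(ValueError):
            rank_catalogue(cat, "weekend")


def test_planted_enhancers_outscore_background(default_world, default_run):
    """On the default synthetic world the planted regions' mean combined
    score clearly exceeds the background regions' mean."""
    from heartenh.synthetic_data import score_separation

    sep = score_separation(default_world, default_run.catalogue)
    assert sep["n_planted_regions"] > 0 and sep["n_background_regions"] > 0
    assert sep["mean_score_planted"] > sep["mean_score_background"] + 0.1
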