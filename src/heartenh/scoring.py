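"""Empirical confidence scores for candidate enhancers.

Each condition contributes a per-region evidence score: the fraction of that
condition's peaks whose enrichment is equal or weaker, i.e.

    s_c(r) = |{p' in condition c : p' >= p_r}| / N_c

computed on the p scale (equivalently, the fraction of the condition's
-log10 p values <= the region's evidence). It is monotone in enrichment: the
condition's strongest peak scores 1, its weakest 1/N_c. Raw class scores sum
s_c over all conditions with evidence (combined), or only prenatal / only
postnatal conditions, rewarding both enrichment strength and the breadth of
conditions in which a region is observed. Each class is then normalised so
the highest-scoring region in the catalogue reaches 1.0.

The ``variant="literal"`` alternative returns the complementary probability
of an equal-or-*better* enrichment (so stronger peaks score lower); it is
kept for sensitivity analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compendium import CompendiumCatalogue, CompendiumRegion
from .peaks import PRENATAL, POSTNATAL, Condition, Peak


@dataclass(frozen=True)
class ScoreTriple:
    """Normalised combined/prenatal/postnatal scores with their raw sums."""

    all: float
    prenatal: float
    postnatal: float
    raw_all: float
    raw_prenatal: float
    raw_postnatal: float

    def __post_init__(self):
        for v in (self.all, self.prenatal, self.postnatal):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"normalised score {v} outside [0, 1]")


class ConditionScoreTable:
    """Per-condition empirical -log10 p distributions.

    Built from each condition's final (post-consensus, post-mapping) peak
    set; the sorted arrays back rank queries in O(log N).
    """

    def __init__(self, per_condition_values: dict[str, "np.ndarray | list[float]"]):
        self.values: dict[str, np.ndarray] = {}
        for cid, vals in per_condition_values.items():
            arr = np.sort(np.asarray(vals, dtype=float))
            if arr.size == 0:
                raise ValueError(f"condition {cid!r}: empty score table")
            self.values[cid] = arr

    @classmethod
    def from_peaks(cls, per_condition_peaks: dict[str, list[Peak]]) -> "ConditionScoreTable":
        return cls({cid: [p.neg_log10_p for p in pks]
                    for cid, pks in per_condition_peaks.items() if pks})

    def n(self, condition_id: str) -> int:
        return int(self.values[condition_id].size)


def condition_score(
    neg_log10_p: float,
    table: "np.ndarray | list[float]",
    variant: str = "rank",
) -> float:
    """Empirical evidence score of one region under one condition.

    ``rank`` (default): fraction of the condition's peaks with equal-or-
    weaker enrichment — |{x <= neg_log10_p}| / N on the -log10 scale. Ties
    share a score through the >=-count rule; monotone non-decreasing in
    enrichment, and the condition's strongest peak scores exactly 1.

    ``literal``: the probability of an equal-or-better enrichment,
    |{x >= neg_log10_p}| / N (kept for sensitivity analysis).
    """
    arr = np.asarray(table, dtype=float)
    if arr.size == 0:
        raise ValueError("empty condition score table")
    arr = np.sort(arr)
    if variant == "rank":
        return float(np.searchsorted(arr, neg_log10_p, side="right")) / arr.size
    if variant == "literal":
        return float(arr.size - np.searchsorted(arr, neg_log10_p, side="left")) / arr.size
    raise ValueError(f"unknown score variant {variant!r}")


def score_catalogue(
    cat: CompendiumCatalogue,
    conditions: dict[str, Condition],
    tables: ConditionScoreTable,
    variant: str = "rank",
) -> CompendiumCatalogue:
    """Fill every region's ScoreTriple in place (and return the catalogue).

    Raw scores sum condition_score over the conditions holding evidence for
    the region; prenatal/postnatal sums restrict to that stage class.
    Conditions without evidence contribute 0. Each class is divided by its
    catalogue-wide raw maximum, so the top region per non-empty class
    scores 1.0.
    """
    for cid in {c for r in cat.regions for c in r.evidence}:
        if cid not in conditions:
            raise ValueError(f"condition {cid!r} missing from the manifest")

    raws = np.zeros((len(cat.regions), 3))  # all, prenatal, postnatal
    for i, region in enumerate(cat.regions):
        for cid, ev in region.evidence.items():
            s = condition_score(ev, tables.values[cid], variant=variant)
            raws[i, 0] += s
            if conditions[cid].stage_class == PRENATAL:
                raws[i, 1] += s
            else:
                raws[i, 2] += s

    maxima = raws.max(axis=0) if len(cat.regions) else np.zeros(3)
    norm = np.where(maxima > 0, maxima, 1.0)
    for i, region in enumerate(cat.regions):
        a, pre, post = raws[i] / norm
        region.scores = ScoreTriple(
            all=float(a), prenatal=float(pre), postnatal=float(post),
            raw_all=float(raws[i, 0]), raw_prenatal=float(raws[i, 1]),
            raw_postnatal=float(raws[i, 2]),
        )
    cat.provenance["score_normalisation_maxima"] = {
        "all": float(maxima[0]), "prenatal": float(maxima[1]),
        "postnatal": float(maxima[2]),
    }
    cat.provenance["score_variant"] = variant
    return cat


SCORE_CLASSES = ("all", "prenatal", "postnatal")


def rank_catalogue(cat: CompendiumCatalogue, score_class: str = "all") -> list[CompendiumRegion]:
    """Regions in descending score order for one class.

    Ties break by raw score, then genomic position, deterministically and
    independently of input order.
    """
    if score_class not in SCORE_CLASSES:
        raise ValueError(f"unknown score class {score_class!r}")
    if any(r.scores is None for r in cat.regions):
        raise ValueError("catalogue must be scored before ranking")

    def key(r: CompendiumRegion):
        sc = getattr(r.scores, score_class)
        raw = getattr(r.scores, "raw_" + score_class)
        return (-sc, -raw, r.interval.chrom, r.interval.start, r.interval.end)

    return sorted(cat.regions, key=key)
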