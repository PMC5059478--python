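"""Validation-rate calibration from transgenic reporter assays.

Candidate regions are matched to experimentally tested elements (VISTA-style
intervals labelled heart-positive / any-positive / negative); pairs sharing
at least 500 bp are kept. The binary outcome is then regressed on the
confidence score with a natural cubic regression spline (3 degrees of
freedom), giving a curve that estimates the in vivo validation rate across
the whole score range. Outside the observed score range the curve is held
constant at the boundary value, and evaluations are clamped to [0, 1].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .compendium import CompendiumCatalogue, CompendiumRegion
from .intervals import GenomicInterval, IntervalSet, merge_intervals, overlap_bases

logger = logging.getLogger(__name__)

MIN_OVERLAP_BP = 500
SPLINE_DF = 3
MIN_PAIRS = 10


@dataclass(frozen=True)
class ValidationElement:
    """One element tested in an E11.5 transgenic reporter assay."""

    element_id: str
    interval: GenomicInterval
    heart_positive: bool
    any_positive: bool

    def __post_init__(self):
        if self.heart_positive and not self.any_positive:
            raise ValueError(
                f"{self.element_id}: heart_positive implies any_positive")


def read_validation_table(path, assembly: str) -> list[ValidationElement]:
    """TSV with columns element_id, chrom, start, end, heart_positive, any_positive."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(ValidationElement(
            str(r.element_id),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), assembly),
            bool(int(r.heart_positive)), bool(int(r.any_positive)),
        ))
    return out


def _touches(iv: GenomicInterval, index: dict[str, list[GenomicInterval]]) -> bool:
    return any(overlap_bases(iv, o) > 0 for o in index.get(iv.chrom, ()))


def filter_elements(
    elements: list[ValidationElement],
    promoter_windows: IntervalSet | None = None,
    blacklist: IntervalSet | None = None,
) -> list[ValidationElement]:
    """Drop elements overlapping promoter windows or blacklisted sequence."""
    def index(s: IntervalSet | None):
        idx: dict[str, list[GenomicInterval]] = {}
        if s is not None:
            for iv in merge_intervals(s):
                idx.setdefault(iv.chrom, []).append(iv)
        return idx

    prom_idx, bl_idx = index(promoter_windows), index(blacklist)
    return [e for e in elements
            if not _touches(e.interval, prom_idx) and not _touches(e.interval, bl_idx)]


@dataclass
class MatchedPair:
    region: CompendiumRegion
    element: ValidationElement
    overlap: int


def match_validation(
    cat: CompendiumCatalogue,
    elements: list[ValidationElement],
    min_overlap: int = MIN_OVERLAP_BP,
    promoter_windows: IntervalSet | None = None,
    blacklist: IntervalSet | None = None,
) -> list[MatchedPair]:
    """(region, element) pairs sharing at least ``min_overlap`` bases.

    Elements overlapping promoter windows or the blacklist are excluded
    first. An element straddling several catalogue regions yields one pair
    per qualifying region.
    """
    elements = filter_elements(elements, promoter_windows, blacklist)
    by_chrom: dict[str, list[CompendiumRegion]] = {}
    for r in cat.regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    pairs = []
    for el in elements:
        for r in by_chrom.get(el.interval.chrom, ()):
            ov = overlap_bases(r.interval, el.interval)
            if ov >= min_overlap:
                pairs.append(MatchedPair(r, el, ov))
    return pairs


class CalibrationCurve:
    """Fitted score -> validation-rate function for one score class.

    A natural cubic regression spline with ``df=3`` fitted by ordinary least
    squares on the 0/1 outcomes (``link="logit"`` refits as a binomial GLM
    on the same basis). Constant beyond the fitted score range; values
    clamped to [0, 1]. ``degenerate`` marks an all-identical-outcome fit.
    """

    def __init__(self, score_class: str, design_info, params: np.ndarray,
                 lo: float, hi: float, n_elements: int,
                 link: str = "identity", degenerate_value: float | None = None):
        self.score_class = score_class
        self._design_info = design_info
        self._params = params
        self.lo = lo
        self.hi = hi
        self.n_elements = n_elements
        self.link = link
        self._degenerate_value = degenerate_value

    @property
    def degenerate(self) -> bool:
        return self._degenerate_value is not None

    def predict(self, scores) -> np.ndarray:
        x = np.atleast_1d(np.asarray(scores, dtype=float))
        if self.degenerate:
            return np.full(x.shape, self._degenerate_value)
        xc = np.clip(x, self.lo, self.hi)  # constant extrapolation
        (X,) = patsy.build_design_matrices([self._design_info], {"score": xc})
        eta = np.asarray(X) @ self._params
        if self.link == "logit":
            eta = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(eta, 0.0, 1.0)

    def __call__(self, scores):
        return self.predict(scores)

    def grid(self, n: int = 101) -> pd.DataFrame:
        s = np.linspace(0.0, 1.0, n)
        return pd.DataFrame({"score": s, "validation_rate": self.predict(s)})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "score_class": self.score_class,
                "link": self.link,
                "df": SPLINE_DF,
                "params": None if self.degenerate else list(map(float, self._params)),
                "degenerate_value": self._degenerate_value,
                "score_range": [self.lo, self.hi],
                "n_elements": self.n_elements,
            }, fh, indent=2)


def fit_validation_curve(
    pairs: list[MatchedPair],
    outcome: str = "heart_positive",
    score_class: str = "all",
    link: str = "identity",
    x: str = "score",
) -> CalibrationCurve:
    """Fit the validation-rate spline over matched pairs.

    ``outcome`` is ``heart_positive`` or ``any_positive``; ``score_class``
    selects which normalised score is the regressor. ``x="rank"`` regresses
    on the (0-1 scaled) descending score rank instead of the score value.
    """
    if outcome not in ("heart_positive", "any_positive"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if len(pairs) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} matched pairs, got {len(pairs)}")

    y = np.array([float(getattr(p.element, outcome)) for p in pairs])
    scores = np.array([getattr(p.region.scores, score_class) for p in pairs])
    if x == "rank":
        order = np.argsort(np.argsort(-scores))
        scores = 1.0 - order / max(len(scores) - 1, 1)
    elif x != "score":
        raise ValueError("x must be 'score' or 'rank'")

    n = len(pairs)
    if y.min() == y.max():
        logger.warning("all outcomes identical (%g); degenerate constant curve", y[0])
        return CalibrationCurve(score_class, None, np.zeros(0),
                                float(scores.min()), float(scores.max()), n,
                                link=link, degenerate_value=float(y[0]))

    data = {"score": scores}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = patsy.dmatrix(f"cr(score, df={SPLINE_DF})", data, return_type="dataframe")
        if link == "logit":
            model = sm.GLM(y, X, family=sm.families.Binomial())
        else:
            model = sm.OLS(y, X)
        res = model.fit()
    return CalibrationCurve(score_class, X.design_info, np.asarray(res.params),
                            float(scores.min()), float(scores.max()), n, link=link)


def rediscovery_rate(
    cat: CompendiumCatalogue,
    elements: list[ValidationElement],
    min_overlap: int = MIN_OVERLAP_BP,
    promoter_windows: IntervalSet | None = None,
    blacklist: IntervalSet | None = None,
) -> tuple[int, int, float]:
    """Fraction of heart-positive tested elements the catalogue rediscovers.

    Returns (n_overlapping_positive, n_positive, fraction) over the
    heart-positive elements that survive the promoter/blacklist filter; each
    element counts once however many regions it touches.
    """
    kept = filter_elements(elements, promoter_windows, blacklist)
    positives = [e for e in kept if e.heart_positive]
    if not positives:
        raise ValueError("no heart-positive elements after filtering")
    pairs = match_validation(cat, positives, min_overlap)
    hit_ids = {p.element.element_id for p in pairs}
    n_hit = sum(e.element_id in hit_ids for e in positives)
    return n_hit, len(positives), n_hit / len(positives)
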