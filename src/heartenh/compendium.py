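"""Integration of condition-level peaks into one merged candidate catalogue.

The union of all condition peak sets is merged; each merged region is
re-annotated with, per condition, the best (lowest) MACS p-value among the
condition's overlapping peaks, kept as -log10 p. Regions whose best evidence
across conditions is weaker than the significance gate (p <= 1e-10, i.e.
-log10 p >= 10) are dropped, as are regions touching the artifact blacklist.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, merge_intervals, subtract_intervals
from .peaks import Peak

logger = logging.getLogger(__name__)

DEFAULT_GATE = 10.0  # -log10 of the p <= 1e-10 significance gate


@dataclass
class CompendiumRegion:
    """A merged candidate enhancer with per-condition evidence.

    ``evidence`` maps condition id -> best -log10 p among that condition's
    peaks overlapping the region; a condition with no overlapping peak is
    absent (distinct from 0), so breadth of observation can be counted.
    """

    interval: GenomicInterval
    evidence: dict[str, float]
    scores: object | None = None  # ScoreTriple, filled by the scoring stage
    annotations: dict = field(default_factory=dict)

    @property
    def max_evidence(self) -> float:
        return max(self.evidence.values())

    @property
    def n_conditions(self) -> int:
        return len(self.evidence)


@dataclass
class CompendiumCatalogue:
    regions: list[CompendiumRegion]
    conditions: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def assembly(self) -> str:
        return self.regions[0].interval.assembly if self.regions else ""

    def interval_set(self) -> IntervalSet:
        return IntervalSet([r.interval for r in self.regions])


class _OverlapIndex:
    """Sorted per-chromosome peak index for best-overlapping-p lookup."""

    def __init__(self, peaks: list[Peak]):
        self.by_chrom: dict[str, tuple[list[int], list[Peak]]] = {}
        for chrom in {p.interval.chrom for p in peaks}:
            ps = sorted((p for p in peaks if p.interval.chrom == chrom),
                        key=lambda p: p.interval.start)
            self.by_chrom[chrom] = ([p.interval.start for p in ps], ps)

    def best_p(self, region: GenomicInterval) -> float | None:
        entry = self.by_chrom.get(region.chrom)
        if entry is None:
            return None
        starts, ps = entry
        best = None
        # peaks are bounded in length only by the data; scan left until starts
        # clear the region, right-bounded by start < region.end
        i = bisect.bisect_left(starts, region.end)
        for p in ps[:i]:
            if p.interval.end > region.start:
                if best is None or p.neg_log10_p > best:
                    best = p.neg_log10_p
        return best


def build_catalogue(
    per_condition_peaks: dict[str, list[Peak]],
    gate_neg_log10_p: float = DEFAULT_GATE,
    blacklist: IntervalSet | None = None,
    blacklist_mode: str = "drop",
    provenance: dict | None = None,
) -> CompendiumCatalogue:
    """Merge condition peak sets into a gated, blacklist-filtered catalogue.

    Parameters
    ----------
    per_condition_peaks : dict
        Condition id -> that condition's final (post-consensus, post-mapping,
        promoter-free) peaks, all on the reference assembly.
    gate_neg_log10_p : float
        A region survives iff its best evidence across conditions reaches
        this -log10 p (default 10.0, i.e. p <= 1e-10).
    blacklist : IntervalSet, optional
        Regions touching the blacklist by >= 1 base are removed
        (``blacklist_mode="drop"``) or trimmed (``"subtract"``).
    """
    if gate_neg_log10_p < 0:
        raise ValueError("gate must be >= 0")
    if blacklist_mode not in ("drop", "subtract"):
        raise ValueError("blacklist_mode must be 'drop' or 'subtract'")
    for cid, pks in per_condition_peaks.items():
        for p in pks:
            if p.condition_id != cid:
                raise ValueError(
                    f"peak tagged {p.condition_id!r} found under condition {cid!r}")

    all_intervals = [p.interval for pks in per_condition_peaks.values() for p in pks]
    if not all_intervals:
        logger.warning("no peaks supplied; returning empty catalogue")
        return CompendiumCatalogue([], sorted(per_condition_peaks), provenance or {})

    merged = merge_intervals(IntervalSet(all_intervals))
    n_merged = len(merged)

    if blacklist is not None and blacklist_mode == "subtract":
        merged = subtract_intervals(merged, blacklist)

    indexes = {cid: _OverlapIndex(pks) for cid, pks in per_condition_peaks.items()}
    bl_index = None
    if blacklist is not None and blacklist_mode == "drop":
        bl_index = _OverlapIndex(
            [Peak(iv, "__bl__", 0.0) for iv in merge_intervals(blacklist)]
        )

    regions: list[CompendiumRegion] = []
    n_gated = n_blacklisted = 0
    for iv in merged:
        evidence = {}
        for cid, idx in indexes.items():
            best = idx.best_p(iv)
            if best is not None:
                evidence[cid] = best
        if not evidence:
            continue
        if max(evidence.values()) < gate_neg_log10_p:
            n_gated += 1
            continue
        if bl_index is not None and bl_index.best_p(iv) is not None:
            n_blacklisted += 1
            continue
        regions.append(CompendiumRegion(iv, evidence))

    regions.sort(key=lambda r: r.interval)
    logger.info(
        "catalogue: %d merged regions -> %d gated out, %d blacklisted, %d kept",
        n_merged, n_gated, n_blacklisted, len(regions),
    )
    prov = dict(provenance or {})
    prov.update({
        "gate_neg_log10_p": gate_neg_log10_p,
        "blacklist_mode": blacklist_mode,
        "n_merged": n_merged,
        "n_gated_out": n_gated,
        "n_blacklisted": n_blacklisted,
        "n_regions": len(regions),
    })
    return CompendiumCatalogue(regions, sorted(per_condition_peaks), prov)


def size_summary(cat: CompendiumCatalogue) -> dict:
    """Region count, covered bases, and size-class counts/fractions."""
    if not cat.regions:
        raise ValueError("size_summary needs a non-empty catalogue")
    sizes = [r.interval.length for r in cat.regions]
    n = len(sizes)
    n_lt5 = sum(s < 5_000 for s in sizes)
    n_lt10 = sum(s < 10_000 for s in sizes)
    return {
        "n_regions": n,
        "total_bases": sum(sizes),
        "n_below_5kb": n_lt5,
        "n_below_10kb": n_lt10,
        "n_above_10kb": n - n_lt10,
        "fraction_below_5kb": n_lt5 / n,
        "fraction_below_10kb": n_lt10 / n,
    }


# ---------------------------------------------------------------------------
# catalogue TSV I/O

CATALOGUE_COLUMNS = [
    "chrom", "start", "end", "size",
    "score_All", "score_Prenatal", "score_Postnatal",
    "n_conditions", "max_neg_log10_p",
    "nearest_gene", "distance_to_nearest_gene",
    "nearest_heart_phenotype_gene", "gwas_hits",
]


def catalogue_to_frame(cat: CompendiumCatalogue) -> pd.DataFrame:
    rows = []
    for r in cat.regions:
        sc = r.scores
        ann = r.annotations
        rows.append({
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "size": r.interval.length,
            "score_All": round(sc.all, 6) if sc else float("nan"),
            "score_Prenatal": round(sc.prenatal, 6) if sc else float("nan"),
            "score_Postnatal": round(sc.postnatal, 6) if sc else float("nan"),
            "n_conditions": r.n_conditions,
            "max_neg_log10_p": r.max_evidence,
            "nearest_gene": ann.get("nearest_gene", ""),
            "distance_to_nearest_gene": ann.get("distance_to_nearest_gene", ""),
            "nearest_heart_phenotype_gene": ann.get("nearest_heart_phenotype_gene", ""),
            "gwas_hits": ann.get("gwas_hits", ""),
        })
    return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)


def write_catalogue(cat: CompendiumCatalogue, path, provenance_path=None) -> None:
    catalogue_to_frame(cat).to_csv(path, sep="\t", index=False)
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(cat.provenance, fh, indent=2, sort_keys=True)


def read_catalogue_frame(path) -> pd.DataFrame:
    """Read a catalogue TSV back as a DataFrame (for summary recomputation)."""
    return pd.read_csv(path, sep="\t")
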