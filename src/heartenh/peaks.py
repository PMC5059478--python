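"""Condition-tagged ChIP-seq peaks, replicate consensus, promoter partition.

A *condition* is one species x developmental stage x mark experiment (e.g.
"E11.5 mouse H3K27ac"); it is the unit over which evidence is later summed.
Peak significance is carried exclusively as -log10 of the MACS p-value, so a
gate of p <= 1e-10 is the threshold 10.0 on this scale and p ~ 1e-300 needs
no special handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    MixedAssemblyError,
    merge_intervals,
    overlap_bases,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

PRENATAL = "prenatal"
POSTNATAL = "postnatal"
STAGE_CLASSES = (PRENATAL, POSTNATAL)


@dataclass(frozen=True)
class Condition:
    """One species x stage x mark profiling experiment."""

    id: str
    species: str  # human | mouse
    stage: str  # free text, e.g. "E11.5", "P56", "34 years"
    stage_class: str  # prenatal | postnatal
    mark: str  # H3K27ac | p300

    def __post_init__(self):
        if self.stage_class not in STAGE_CLASSES:
            raise ValueError(
                f"condition {self.id!r}: stage_class must be one of {STAGE_CLASSES}, "
                f"got {self.stage_class!r}"
            )


@dataclass(frozen=True)
class Peak:
    """An enriched interval with its condition and -log10 MACS p-value."""

    interval: GenomicInterval
    condition_id: str
    neg_log10_p: float

    def __post_init__(self):
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    tss: int  # 0-based position
    strand: str  # + | -

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


# ---------------------------------------------------------------------------
# table I/O

MANIFEST_COLUMNS = ["id", "species", "stage", "stage_class", "mark",
                    "peak_file", "replicate_group"]


def read_manifest(path) -> pd.DataFrame:
    """Read the condition manifest TSV.

    Rows sharing an ``id`` are biological replicates of one condition and are
    distinguished by ``replicate_group``; they must agree on the descriptive
    columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    for cid, grp in df.groupby("id"):
        desc = grp[["species", "stage", "stage_class", "mark"]].drop_duplicates()
        if len(desc) > 1:
            raise ValueError(f"manifest {path}: replicates of {cid!r} disagree on metadata")
        if grp["replicate_group"].duplicated().any():
            raise ValueError(f"manifest {path}: duplicate replicate_group for {cid!r}")
    return df


def conditions_from_manifest(manifest: pd.DataFrame) -> dict[str, Condition]:
    out: dict[str, Condition] = {}
    for _, row in manifest.drop_duplicates("id").iterrows():
        out[row["id"]] = Condition(
            id=row["id"], species=row["species"], stage=row["stage"],
            stage_class=row["stage_class"], mark=row["mark"],
        )
    return out


def read_peaks(path, assembly: str, condition_id: str, p_col: int = 5) -> list[Peak]:
    """Read a peak BED file; column ``p_col`` (1-based) holds -log10(p).

    The default column 5 is the BED score slot; narrowPeak files carry the
    value in column 8 (pass ``p_col=8``).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < p_col:
                raise ValueError(f"{path}:{lineno}: expected >= {p_col} columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), assembly)
            peaks.append(Peak(iv, condition_id, float(fields[p_col - 1])))
    return peaks


def write_peaks(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for pk in sorted(peaks, key=lambda p: p.interval):
            iv = pk.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.condition_id}\t{pk.neg_log10_p:.6g}\n")


def read_tss_table(path) -> list[TssRecord]:
    """Read a TSS table TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "tss": int, "strand": str})
    return [TssRecord(r.gene, r.chrom, int(r.tss), r.strand) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# replicate consensus

def combine_replicates(replicates: list[list[Peak]]) -> list[Peak]:
    """Consensus of biological replicates by the best-p overlap rule.

    A peak is confirmed iff it overlaps at least one peak in *every* other
    replicate; confirmed overlapping peaks are merged into a single interval
    carrying the maximum -log10 p among the contributors (the best MACS
    p-value — no p-value is ever invented). A single replicate passes
    through unchanged.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if len(replicates) == 1:
        return list(replicates[0])

    assemblies = {p.interval.assembly for rep in replicates for p in rep}
    if len(assemblies) > 1:
        raise MixedAssemblyError(f"replicates span assemblies {sorted(assemblies)}")

    confirmed: list[Peak] = []
    for i, rep in enumerate(replicates):
        others = [r for j, r in enumerate(replicates) if j != i]
        for pk in rep:
            if all(any(overlap_bases(pk.interval, q.interval) > 0 for q in other)
                   for other in others):
                confirmed.append(pk)
    if not confirmed:
        return []

    merged = merge_intervals(IntervalSet([p.interval for p in confirmed]))
    out = []
    cid = confirmed[0].condition_id
    for region in merged:
        best = max(p.neg_log10_p for p in confirmed
                   if overlap_bases(p.interval, region) > 0)
        out.append(Peak(region, cid, best))
    return out


# ---------------------------------------------------------------------------
# promoter exclusion

def partition_promoters(
    peaks: list[Peak], tss: list[TssRecord], window: int = 1500
) -> tuple[list[Peak], list[Peak]]:
    """Split peaks into (promoter, enhancer) sets by centre-to-TSS distance.

    A peak is promoter-proximal iff its centre (lower median for even
    lengths) lies within ``window`` bases (inclusive) of any TSS on the same
    chromosome. The two outputs partition the input exactly.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    tss_by_chrom: dict[str, list[int]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t.tss)
    for v in tss_by_chrom.values():
        v.sort()

    import bisect

    promoters, enhancers = [], []
    for pk in peaks:
        centre = pk.interval.centre
        positions = tss_by_chrom.get(pk.interval.chrom, [])
        is_prom = False
        if positions:
            i = bisect.bisect_left(positions, centre)
            for j in (i - 1, i):
                if 0 <= j < len(positions) and abs(centre - positions[j]) <= window:
                    is_prom = True
                    break
        (promoters if is_prom else enhancers).append(pk)
    return promoters, enhancers


def tss_windows(tss: list[TssRecord], assembly: str, window: int = 1500) -> IntervalSet:
    """The +/-window intervals around each TSS, clamped at chromosome start."""
    out = []
    for t in tss:
        start = max(0, t.tss - window)
        out.append(GenomicInterval(t.chrom, start, t.tss + window + 1, assembly))
    return IntervalSet(out, assembly=assembly)


def subtract_tss_windows(
    enhancers: IntervalSet, tss: list[TssRecord], window: int = 1500
) -> IntervalSet:
    """Remove every base within +/-window of a TSS from the enhancer set.

    Guards against very large enriched regions whose centre escapes the
    promoter rule while the region still spans a promoter: the returned
    intervals are disjoint from every TSS window.
    """
    return subtract_intervals(enhancers, tss_windows(tss, enhancers.assembly, window))


def subtract_tss_from_peaks(
    peaks: list[Peak], tss: list[TssRecord], window: int = 1500
) -> list[Peak]:
    """Per-peak TSS-window subtraction; fragments inherit the parent's p."""
    out = []
    for pk in peaks:
        frags = subtract_tss_windows(IntervalSet([pk.interval]), tss, window)
        for frag in frags:
            out.append(replace(pk, interval=frag))
    return out
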