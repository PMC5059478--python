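"""Interval algebra and BED I/O underpinning every pipeline stage.

All coordinates are 0-based half-open (BED convention). Every interval is
tagged with the assembly it lives on, and set-level operations refuse to mix
assemblies: in a pipeline that shuttles regions between two genome builds,
silent coordinate-space confusion is the classic failure mode.

Coordinate pairs printed in prose (e.g. deletion spans quoted as
"chr5:122,092,252-122,094,768") follow the 1-based fully-closed convention;
:func:`span_length_1based` converts such a pair to a length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)


class MixedAssemblyError(ValueError):
    """Raised when an operation receives intervals on different assemblies."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome of one assembly.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open bounds; ``0 <= start < end``.
    assembly : str
        Assembly label, e.g. ``"hg19"`` or ``"asmA"`` in synthetic runs.
    payload : tuple of str
        Extra BED columns carried through I/O as opaque strings.
    """

    chrom: str
    start: int
    end: int
    assembly: str = ""
    payload: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        """Lower-median centre: floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 when disjoint).

    Symmetric; intervals on different chromosomes never overlap. Raises
    :class:`MixedAssemblyError` when assemblies differ.
    """
    if a.assembly != b.assembly:
        raise MixedAssemblyError(
            f"cannot overlap intervals on assemblies {a.assembly!r} and {b.assembly!r}"
        )
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def span_length_1based(printed_start: int, printed_end: int) -> int:
    """Length of a 1-based fully-closed span as printed in prose.

    A pair like (122092252, 122094768) denotes every base from the first to
    the last inclusive, so the length is ``end - start + 1``.
    """
    if printed_end < printed_start:
        raise ValueError(
            f"printed_end ({printed_end}) < printed_start ({printed_start})"
        )
    return printed_end - printed_start + 1


class IntervalSet:
    """A collection of :class:`GenomicInterval` on a single assembly.

    Normalisation sorts by (chrom, start, end) and collapses duplicate
    records. The assembly is inferred from members and enforced.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), assembly: str | None = None):
        self.intervals: list[GenomicInterval] = list(intervals)
        assemblies = {iv.assembly for iv in self.intervals}
        if len(assemblies) > 1:
            raise MixedAssemblyError(f"mixed assemblies in one set: {sorted(assemblies)}")
        if assembly is None:
            assembly = assemblies.pop() if assemblies else ""
        elif assemblies and assemblies != {assembly}:
            raise MixedAssemblyError(
                f"intervals on {assemblies.pop()!r} placed in a {assembly!r} set"
            )
        self.assembly = assembly
        self.sorted = False

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (self.assembly == other.assembly
                and sorted(self.intervals) == sorted(other.intervals))

    def normalize(self) -> "IntervalSet":
        """Return a sorted copy with duplicate records removed."""
        seen = set()
        out = []
        for iv in sorted(self.intervals):
            key = (iv.chrom, iv.start, iv.end, iv.payload)
            if key not in seen:
                seen.add(key)
                out.append(iv)
        s = IntervalSet(out, assembly=self.assembly)
        s.sorted = True
        return s

    def total_bases(self) -> int:
        """Covered bases counting overlaps once (computed on the merged set)."""
        return sum(iv.length for iv in merge_intervals(self))


def _check_same_assembly(*sets: IntervalSet) -> None:
    labels = {s.assembly for s in sets if len(s)}
    if len(labels) > 1:
        raise MixedAssemblyError(f"operation across assemblies {sorted(labels)}")


def merge_intervals(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge intervals closer than or equal to ``gap`` bases apart.

    With the default ``gap=0``, overlapping and book-ended intervals merge
    (mergeBed's default behaviour); the covered-base set is then preserved
    exactly. The result is minimal: no two output intervals on one
    chromosome are within ``gap`` of each other.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    ivs = sorted(s.intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, s.assembly)
            continue
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, s.assembly))
    res = IntervalSet(out, assembly=s.assembly)
    res.sorted = True
    return res


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases in ``a`` and not in ``b``, splitting where ``b`` punches holes.

    Zero-length fragments are dropped. Input payloads are not propagated
    (fragments are new records).
    """
    _check_same_assembly(a, b)
    b_merged = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in sorted(a.intervals):
        cur = iv.start
        for cut in by_chrom.get(iv.chrom, ()):
            if cut.end <= cur or cut.start >= iv.end:
                continue
            if cut.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, cut.start, a.assembly))
            cur = max(cur, cut.end)
            if cur >= iv.end:
                break
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end, a.assembly))
    res = IntervalSet(out, assembly=a.assembly)
    res.sorted = True
    return res


class BedParseError(ValueError):
    pass


def read_bed(path, assembly: str) -> IntervalSet:
    """Read a BED3+ file (tab-separated, 0-based half-open).

    ``track``/``browser``/``#`` lines are skipped. Extra columns are kept
    as the interval's ``payload``. Records with ``start >= end`` are
    rejected with a logged warning; otherwise-malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                logger.warning("%s:%d: zero/negative length record %s:%d-%d rejected",
                               path, lineno, chrom, start, end)
                continue
            out.append(GenomicInterval(chrom, start, end, assembly,
                                       payload=tuple(fields[3:])))
    return IntervalSet(out, assembly=assembly)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED3+ with payload columns appended, sorted."""
    with open(path, "w") as fh:
        for iv in sorted(s.intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), *iv.payload]
            fh.write("\t".join(cols) + "\n")
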