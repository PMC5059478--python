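"""Cross-assembly interval mapping through UCSC chain alignments.

Implements liftOver-style projection with three acceptance criteria applied
to every region:

* coverage   — at least ``min_fraction`` (default 0.5) of the region's bases
               must project through alignment blocks;
* uniqueness — all projected bases must lie on a single chain (stricter than
               a single chromosome, and deterministic);
* reciprocality — the projected region, mapped back with the reverse chain
               set under the same rules, must land on the original
               chromosome and overlap the original region by at least
               ``min_fraction`` of its length.

The mapped target is the minimal interval spanning all projected bases
(liftOver semantics): alignment gaps inside the span are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .intervals import GenomicInterval, overlap_bases


class ChainParseError(ValueError):
    pass


class MappingStatus(str, Enum):
    MAPPED = "mapped"
    UNMAPPED = "unmapped"
    AMBIGUOUS = "ambiguous"
    LOW_COVERAGE = "low_coverage"
    NON_RECIPROCAL = "non_reciprocal"


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block: equal-length source and target spans.

    Target coordinates are stored in forward-strand space; ``target_strand``
    records whether the alignment reverses orientation.
    """

    src_start: int
    src_end: int
    tgt_start: int
    tgt_end: int

    def __post_init__(self):
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ChainParseError("block source and target lengths differ")


@dataclass
class ChainAlignment:
    chain_id: str
    score: float
    src_chrom: str
    src_size: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str  # + | -
    blocks: list[ChainBlock]

    def project(self, iv: GenomicInterval) -> tuple[int, list[tuple[int, int]]]:
        """Project ``iv`` block-wise: (projected base count, target fragments).

        Fragments are forward-strand [start, end) pairs on the target
        chromosome.
        """
        bases = 0
        frags: list[tuple[int, int]] = []
        for blk in self.blocks:
            lo = max(iv.start, blk.src_start)
            hi = min(iv.end, blk.src_end)
            if hi <= lo:
                continue
            bases += hi - lo
            off_lo = lo - blk.src_start
            off_hi = hi - blk.src_start
            if self.tgt_strand == "+":
                frags.append((blk.tgt_start + off_lo, blk.tgt_start + off_hi))
            else:
                # reversed alignment: later source bases map to earlier
                # forward-strand target coordinates
                frags.append((blk.tgt_end - off_hi, blk.tgt_end - off_lo))
        return bases, frags


def read_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file.

    Header grammar: ``chain score tName tSize tStrand tStart tEnd qName
    qSize qStrand qStart qEnd id``; the t-side is the mapping source and the
    q-side the target (as in UCSC liftOver chain files, where an
    mm10-to-hg19 file carries mm10 on the t-side). Data lines are
    ``size dt dq`` triplets with a bare ``size`` terminator. Block
    arithmetic must reconstruct the declared tEnd/qEnd exactly.
    """
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("chain"):
            raise ChainParseError(f"{path}:{i + 1}: expected chain header, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise ChainParseError(f"{path}:{i + 1}: chain header needs 13 fields")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        if t_strand != "+":
            raise ChainParseError(f"chain {chain_id}: source strand must be +")
        if q_strand not in "+-":
            raise ChainParseError(f"chain {chain_id}: bad target strand {q_strand!r}")

        i += 1
        blocks: list[ChainBlock] = []
        t_cur, q_cur = t_start, q_start
        done = False
        while i < n:
            data = lines[i].strip()
            i += 1
            if not data:
                continue
            nums = data.split()
            if len(nums) == 1:
                size = int(nums[0])
                dt = dq = None
            elif len(nums) == 3:
                size, dt, dq = (int(x) for x in nums)
                if dt < 0 or dq < 0:
                    raise ChainParseError(f"chain {chain_id}: negative gap")
            else:
                raise ChainParseError(f"{path}:{i}: bad block line {data!r}")
            if size < 0:
                raise ChainParseError(f"chain {chain_id}: negative block size")
            if size > 0:
                if q_strand == "+":
                    tgt_lo, tgt_hi = q_cur, q_cur + size
                else:
                    tgt_lo, tgt_hi = q_size - (q_cur + size), q_size - q_cur
                blocks.append(ChainBlock(t_cur, t_cur + size, tgt_lo, tgt_hi))
            t_cur += size
            q_cur += size
            if dt is None:
                done = True
                break
            t_cur += dt
            q_cur += dq
        if not done:
            raise ChainParseError(f"{path}: chain {chain_id} truncated at line {i}")
        if t_cur != t_end or q_cur != q_end:
            raise ChainParseError(
                f"chain {chain_id}: block arithmetic gives ends ({t_cur}, {q_cur}), "
                f"header declares ({t_end}, {q_end})"
            )
        chains.append(ChainAlignment(chain_id, float(score), t_name, t_size,
                                     q_name, q_size, q_strand, blocks))
    return chains


def write_chain(chains: list[ChainAlignment], path) -> None:
    """Serialise chains back to UCSC chain format (inverse of read_chain)."""
    with open(path, "w") as fh:
        for ch in chains:
            if not ch.blocks:
                continue
            t_start = ch.blocks[0].src_start
            t_end = ch.blocks[-1].src_end
            if ch.tgt_strand == "+":
                q_start = ch.blocks[0].tgt_start
                q_end = ch.blocks[-1].tgt_end
            else:
                q_start = ch.tgt_size - ch.blocks[0].tgt_end
                q_end = ch.tgt_size - ch.blocks[-1].tgt_start
            fh.write(
                f"chain {ch.score:g} {ch.src_chrom} {ch.src_size} + {t_start} {t_end} "
                f"{ch.tgt_chrom} {ch.tgt_size} {ch.tgt_strand} {q_start} {q_end} {ch.chain_id}\n"
            )
            for j, blk in enumerate(ch.blocks):
                size = blk.src_end - blk.src_start
                if j + 1 < len(ch.blocks):
                    nxt = ch.blocks[j + 1]
                    dt = nxt.src_start - blk.src_end
                    if ch.tgt_strand == "+":
                        dq = nxt.tgt_start - blk.tgt_end
                    else:
                        dq = blk.tgt_start - nxt.tgt_end
                    fh.write(f"{size} {dt} {dq}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


@dataclass
class MappingResult:
    status: MappingStatus
    target: GenomicInterval | None = None
    mapped_fraction: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status is MappingStatus.MAPPED


def map_interval(
    iv: GenomicInterval,
    chains: list[ChainAlignment],
    min_fraction: float = 0.5,
    target_assembly: str = "",
) -> MappingResult:
    """Project one interval through a chain set.

    Only chains contributing >= 1 projected base count toward uniqueness;
    more than one such chain (or more than one target chromosome) is
    ambiguous. Coverage below ``min_fraction`` of the interval's bases is
    low_coverage. The mapped target spans all projected bases.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    touching = [ch for ch in chains if ch.src_chrom == iv.chrom]
    if not touching:
        return MappingResult(MappingStatus.UNMAPPED)

    hits: list[tuple[ChainAlignment, int, list[tuple[int, int]]]] = []
    for ch in touching:
        bases, frags = ch.project(iv)
        if bases > 0:
            hits.append((ch, bases, frags))
    if not hits:
        return MappingResult(MappingStatus.LOW_COVERAGE, mapped_fraction=0.0)
    if len(hits) > 1 or len({h[0].tgt_chrom for h in hits}) > 1:
        return MappingResult(MappingStatus.AMBIGUOUS)

    chain, bases, frags = hits[0]
    fraction = bases / iv.length
    if fraction < min_fraction:
        return MappingResult(MappingStatus.LOW_COVERAGE, mapped_fraction=fraction)
    start = min(f[0] for f in frags)
    end = max(f[1] for f in frags)
    target = GenomicInterval(chain.tgt_chrom, start, end,
                             target_assembly or iv.assembly)
    return MappingResult(MappingStatus.MAPPED, target=target, mapped_fraction=fraction)


def map_reciprocal(
    iv: GenomicInterval,
    forward: list[ChainAlignment],
    backward: list[ChainAlignment],
    min_fraction: float = 0.5,
    target_assembly: str = "",
) -> MappingResult:
    """Forward mapping with a reciprocal round-trip filter.

    The forward target, mapped back through ``backward`` under the same
    coverage/uniqueness rules, must land on the original chromosome and
    overlap the original interval by >= ``min_fraction`` of its length;
    otherwise the result is non_reciprocal. Reciprocal filtering only ever
    removes mappings, never changes the forward target.
    """
    fwd = map_interval(iv, forward, min_fraction, target_assembly)
    if not fwd.ok:
        return fwd
    back = map_interval(fwd.target, backward, min_fraction, iv.assembly)
    if not back.ok:
        return MappingResult(MappingStatus.NON_RECIPROCAL, mapped_fraction=fwd.mapped_fraction)
    rt = back.target
    if rt.chrom != iv.chrom or overlap_bases(rt, iv) < min_fraction * iv.length:
        return MappingResult(MappingStatus.NON_RECIPROCAL, mapped_fraction=fwd.mapped_fraction)
    return fwd


def identity_chains(chrom_sizes: dict[str, int], src_assembly: str = "",
                    tgt_assembly: str = "") -> list[ChainAlignment]:
    """One whole-chromosome identity chain per chromosome (testing aid)."""
    out = []
    for i, (chrom, size) in enumerate(sorted(chrom_sizes.items()), start=1):
        out.append(ChainAlignment(str(i), float(size), chrom, size, chrom, size,
                                  "+", [ChainBlock(0, size, 0, size)]))
    return out
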