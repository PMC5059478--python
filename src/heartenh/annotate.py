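"""Gene and GWAS-variant annotation of catalogue regions.

Regions are annotated with the nearest gene TSS (optionally restricted to
genes with curated heart phenotypes in the mouse-genetics or human-phenotype
ontologies), and intersected with LD-expanded GWAS variants: proxies are
kept when r^2 >= 0.8 with the lead variant and within 500 kb of it, and a
variant hits a region when its position falls inside the half-open region
interval.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import CompendiumCatalogue, CompendiumRegion
from .intervals import GenomicInterval

MIN_R2 = 0.8
MAX_LEAD_DISTANCE = 500_000


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    chrom: str
    tss: int
    strand: str
    heart_phenotype_mgi: bool = False
    heart_phenotype_hpo: bool = False

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS variant: lead or LD proxy. 0-based position internally."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    lead_rsid: str
    r2: float
    distance_to_lead: int

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must be in [0, 1]")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


def read_gene_table(path) -> list[GeneRecord]:
    """TSV: gene, chrom, tss, strand [, heart_phenotype_mgi, heart_phenotype_hpo]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(GeneRecord(
            str(r.gene), str(r.chrom), int(r.tss), str(r.strand),
            bool(int(getattr(r, "heart_phenotype_mgi", 0))),
            bool(int(getattr(r, "heart_phenotype_hpo", 0))),
        ))
    return out


def read_snp_table(path, coords: int = 1) -> list[SnpRecord]:
    """TSV: rsid, chrom, pos, trait, lead_rsid, r2, distance_to_lead.

    Positions are 1-based (VCF-style) by default and converted internally;
    pass ``coords=0`` for files already 0-based.
    """
    if coords not in (0, 1):
        raise ValueError("coords must be 0 or 1")
    df = pd.read_csv(path, sep="\t")
    return [SnpRecord(str(r.rsid), str(r.chrom), int(r.pos) - coords, str(r.trait),
                      str(r.lead_rsid), float(r.r2), int(r.distance_to_lead))
            for r in df.itertuples()]


GENE_FILTERS = ("all", "mgi_heart", "hpo_heart")


def nearest_gene(
    region: CompendiumRegion | GenomicInterval,
    genes: list[GeneRecord],
    filter: str = "all",
) -> tuple[GeneRecord | None, int | None]:
    """Nearest TSS to the region centre within the filtered gene set.

    Distance is minimised as |centre - tss| over all chromosome-matched
    genes passing the filter; the returned signed distance is tss - centre
    (positive when the TSS lies at a greater coordinate than the centre).
    Ties break by smaller TSS coordinate, then gene symbol. Returns
    (None, None) when the filtered set is empty on that chromosome.
    """
    if filter not in GENE_FILTERS:
        raise ValueError(f"unknown gene filter {filter!r}")
    iv = region.interval if isinstance(region, CompendiumRegion) else region
    centre = iv.centre
    best: tuple[int, int, str] | None = None
    best_gene = None
    for g in genes:
        if g.chrom != iv.chrom:
            continue
        if filter == "mgi_heart" and not g.heart_phenotype_mgi:
            continue
        if filter == "hpo_heart" and not g.heart_phenotype_hpo:
            continue
        key = (abs(centre - g.tss), g.tss, g.gene)
        if best is None or key < best:
            best, best_gene = key, g
    if best_gene is None:
        return None, None
    return best_gene, best_gene.tss - centre


def annotate_genes(cat: CompendiumCatalogue, genes: list[GeneRecord]) -> None:
    """Attach nearest-gene and nearest-heart-phenotype-gene annotations."""
    for r in cat.regions:
        g, d = nearest_gene(r, genes, "all")
        r.annotations["nearest_gene"] = g.gene if g else "none"
        r.annotations["distance_to_nearest_gene"] = d if d is not None else ""
        hits = []
        for filt in ("mgi_heart", "hpo_heart"):
            hg, _ = nearest_gene(r, genes, filt)
            if hg is not None and hg.gene not in hits:
                hits.append(hg.gene)
        r.annotations["nearest_heart_phenotype_gene"] = ";".join(hits) if hits else "none"


GWAS_COLUMNS = ["rsid", "chrom", "pos", "trait", "lead_rsid", "r2",
                "distance_to_lead", "region_chrom", "region_start", "region_end",
                "score_All", "score_Prenatal", "score_Postnatal"]


def intersect_gwas(
    cat: CompendiumCatalogue,
    snps: list[SnpRecord],
    min_r2: float = MIN_R2,
    max_lead_distance: int = MAX_LEAD_DISTANCE,
) -> pd.DataFrame:
    """One row per (variant, region) containment hit, best-scored first.

    Variants are filtered to r2 >= ``min_r2`` and lead distance <=
    ``max_lead_distance`` (lead variants pass trivially with r2=1 at
    distance 0); a variant hits a region iff region.start <= pos <
    region.end. Output is sorted descending by the region's combined score.
    """
    by_chrom: dict[str, tuple[list[int], list[CompendiumRegion]]] = {}
    for chrom in {r.interval.chrom for r in cat.regions}:
        rs = [r for r in cat.regions if r.interval.chrom == chrom]
        rs.sort(key=lambda r: r.interval.start)
        by_chrom[chrom] = ([r.interval.start for r in rs], rs)

    rows = []
    for s in snps:
        if s.r2 < min_r2 or s.distance_to_lead > max_lead_distance:
            continue
        entry = by_chrom.get(s.chrom)
        if entry is None:
            continue
        starts, rs = entry
        i = bisect.bisect_right(starts, s.pos)
        for r in rs[max(0, i - 64):i]:  # regions are non-overlapping; scan back
            if r.interval.start <= s.pos < r.interval.end:
                sc = r.scores
                rows.append({
                    "rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
                    "trait": s.trait, "lead_rsid": s.lead_rsid, "r2": s.r2,
                    "distance_to_lead": s.distance_to_lead,
                    "region_chrom": r.interval.chrom,
                    "region_start": r.interval.start,
                    "region_end": r.interval.end,
                    "score_All": sc.all if sc else np.nan,
                    "score_Prenatal": sc.prenatal if sc else np.nan,
                    "score_Postnatal": sc.postnatal if sc else np.nan,
                })
    df = pd.DataFrame(rows, columns=GWAS_COLUMNS)
    if len(df):
        df = df.sort_values(["score_All", "chrom", "pos"],
                            ascending=[False, True, True]).reset_index(drop=True)
    return df


def locus_report(
    cat: CompendiumCatalogue,
    snps: list[SnpRecord],
    locus: GenomicInterval,
    min_r2: float = MIN_R2,
    max_lead_distance: int = MAX_LEAD_DISTANCE,
) -> dict:
    """In-enhancer variant hits restricted to one locus.

    Reports the hit count, per-hit region scores, and the maximum combined
    score among hit regions (None when no hits).
    """
    df = intersect_gwas(cat, snps, min_r2, max_lead_distance)
    if len(df):
        mask = ((df["chrom"] == locus.chrom)
                & (df["pos"] >= locus.start) & (df["pos"] < locus.end))
        df = df[mask].reset_index(drop=True)
    return {
        "locus": str(locus),
        "n_hits": int(len(df)),
        "hits": df,
        "max_score": float(df["score_All"].max()) if len(df) else None,
    }
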