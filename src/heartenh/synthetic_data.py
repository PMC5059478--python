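"""Seeded synthetic worlds with planted ground truth for the full pipeline.

A world consists of two assemblies linked by generated chain files, a
condition-structured set of peak files (the cross-assembly conditions in the
second assembly's coordinates), planted enhancers with known strength theta
and known active-condition subsets, TSS/gene tables, a blacklist, validation
elements whose positive-label probability is monotone in theta, and
lead+proxy GWAS variant sets. Everything derives from one seeded generator,
so one seed gives byte-identical output files.

The defaults are deliberately desk-scale (2 chromosomes x 5 Mb per assembly,
8 conditions, 300 planted enhancers) so the end-to-end pipeline runs in
seconds while still exercising replicate consensus, liftover, gating,
scoring, calibration and annotation with a known answer key.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chainmap import ChainAlignment, ChainBlock, map_interval, map_reciprocal, write_chain
from .intervals import GenomicInterval, IntervalSet, overlap_bases, write_bed
from .peaks import MANIFEST_COLUMNS

ASSEMBLY_A = "asmA"  # reference ("human-like")
ASSEMBLY_B = "asmB"  # mapped ("mouse-like")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults define the study conditions."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_enhancers: int = 300
    enhancer_len_min: int = 1_000
    enhancer_len_max: int = 3_000
    enhancer_min_gap: int = 1_000

    # planted peak -log10 p model: Normal(mu0 + beta*theta, sigma),
    # truncated below at the significance gate
    theta_shape: float = 2.0
    theta_scale: float = 1.0
    p_mu0: float = 10.0
    p_beta: float = 5.0
    p_sigma: float = 3.0
    gate: float = 10.0
    jitter_sd: float = 100.0  # peak boundary jitter, bp
    jitter_max: int = 300

    # background peaks: -log10 p = floor + Exponential(scale)
    background_rate_per_mb: float = 20.0
    background_floor: float = 2.0
    background_scale: float = 1.5
    background_len_min: int = 500
    background_len_max: int = 2_000

    # activity breadth grows with theta
    activity_base: float = 0.10
    activity_slope: float = 0.20

    n_replicates: int = 1

    # chain structure
    segment_length: int = 250_000
    block_len_min: int = 30_000
    block_len_max: int = 60_000
    max_gap: int = 100
    inversion_rate: float = 0.05
    duplication_rate: float = 0.0
    nonreciprocal_rate: float = 0.0

    n_genes: int = 60
    promoter_window: int = 1_500
    gene_mgi_heart_rate: float = 0.2
    gene_hpo_heart_rate: float = 0.15

    n_blacklist: int = 15
    blacklist_len_min: int = 5_000
    blacklist_len_max: int = 20_000

    n_validation_planted: int = 100
    n_validation_background: int = 50
    validation_a: float = -2.0  # logistic intercept on theta
    validation_b: float = 1.5  # logistic slope on theta
    any_positive_extra: float = 0.15
    validation_min_len: int = 1_200

    n_lead_snps: int = 30
    proxies_per_lead: float = 8.0
    snp_in_enhancer_fraction: float = 0.5  # of lead SNPs

    def validate(self) -> None:
        if self.n_enhancers < 1:
            raise ValueError("n_enhancers must be >= 1")
        for name in ("background_rate_per_mb", "inversion_rate",
                     "duplication_rate", "nonreciprocal_rate", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


CONDITION_DEFS = [
    # id, species, stage, stage_class, mark
    ("hs_fetal_h3k27ac", "human", "17 weeks", "prenatal", "H3K27ac"),
    ("hs_fetal_p300", "human", "fetal", "prenatal", "p300"),
    ("hs_adult_lv", "human", "34 years LV", "postnatal", "H3K27ac"),
    ("hs_adult_rv", "human", "46 years RV", "postnatal", "H3K27ac"),
    ("mm_e11_h3k27ac", "mouse", "E11.5", "prenatal", "H3K27ac"),
    ("mm_e14_h3k27ac", "mouse", "E14.5", "prenatal", "H3K27ac"),
    ("mm_p0_h3k27ac", "mouse", "P0", "postnatal", "H3K27ac"),
    ("mm_adult_h3k27ac", "mouse", "P56", "postnatal", "H3K27ac"),
]


@dataclass
class PlantedEnhancer:
    enhancer_id: str
    interval: GenomicInterval  # reference (assembly A) coordinates
    interval_b: GenomicInterval  # image on assembly B
    theta: float
    active_conditions: list[str]
    max_emitted: float = 0.0


@dataclass
class SyntheticWorld:
    config: GeneratorConfig
    seed: int
    out_dir: str
    chrom_lengths: dict[str, int]
    enhancers: list[PlantedEnhancer]
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def gate(self) -> float:
        return self.config.gate

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.enhancers:
            rows.append({
                "enhancer_id": e.enhancer_id,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "theta": round(e.theta, 6),
                "n_active": len(e.active_conditions),
                "active_conditions": ";".join(e.active_conditions),
                "max_emitted_neg_log10_p": round(e.max_emitted, 6),
                "exceeds_gate": int(e.max_emitted >= self.config.gate),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chain construction


def _build_chains(cfg: GeneratorConfig, rng: np.random.Generator,
                  chrom_lengths: dict[str, int]):
    """Segment-wise B->A chains, their A->B inverses, and stress variants.

    Each B chromosome is partitioned into segments; a segment maps to an
    offset location on the same A chromosome through a few blocks separated
    by small indel gaps. Intervals straddling a segment boundary project on
    two chains and therefore come out ambiguous, as with real chain files.
    With positive duplication / non-reciprocality rates, some segments gain
    a second forward chain (ambiguity) or a backward chain pointing
    elsewhere (reciprocality failure).
    """
    forward: list[ChainAlignment] = []   # source B, target A
    backward: list[ChainAlignment] = []  # source A, target B
    next_id = 1
    L_pad = 4_000

    for chrom, L in sorted(chrom_lengths.items()):
        n_seg = L // cfg.segment_length
        for i in range(n_seg):
            b_lo = i * cfg.segment_length
            b_hi = min((i + 1) * cfg.segment_length, L)
            seg_len = b_hi - b_lo
            delta = int(rng.integers(-1_000, 1_001))
            a_lo = min(max(0, b_lo + delta), L - seg_len - L_pad)
            inverted = rng.random() < cfg.inversion_rate

            blocks: list[ChainBlock] = []
            if inverted:
                blocks.append(ChainBlock(b_lo, b_hi, a_lo, a_lo + seg_len))
                strand = "-"
            else:
                strand = "+"
                src, tgt = b_lo, a_lo
                while src < b_hi:
                    size = int(rng.integers(cfg.block_len_min, cfg.block_len_max + 1))
                    size = min(size, b_hi - src)
                    blocks.append(ChainBlock(src, src + size, tgt, tgt + size))
                    src += size
                    if src >= b_hi:
                        break
                    dt = int(rng.integers(0, cfg.max_gap + 1))
                    dq = int(rng.integers(0, cfg.max_gap + 1))
                    src += dt
                    tgt += size + dq
            fwd = ChainAlignment(str(next_id), float(seg_len), chrom, L, chrom, L,
                                 strand, blocks)
            next_id += 1
            forward.append(fwd)

            # inverse chain: swap source/target block coordinates
            inv_blocks = sorted(
                (ChainBlock(b.tgt_start, b.tgt_end, b.src_start, b.src_end)
                 for b in blocks),
                key=lambda b: b.src_start,
            )
            nonrecip = rng.random() < cfg.nonreciprocal_rate
            if nonrecip:
                # backward chain sends the A image to a disjoint B location
                shift = (b_lo + L // 2 + cfg.segment_length) % (L - seg_len - 1)
                if abs(shift - b_lo) < seg_len + 1_000:
                    shift = (shift + 2 * cfg.segment_length) % (L - seg_len - 1)
                inv_blocks = [ChainBlock(b.src_start, b.src_end,
                                         shift + (b.src_start - inv_blocks[0].src_start),
                                         shift + (b.src_end - inv_blocks[0].src_start))
                              for b in inv_blocks]
            backward.append(ChainAlignment(str(next_id), float(seg_len), chrom, L,
                                           chrom, L, strand, inv_blocks))
            next_id += 1

            if rng.random() < cfg.duplication_rate:
                # duplicate the segment to a second A location -> ambiguity
                dup_lo = (a_lo + L // 2) % (L - seg_len - L_pad)
                dup = ChainAlignment(str(next_id), float(seg_len), chrom, L, chrom, L,
                                     "+", [ChainBlock(b_lo, b_hi, dup_lo, dup_lo + seg_len)])
                next_id += 1
                forward.append(dup)
    return forward, backward


# ---------------------------------------------------------------------------
# generation


def _place_intervals(rng, chrom_lengths, n, len_min, len_max, forbidden, min_gap,
                     max_attempts=20_000, extra_ok=None):
    """Rejection-sample n non-overlapping intervals avoiding forbidden zones."""
    chroms = sorted(chrom_lengths)
    placed: list[GenomicInterval] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} intervals in the synthetic genome "
                f"(placed {len(placed)}): genome too small or constraints too tight")
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(len_min, len_max + 1))
        L = chrom_lengths[chrom]
        start = int(rng.integers(0, L - length))
        iv = GenomicInterval(chrom, start, start + length, ASSEMBLY_A)
        pad = GenomicInterval(chrom, max(0, start - min_gap), start + length + min_gap,
                              ASSEMBLY_A)
        if any(overlap_bases(pad, f) > 0 for f in forbidden if f.chrom == chrom):
            continue
        if any(overlap_bases(pad, p) > 0 for p in placed if p.chrom == chrom):
            continue
        if extra_ok is not None and not extra_ok(iv):
            continue
        placed.append(iv)
    return placed


def generate(config: GeneratorConfig, seed: int, out_dir: str) -> SyntheticWorld:
    """Generate a synthetic world and write every input file the pipeline reads.

    Outputs under ``out_dir``: manifest.tsv, peaks/*.bed, chains/b_to_a.chain
    and chains/a_to_b.chain, tss.tsv, genes.tsv, blacklist.bed,
    validation.tsv, snps.tsv, truth.tsv and world.json.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "peaks"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "chains"), exist_ok=True)

    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genome_mb = sum(chrom_lengths.values()) / 1e6

    forward, backward = _build_chains(config, rng, chrom_lengths)
    paths = {
        "forward_chain": os.path.join(out_dir, "chains", "b_to_a.chain"),
        "backward_chain": os.path.join(out_dir, "chains", "a_to_b.chain"),
    }
    write_chain(forward, paths["forward_chain"])
    write_chain(backward, paths["backward_chain"])

    # --- genes / TSS on the reference assembly
    margin = config.promoter_window + config.jitter_max + 200
    gene_pos: list[tuple[str, int]] = []
    chroms = sorted(chrom_lengths)
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(margin, chrom_lengths[chrom] - margin))
        gene_pos.append((chrom, pos))
    genes = pd.DataFrame({
        "gene": [f"GENE{i + 1}" for i in range(config.n_genes)],
        "chrom": [c for c, _ in gene_pos],
        "tss": [p for _, p in gene_pos],
        "strand": [("+", "-")[int(rng.integers(2))] for _ in range(config.n_genes)],
        "heart_phenotype_mgi": (rng.random(config.n_genes) < config.gene_mgi_heart_rate).astype(int),
        "heart_phenotype_hpo": (rng.random(config.n_genes) < config.gene_hpo_heart_rate).astype(int),
    })
    paths["genes"] = os.path.join(out_dir, "genes.tsv")
    genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["tss"] = os.path.join(out_dir, "tss.tsv")
    genes[["gene", "chrom", "tss", "strand"]].to_csv(paths["tss"], sep="\t", index=False)

    tss_forbidden = [GenomicInterval(c, max(0, p - margin), p + margin, ASSEMBLY_A)
                     for c, p in gene_pos]

    # --- blacklist
    blacklist = _place_intervals(
        rng, chrom_lengths, config.n_blacklist,
        config.blacklist_len_min, config.blacklist_len_max,
        forbidden=tss_forbidden, min_gap=500,
    )
    paths["blacklist"] = os.path.join(out_dir, "blacklist.bed")
    write_bed(IntervalSet(blacklist, ASSEMBLY_A), paths["blacklist"])

    # --- planted enhancers: away from TSS windows / blacklist, cleanly
    #     reciprocal across assemblies even after boundary jitter
    pad = config.jitter_max + 100

    def cleanly_mapped(iv: GenomicInterval) -> bool:
        wide = GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad, ASSEMBLY_A)
        res = map_reciprocal(wide, backward, forward, 0.95, ASSEMBLY_B)
        return res.ok

    forbidden = tss_forbidden + blacklist
    enh_ivs = _place_intervals(
        rng, chrom_lengths, config.n_enhancers,
        config.enhancer_len_min, config.enhancer_len_max,
        forbidden=forbidden, min_gap=config.enhancer_min_gap,
        extra_ok=cleanly_mapped,
    )

    conditions = [c for c in CONDITION_DEFS]
    cond_ids = [c[0] for c in conditions]
    enhancers: list[PlantedEnhancer] = []
    for i, iv in enumerate(enh_ivs):
        theta = float(rng.gamma(config.theta_shape, config.theta_scale))
        p_active = min(0.95, config.activity_base + config.activity_slope * theta)
        active = [cid for cid in cond_ids if rng.random() < p_active]
        if not active:
            active = [cond_ids[int(rng.integers(len(cond_ids)))]]
        b_iv = map_interval(iv, backward, 0.5, ASSEMBLY_B).target
        enhancers.append(PlantedEnhancer(f"enh{i + 1:04d}", iv, b_iv, theta, active))

    # --- peak emission per condition x replicate
    manifest_rows = []
    for cid, species, stage, stage_class, mark in conditions:
        assembly = ASSEMBLY_A if species == "human" else ASSEMBLY_B
        for rep in range(1, config.n_replicates + 1):
            rows = []
            for enh in enhancers:
                if cid not in enh.active_conditions:
                    continue
                base = enh.interval if assembly == ASSEMBLY_A else enh.interval_b
                ds = int(np.clip(rng.normal(0, config.jitter_sd), -config.jitter_max,
                                 config.jitter_max))
                de = int(np.clip(rng.normal(0, config.jitter_sd), -config.jitter_max,
                                 config.jitter_max))
                start = max(0, base.start + ds)
                end = max(start + 200, base.end + de)
                # truncated normal: resample below the gate
                val = rng.normal(config.p_mu0 + config.p_beta * enh.theta, config.p_sigma)
                tries = 0
                while val < config.gate and tries < 200:
                    val = rng.normal(config.p_mu0 + config.p_beta * enh.theta,
                                     config.p_sigma)
                    tries += 1
                val = max(val, config.gate)
                enh.max_emitted = max(enh.max_emitted, float(val))
                rows.append((base.chrom, start, end, float(val)))
            n_bg = int(rng.poisson(config.background_rate_per_mb * genome_mb))
            for _ in range(n_bg):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = int(rng.integers(config.background_len_min,
                                          config.background_len_max + 1))
                start = int(rng.integers(0, chrom_lengths[chrom] - length))
                val = config.background_floor + float(rng.exponential(config.background_scale))
                rows.append((chrom, start, start + length, val))
            rows.sort()
            fname = os.path.join("peaks", f"{cid}_rep{rep}.bed")
            with open(os.path.join(out_dir, fname), "w") as fh:
                for j, (chrom, start, end, val) in enumerate(rows):
                    fh.write(f"{chrom}\t{start}\t{end}\tpeak{j + 1}\t{val:.6f}\n")
            manifest_rows.append({
                "id": cid, "species": species, "stage": stage,
                "stage_class": stage_class, "mark": mark,
                "peak_file": fname, "replicate_group": f"rep{rep}",
            })
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    paths["manifest"] = os.path.join(out_dir, "manifest.tsv")
    manifest.to_csv(paths["manifest"], sep="\t", index=False)

    # --- validation elements: planted subset + background negatives
    n_val = min(config.n_validation_planted, len(enhancers))
    chosen = rng.choice(len(enhancers), size=n_val, replace=False)
    val_rows = []
    for k, idx in enumerate(sorted(chosen)):
        enh = enhancers[idx]
        iv = enh.interval
        grow = max(0, config.validation_min_len - iv.length)
        lo = max(0, iv.start - grow // 2)
        hi = iv.end + (grow - grow // 2)
        p_pos = 1.0 / (1.0 + np.exp(-(config.validation_a
                                      + config.validation_b * enh.theta)))
        heart = bool(rng.random() < p_pos)
        anyp = heart or bool(rng.random() < config.any_positive_extra)
        val_rows.append({"element_id": f"el{k + 1:04d}", "chrom": iv.chrom,
                         "start": lo, "end": hi,
                         "heart_positive": int(heart), "any_positive": int(anyp)})
    bg_elements = _place_intervals(
        rng, chrom_lengths, config.n_validation_background,
        config.validation_min_len, config.validation_min_len + 800,
        forbidden=forbidden + enh_ivs, min_gap=500,
    )
    p0 = 1.0 / (1.0 + np.exp(-config.validation_a))
    for k, iv in enumerate(bg_elements):
        heart = bool(rng.random() < p0)
        anyp = heart or bool(rng.random() < config.any_positive_extra)
        val_rows.append({"element_id": f"bg{k + 1:04d}", "chrom": iv.chrom,
                         "start": iv.start, "end": iv.end,
                         "heart_positive": int(heart), "any_positive": int(anyp)})
    paths["validation"] = os.path.join(out_dir, "validation.tsv")
    pd.DataFrame(val_rows).to_csv(paths["validation"], sep="\t", index=False)

    # --- GWAS lead + proxy variants (positions written 1-based)
    snp_rows = []
    traits = ["atrial fibrillation", "heart rate", "coronary artery disease",
              "QT interval"]
    for i in range(config.n_lead_snps):
        trait = traits[int(rng.integers(len(traits)))]
        lead_id = f"rs{100000 + i}"
        inside = rng.random() < config.snp_in_enhancer_fraction and enhancers
        if inside:
            enh = enhancers[int(rng.integers(len(enhancers)))]
            chrom = enh.interval.chrom
            pos = int(rng.integers(enh.interval.start, enh.interval.end))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, chrom_lengths[chrom]))
        snp_rows.append({"rsid": lead_id, "chrom": chrom, "pos": pos + 1,
                         "trait": trait, "lead_rsid": lead_id, "r2": 1.0,
                         "distance_to_lead": 0})
        n_prox = int(rng.poisson(config.proxies_per_lead))
        for j in range(n_prox):
            dist = int(rng.integers(1, 600_000))
            ppos = min(max(0, pos + int(rng.choice([-1, 1])) * dist),
                       chrom_lengths[chrom] - 1)
            snp_rows.append({
                "rsid": f"rs{100000 + i}_{j + 1}", "chrom": chrom, "pos": ppos + 1,
                "trait": trait, "lead_rsid": lead_id,
                "r2": round(float(rng.uniform(0.6, 1.0)), 3),
                "distance_to_lead": abs(ppos - pos),
            })
    paths["snps"] = os.path.join(out_dir, "snps.tsv")
    pd.DataFrame(snp_rows).to_csv(paths["snps"], sep="\t", index=False)

    world = SyntheticWorld(config, seed, out_dir, chrom_lengths, enhancers, paths)
    paths["truth"] = os.path.join(out_dir, "truth.tsv")
    world.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["world"] = os.path.join(out_dir, "world.json")
    with open(paths["world"], "w") as fh:
        json.dump({"seed": seed, "chrom_lengths": chrom_lengths,
                   "assembly_reference": ASSEMBLY_A, "assembly_mapped": ASSEMBLY_B,
                   "config": asdict(config)}, fh, indent=2, sort_keys=True)
    return world


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(world: SyntheticWorld, catalogue) -> dict:
    """Precision/recall of a catalogue against the world's planted truth.

    A planted enhancer is recovered when some catalogue region covers at
    least half of its bases; precision is the fraction of catalogue regions
    touching any planted enhancer at all.
    """
    regions_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in catalogue.regions:
        regions_by_chrom.setdefault(r.interval.chrom, []).append(r.interval)

    def covered(enh: PlantedEnhancer) -> int:
        return max((overlap_bases(enh.interval, iv)
                    for iv in regions_by_chrom.get(enh.interval.chrom, ())), default=0)

    recovered = [covered(e) >= 0.5 * e.interval.length for e in world.enhancers]
    gated = [e.max_emitted >= world.gate for e in world.enhancers]
    n_gated = sum(gated)
    n_rec_gated = sum(r for r, g in zip(recovered, gated) if g)

    enh_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in world.enhancers:
        enh_by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
    n_true_regions = sum(
        any(overlap_bases(r.interval, iv) > 0
            for iv in enh_by_chrom.get(r.interval.chrom, ()))
        for r in catalogue.regions)

    n_regions = len(catalogue.regions)
    return {
        "n_planted": len(world.enhancers),
        "n_gate_exceeding": n_gated,
        "n_recovered": sum(recovered),
        "recall": sum(recovered) / len(world.enhancers),
        "recall_gated": n_rec_gated / n_gated if n_gated else float("nan"),
        "n_regions": n_regions,
        "n_regions_planted": n_true_regions,
        "precision": n_true_regions / n_regions if n_regions else float("nan"),
    }


def score_separation(world: SyntheticWorld, catalogue) -> dict:
    """Mean combined score of planted-overlapping vs background regions."""
    enh_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in world.enhancers:
        enh_by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
    planted, background = [], []
    for r in catalogue.regions:
        hit = any(overlap_bases(r.interval, iv) > 0
                  for iv in enh_by_chrom.get(r.interval.chrom, ()))
        (planted if hit else background).append(r.scores.all)
    return {
        "mean_score_planted": float(np.mean(planted)) if planted else float("nan"),
        "mean_score_background": float(np.mean(background)) if background else float("nan"),
        "n_planted_regions": len(planted),
        "n_background_regions": len(background),
    }
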