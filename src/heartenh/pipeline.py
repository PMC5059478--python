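"""End-to-end pipeline: peaks in, scored and annotated catalogue out.

Stage order: replicate consensus -> cross-assembly mapping of the mapped
species' conditions -> promoter partition and TSS-window subtraction ->
merged, gated, blacklist-filtered catalogue -> empirical scoring ->
validation-rate calibration (when a validation table is given) -> gene and
GWAS annotation. Every stage logs its input/output counts into a run report
so the bookkeeping can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import annotate as ann
from . import calibration as cal
from .chainmap import MappingStatus, map_reciprocal, read_chain
from .compendium import (CompendiumCatalogue, build_catalogue, size_summary,
                         write_catalogue)
from .intervals import IntervalSet, read_bed
from .peaks import (Peak, combine_replicates, conditions_from_manifest,
                    partition_promoters, read_manifest, read_peaks,
                    read_tss_table, subtract_tss_from_peaks, tss_windows,
                    write_peaks)
from .scoring import ConditionScoreTable, score_catalogue

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Defaults reproduce the published analysis parameters: significance gate
    -log10 p = 10 (p <= 1e-10), 1.5 kb promoter window, >= 50% liftover base
    mapping with reciprocal filtering, >= 500 bp validation overlap,
    r^2 >= 0.8 within 500 kb for LD proxies.
    """

    manifest: str = ""
    base_dir: str = ""  # peak_file paths in the manifest resolve against this
    reference_assembly: str = "asmA"
    mapped_assembly: str = "asmB"
    mapped_species: str = "mouse"
    forward_chain: str = ""  # mapped -> reference
    backward_chain: str = ""  # reference -> mapped
    tss_table: str = ""
    gene_table: str = ""
    blacklist: str = ""
    validation_table: str = ""
    snp_table: str = ""
    gate: float = 10.0
    promoter_window: int = 1500
    min_fraction: float = 0.5
    min_overlap: int = 500
    min_r2: float = 0.8
    max_lead_distance: int = 500_000
    blacklist_mode: str = "drop"
    score_variant: str = "rank"
    peak_p_col: int = 5
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_world(cls, world, out_dir: str, **overrides) -> "RunConfig":
        """Configuration pointing at a synthetic world's files."""
        p = world.paths
        kw = dict(
            manifest=p["manifest"], base_dir=world.out_dir,
            forward_chain=p["forward_chain"], backward_chain=p["backward_chain"],
            tss_table=p["tss"], gene_table=p["genes"], blacklist=p["blacklist"],
            validation_table=p["validation"], snp_table=p["snps"],
            gate=world.config.gate, out_dir=out_dir, seed=world.seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    catalogue: CompendiumCatalogue
    curves: dict = field(default_factory=dict)
    gwas: object = None
    report: dict = field(default_factory=dict)
    promoter_peaks: dict = field(default_factory=dict)


def _stage(report: dict, name: str, **counts) -> None:
    report.setdefault("stages", []).append({"stage": name, **counts})
    logger.info("stage %s: %s", name, counts)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline; any stage failure aborts with its name."""
    report: dict = {"config": dataclasses.asdict(config)}

    def resolve(path: str) -> str:
        return path if os.path.isabs(path) or not config.base_dir \
            else os.path.join(config.base_dir, path)

    # --- load inputs
    try:
        manifest = read_manifest(config.manifest)
        conditions = conditions_from_manifest(manifest)
        tss = read_tss_table(config.tss_table) if config.tss_table else []
        blacklist = (read_bed(config.blacklist, config.reference_assembly)
                     if config.blacklist else None)
    except Exception as exc:
        raise PipelineError(f"stage load-inputs failed: {exc}") from exc

    needs_chains = (manifest["species"] == config.mapped_species).any()
    forward = backward = []
    if needs_chains:
        if not config.forward_chain or not config.backward_chain:
            missing = manifest.loc[manifest["species"] == config.mapped_species, "id"].unique()
            raise PipelineError(
                f"stage liftover failed: conditions {list(missing)} are on the "
                f"mapped assembly but no chain files were provided")
        try:
            forward = read_chain(config.forward_chain)
            backward = read_chain(config.backward_chain)
        except Exception as exc:
            raise PipelineError(f"stage read-chains failed: {exc}") from exc

    # --- replicate consensus per condition
    per_condition: dict[str, list[Peak]] = {}
    for cid, grp in manifest.groupby("id", sort=True):
        species = grp["species"].iloc[0]
        assembly = (config.mapped_assembly if species == config.mapped_species
                    else config.reference_assembly)
        try:
            reps = [read_peaks(resolve(row["peak_file"]), assembly, cid,
                               config.peak_p_col)
                    for _, row in grp.iterrows()]
            per_condition[cid] = combine_replicates(reps)
        except Exception as exc:
            raise PipelineError(f"stage consensus failed for {cid!r}: {exc}") from exc
        _stage(report, f"consensus:{cid}",
               n_replicates=len(reps), peaks_in=sum(map(len, reps)),
               peaks_out=len(per_condition[cid]))

    # --- cross-assembly mapping of mapped-species conditions
    for cid, grp in manifest.groupby("id", sort=True):
        if grp["species"].iloc[0] != config.mapped_species:
            continue
        mapped: list[Peak] = []
        counts = {s.value: 0 for s in MappingStatus}
        for pk in per_condition[cid]:
            res = map_reciprocal(pk.interval, forward, backward,
                                 config.min_fraction, config.reference_assembly)
            counts[res.status.value] += 1
            if res.ok:
                mapped.append(Peak(res.target, cid, pk.neg_log10_p))
        per_condition[cid] = mapped
        _stage(report, f"liftover:{cid}", **counts)

    # --- promoter partition + TSS-window subtraction
    promoter_peaks: dict[str, list[Peak]] = {}
    for cid in sorted(per_condition):
        proms, enhs = partition_promoters(per_condition[cid], tss,
                                          config.promoter_window)
        enhs = subtract_tss_from_peaks(enhs, tss, config.promoter_window)
        promoter_peaks[cid] = proms
        n_in = len(per_condition[cid])
        per_condition[cid] = enhs
        _stage(report, f"promoters:{cid}", peaks_in=n_in,
               promoters=len(proms), enhancer_peaks=len(enhs))

    # --- merged gated catalogue
    try:
        catalogue = build_catalogue(per_condition, config.gate, blacklist,
                                    config.blacklist_mode,
                                    provenance={"seed": config.seed})
    except Exception as exc:
        raise PipelineError(f"stage build-catalogue failed: {exc}") from exc
    _stage(report, "catalogue", **{k: v for k, v in catalogue.provenance.items()
                                   if k.startswith("n_")})

    # --- scoring
    try:
        tables = ConditionScoreTable.from_peaks(
            {cid: pks for cid, pks in per_condition.items() if pks})
        score_catalogue(catalogue, conditions, tables, config.score_variant)
    except Exception as exc:
        raise PipelineError(f"stage scoring failed: {exc}") from exc
    _stage(report, "scoring", n_scored=len(catalogue))

    # --- calibration
    curves: dict[str, cal.CalibrationCurve] = {}
    rediscovery = None
    if config.validation_table:
        try:
            elements = cal.read_validation_table(config.validation_table,
                                                 config.reference_assembly)
            windows = tss_windows(tss, config.reference_assembly,
                                  config.promoter_window) if tss else None
            pairs = cal.match_validation(catalogue, elements, config.min_overlap,
                                         windows, blacklist)
            for score_class in ("all", "prenatal", "postnatal"):
                curves[score_class] = cal.fit_validation_curve(
                    pairs, "heart_positive", score_class)
            rediscovery = cal.rediscovery_rate(catalogue, elements,
                                               config.min_overlap, windows,
                                               blacklist)
        except Exception as exc:
            raise PipelineError(f"stage calibration failed: {exc}") from exc
        _stage(report, "calibration", n_elements=len(elements), n_pairs=len(pairs),
               rediscovered=rediscovery[0], positives=rediscovery[1])
        report["rediscovery"] = {
            "n_overlapping_positive": rediscovery[0],
            "n_positive": rediscovery[1],
            "fraction": rediscovery[2],
        }

    # --- annotation
    gwas_df = None
    try:
        if config.gene_table:
            genes = ann.read_gene_table(config.gene_table)
            ann.annotate_genes(catalogue, genes)
            _stage(report, "genes", n_genes=len(genes))
        if config.snp_table:
            snps = ann.read_snp_table(config.snp_table)
            gwas_df = ann.intersect_gwas(catalogue, snps, config.min_r2,
                                         config.max_lead_distance)
            hits = (gwas_df.set_index(["region_chrom", "region_start",
                                       "region_end"]).sort_index()
                    if len(gwas_df) else None)
            for r in catalogue.regions:
                key = (r.interval.chrom, r.interval.start, r.interval.end)
                if hits is not None and key in hits.index:
                    sub = hits.loc[[key]]
                    r.annotations["gwas_hits"] = ";".join(sub["rsid"])
            _stage(report, "gwas", n_snps=len(snps), n_hits=len(gwas_df))
    except Exception as exc:
        raise PipelineError(f"stage annotation failed: {exc}") from exc

    report["size_summary"] = size_summary(catalogue) if len(catalogue) else {}

    # --- outputs
    os.makedirs(config.out_dir, exist_ok=True)
    write_catalogue(catalogue, os.path.join(config.out_dir, "catalogue.tsv"),
                    os.path.join(config.out_dir, "provenance.json"))
    for cid, proms in promoter_peaks.items():
        if proms:
            write_peaks(proms, os.path.join(config.out_dir, f"promoters_{cid}.bed"))
    for score_class, curve in curves.items():
        curve.grid().to_csv(os.path.join(config.out_dir,
                                         f"validation_curve_{score_class}.tsv"),
                            sep="\t", index=False)
        curve.to_json(os.path.join(config.out_dir,
                                   f"validation_curve_{score_class}.json"))
    if gwas_df is not None:
        gwas_df.to_csv(os.path.join(config.out_dir, "gwas_hits.tsv"),
                       sep="\t", index=False)
    with open(os.path.join(config.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    return RunResult(catalogue, curves, gwas_df, report, promoter_peaks)
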