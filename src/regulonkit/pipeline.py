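"""End-to-end orchestration: reconcile -> merge -> assign -> motifs ->
signal -> DE -> classify -> (optional) cobind.

Each stage is also usable standalone through the library or the CLI; this
module wires them together from a single config, logs per-stage in/out
counts, writes every result as a headered TSV, and records a manifest with
parameters and input checksums.  Reruns on identical inputs reproduce
identical bytes (no timestamps in outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .genome import (
    GenomicInterval,
    LocationClassifier,
    promoter_window,
    read_annotation,
)
from . import cobinding as cob
from . import expression as expr
from . import integrate as integ
from . import motifs as mot
from . import occupancy as occ
from . import peaks as pk

log = logging.getLogger("regulonkit")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``summits`` maps an epitope/sample-set label to its per-replicate
    summit BED files; reconciliation runs within each label and the merge
    step unions across labels.
    """

    # inputs
    annotation: str
    chrom_sizes: str
    outdir: str
    summits: dict = field(default_factory=dict)  # label -> [bed, bed]
    genome_fasta: str | None = None
    reads: str | None = None
    expression: str | None = None
    samples: str | None = None
    de_table: str | None = None
    motifs: str | None = None
    categories: str | None = None
    tf_genes: str | None = None
    allowlist: str | None = None
    denylist: str | None = None
    factor_a: str | None = None
    factor_b: str | None = None
    heterodimer_ref: str | None = None
    # thresholds (defaults are the analysis' standard operating values)
    max_dist: int = 100
    merge_dist: int = 100
    upstream: int = 2000
    downstream: int = 200
    motif_window: int = 100
    extsize: int = 200
    bin_size: int = 10
    lfc_thresh: float = 1.0
    padj_thresh: float = 0.05
    fpkm_thresh: float = 1.0
    cobind_threshold: int = 50
    cobind_coverage_target: float = 0.8
    pseudocount: float = 1.0
    rescue: bool = True
    rescue_as_de: bool = True

    def validate(self) -> None:
        def check(name: str, path) -> None:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"config field {name!r}: file not found: {path}")

        for name in (
            "annotation",
            "chrom_sizes",
            "genome_fasta",
            "reads",
            "expression",
            "samples",
            "de_table",
            "motifs",
            "categories",
            "tf_genes",
            "allowlist",
            "denylist",
            "factor_a",
            "factor_b",
            "heterodimer_ref",
        ):
            check(name, getattr(self, name))
        if not self.summits:
            raise ConfigError("config field 'summits': at least one sample set required")
        for label, beds in self.summits.items():
            for b in beds:
                check(f"summits[{label}]", b)
        for name in ("max_dist", "merge_dist", "upstream", "downstream", "motif_window", "extsize"):
            if getattr(self, name) < 0:
                raise ConfigError(f"config field {name!r} must be >= 0")
        if self.expression is not None and self.samples is None:
            raise ConfigError("config field 'samples': required when 'expression' is set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown pipeline config field(s): {sorted(bad)}")
        return cls(**d)


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the in-memory result bundle."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "package": "regulonkit",
        "version": __version__,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (dict,)) and k != "outdir"
        },
        "inputs": {},
        "stages": {},
    }

    def record_input(name: str, path) -> None:
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "md5": _md5(path)}

    record_input("annotation", config.annotation)
    record_input("chrom_sizes", config.chrom_sizes)

    # ---- stage: annotation ----
    try:
        annotation = read_annotation(
            config.annotation,
            config.chrom_sizes,
            categories=config.categories,
            tf_genes=config.tf_genes,
        )
    except Exception as e:
        raise StageError(f"annotation: failed on {config.annotation}: {e}") from e
    log.info("annotation: %d genes on %d chromosomes", len(annotation), len(annotation.chrom_sizes))
    manifest["stages"]["annotation"] = {"genes": len(annotation)}
    results["annotation"] = annotation

    # ---- stage: reconcile ----
    reconciled: dict[str, list] = {}
    for label in sorted(config.summits):
        beds = config.summits[label]
        if len(beds) != 2:
            raise ConfigError(f"summits[{label}]: exactly two replicate BEDs expected")
        for b in beds:
            record_input(f"summits:{label}", b)
        rep_a = pk.read_summits_bed(beds[0])
        rep_b = pk.read_summits_bed(beds[1])
        rec = pk.reconcile_replicates(rep_a, rep_b, config.max_dist)
        reconciled[label] = rec.peaks
        log.info(
            "reconcile[%s]: %d + %d summits -> %d reproducible, %d + %d dropped",
            label, len(rep_a), len(rep_b), len(rec.peaks), len(rec.unmatched_a), len(rec.unmatched_b),
        )
        manifest["stages"][f"reconcile:{label}"] = {
            "in_a": len(rep_a),
            "in_b": len(rep_b),
            "reconciled": len(rec.peaks),
        }
        _write_tsv(pk.peaks_to_frame(rec.peaks), out / f"reconciled_{label}.tsv", index=False)
        dropped = pd.DataFrame(
            [
                {"chrom": s.chrom, "pos": s.pos, "sample_id": s.sample_id, "reason": "unreplicated"}
                for s in sorted(rec.unmatched_a + rec.unmatched_b, key=lambda s: (s.chrom, s.pos))
            ],
            columns=["chrom", "pos", "sample_id", "reason"],
        )
        _write_tsv(dropped, out / f"rejected_summits_{label}.tsv", index=False)

    # ---- stage: merge ----
    labels = sorted(reconciled)
    if len(labels) == 1:
        merged_peaks = reconciled[labels[0]]
        shared_fraction = 1.0
    else:
        merged_peaks = reconciled[labels[0]]
        shared_fraction = 1.0
        for other in labels[1:]:
            merge = pk.merge_peak_sets(
                merged_peaks, reconciled[other], config.merge_dist, "union", other
            )
            merged_peaks = merge.peaks
            shared_fraction = merge.shared_fraction
    if config.allowlist or config.denylist:
        allow = pk.read_summits_bed(config.allowlist) if config.allowlist else ()
        deny = pk.read_summits_bed(config.denylist) if config.denylist else ()
        merged_peaks = pk.apply_site_edits(merged_peaks, allow, deny, tol=config.merge_dist)
    log.info("merge: %d combined target sites (shared fraction %.3f)", len(merged_peaks), shared_fraction)
    manifest["stages"]["merge"] = {
        "peaks": len(merged_peaks),
        "shared_fraction": round(shared_fraction, 6),
    }
    results["merged_peaks"] = merged_peaks
    results["shared_fraction"] = shared_fraction
    pk.write_peaks_bed(merged_peaks, out / "merged_summits.bed")
    _write_tsv(pk.peaks_to_frame(merged_peaks), out / "merged_summits.tsv", index=False)

    # ---- stage: assign ----
    assignment = pk.assign_summits_to_genes(
        merged_peaks, annotation, config.upstream, config.downstream
    )
    site_counts = pk.count_sites_per_promoter(assignment.assignments)
    log.info(
        "assign: %d promoter assignments over %d genes; %d summits outside promoters",
        len(assignment.assignments), len(site_counts), len(assignment.unassigned),
    )
    manifest["stages"]["assign"] = {
        "assignments": len(assignment.assignments),
        "bound_genes": len(site_counts),
        "unassigned": len(assignment.unassigned),
    }
    results["assignment"] = assignment
    results["site_counts"] = site_counts
    _write_tsv(pk.assignments_to_frame(assignment.assignments), out / "promoter_assignments.tsv", index=False)
    _write_tsv(site_counts, out / "sites_per_promoter.tsv", index=True)
    rejects = pd.DataFrame(
        [
            {"chrom": p.chrom, "pos": p.pos, "location": loc, "reason": "outside_promoter_windows"}
            for p, loc in sorted(assignment.unassigned, key=lambda t: (t[0].chrom, t[0].pos))
        ],
        columns=["chrom", "pos", "location", "reason"],
    )
    _write_tsv(rejects, out / "rejected_peaks.tsv", index=False)

    # location breakdown over all merged summits
    classifier = LocationClassifier(annotation, config.upstream, config.downstream)
    from .genome import LOCATION_CATEGORIES

    locs = [classifier.classify(p.chrom, p.pos) for p in merged_peaks]
    loc_counts = (
        pd.Series(locs, dtype=str).value_counts().reindex(list(LOCATION_CATEGORIES), fill_value=0)
    )
    loc_df = loc_counts.rename_axis("location").reset_index(name="n_summits")
    loc_df["pct"] = 100.0 * loc_df["n_summits"] / max(1, len(merged_peaks))
    _write_tsv(loc_df, out / "summit_locations.tsv", index=False)
    results["summit_locations"] = loc_df

    # summit-to-ATG distance table (promoter assignments only)
    dist_df = pd.DataFrame(
        {"distance_to_atg": sorted(a.distance for a in assignment.assignments)}
    )
    _write_tsv(dist_df, out / "summit_atg_distances.tsv", index=False)

    # ---- stage: motifs ----
    if config.genome_fasta and config.motifs:
        record_input("genome_fasta", config.genome_fasta)
        record_input("motifs", config.motifs)
        genome = mot.load_genome_fasta(config.genome_fasta)
        motif_list = mot.read_motif_table(config.motifs)
        presence = mot.motif_presence_matrix(
            merged_peaks, genome, motif_list, config.motif_window
        )
        profile = mot.motif_frequency_profile(merged_peaks, genome, motif_list[0])
        log.info(
            "motifs: %d/%d peaks carry any motif",
            int(presence["any_motif"].sum()), len(presence),
        )
        manifest["stages"]["motifs"] = {
            "peaks_with_any_motif": int(presence["any_motif"].sum())
        }
        results["motif_presence"] = presence
        results["motif_profile"] = profile
        _write_tsv(presence, out / "motif_presence.tsv", index=False)
        _write_tsv(profile, out / "motif_frequency_profile.tsv", index=False)

    # ---- stage: signal ----
    if config.reads:
        record_input("reads", config.reads)
        reads = occ.read_read_starts(config.reads)
        frags = occ.extend_reads(reads, config.extsize, annotation.chrom_sizes)
        track = occ.pileup_fpkm(frags, len(reads), annotation.chrom_sizes, config.bin_size)
        promoter_signal = {}
        for gene_id in site_counts.index:
            g = annotation.genes_by_id[gene_id]
            w = promoter_window(
                g, config.upstream, config.downstream, chrom_len=annotation.chrom_sizes[g.chrom]
            )
            if len(w):
                promoter_signal[gene_id] = occ.window_signal(track, w)
        sig_df = pd.Series(promoter_signal, name="promoter_fpkm").rename_axis("gene_id").reset_index()
        _write_tsv(sig_df.sort_values("gene_id"), out / "promoter_signal.tsv", index=False)
        log.info("signal: %d reads -> FPKM at %d bound promoters", len(reads), len(sig_df))
        manifest["stages"]["signal"] = {"reads": len(reads), "promoters": len(sig_df)}
        results["promoter_signal"] = promoter_signal
        results["track"] = track

    # ---- stage: DE ----
    de_records = None
    if config.expression:
        record_input("expression", config.expression)
        record_input("samples", config.samples)
        matrix = expr.read_expression_tsv(config.expression, config.samples)
        external = expr.read_de_table(config.de_table) if config.de_table else None
        de_records = expr.de_table(
            matrix,
            external=external,
            lfc_thresh=config.lfc_thresh,
            padj_thresh=config.padj_thresh,
            fpkm_thresh=config.fpkm_thresh,
            pseudocount=config.pseudocount,
            rescue=config.rescue,
        )
        counts = de_records["status"].value_counts().to_dict()
        log.info("de: %s", counts)
        manifest["stages"]["de"] = {k: int(v) for k, v in sorted(counts.items())}
        results["de_records"] = de_records
        _write_tsv(de_records, out / "de_records.tsv", index=True)
    elif config.de_table:
        record_input("de_table", config.de_table)
        de_records = expr.read_de_table(config.de_table)
        if "status" not in de_records.columns:
            de_records["status"] = expr.classify_de(
                de_records, config.lfc_thresh, config.padj_thresh
            )
        results["de_records"] = de_records
        _write_tsv(de_records, out / "de_records.tsv", index=True)

    # ---- stage: classify/integrate ----
    if de_records is not None:
        universe = sorted(set(annotation.genes_by_id) | set(de_records.index))
        master = integ.build_regulation_table(
            universe, site_counts, de_records, rescue_as_de=config.rescue_as_de
        )
        class_counts = master["reg_class"].value_counts().to_dict()
        log.info("classify: %s", class_counts)
        manifest["stages"]["classify"] = {k: int(v) for k, v in sorted(class_counts.items())}
        results["master"] = master
        _write_tsv(master, out / "gene_regulation.tsv", index=True)

        categories = {
            g.gene_id: set(g.categories) for g in annotation.genes if g.categories
        }
        if categories:
            summary = integ.summarize_regulon(master, categories)
            _write_tsv(summary, out / "regulon_summary.tsv", index=False)
            enrich = pd.concat(
                [
                    integ.enrichment_table(master, categories, cls)
                    for cls in integ.REG_CLASSES
                    if cls != "none"
                ],
                ignore_index=True,
            )
            _write_tsv(enrich, out / "enrichment.tsv", index=False)
            results["regulon_summary"] = summary
            results["enrichment"] = enrich
        tf_flags = {g.gene_id: g.is_tf for g in annotation.genes}
        if any(tf_flags.values()):
            report = integ.tf_regulon_report(master, tf_flags)
            _write_tsv(report, out / "tf_regulon_report.tsv", index=True)
            results["tf_report"] = report

    # ---- stage: cobind ----
    if config.factor_a and config.factor_b:
        record_input("factor_a", config.factor_a)
        record_input("factor_b", config.factor_b)
        peaks_a = [
            pk.ReconciledPeak(s.chrom, s.pos, (s,), frozenset({s.sample_id}))
            for s in pk.read_summits_bed(config.factor_a, "factorA")
        ]
        peaks_b = [
            pk.ReconciledPeak(s.chrom, s.pos, (s,), frozenset({s.sample_id}))
            for s in pk.read_summits_bed(config.factor_b, "factorB")
        ]
        assign_a = pk.assign_summits_to_genes(peaks_a, annotation, config.upstream, config.downstream)
        assign_b = pk.assign_summits_to_genes(peaks_b, annotation, config.upstream, config.downstream)
        dist = cob.summit_distance_distribution(assign_a.assignments, assign_b.assignments)
        threshold = config.cobind_threshold
        if config.heterodimer_ref:
            record_input("heterodimer_ref", config.heterodimer_ref)
            ref = pd.read_csv(config.heterodimer_ref, sep="\t")["distance"].values
            cal = cob.calibrate_threshold(ref, config.cobind_coverage_target)
            threshold = cal.threshold
            manifest["stages"]["cobind_calibration"] = {
                "threshold": cal.threshold,
                "coverage": round(cal.coverage, 6),
            }
            results["calibration"] = cal
        labeled = cob.classify_cobound(dist, threshold)
        counts = cob.cobound_counts(labeled)
        log.info("cobind: %s at threshold %d bp", counts, threshold)
        manifest["stages"]["cobind"] = {**counts, "threshold": threshold}
        results["cobind"] = labeled
        _write_tsv(labeled, out / "cobind_records.tsv", index=False)
        if len(dist):
            _write_tsv(
                cob.cumulative_distance_curve(dist["distance"].values),
                out / "cobind_ecdf.tsv",
                index=False,
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
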