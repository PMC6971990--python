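"""End-to-end orchestration: annotation -> events -> junction features ->
ORF/PTC -> differential expression/DAGs -> metabolite association.

``run_profile`` executes every stage on a :class:`RunConfig`, writes all
module outputs under one directory and emits a machine-readable JSON run
report (input hashes, parameters, per-stage record counts).  Reruns on the
same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation_io, differential, events, features, metabolites, orf

log = logging.getLogger("splicescape")

_FLOAT_FMT = "%.6g"


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    genome: Path
    reference_gtf: Path
    assembled_gtfs: dict[str, Path]          # condition label -> path
    expression_tsv: Optional[Path] = None
    metabolite_tsv: Optional[Path] = None
    term_map_tsv: Optional[Path] = None
    out_dir: Path = Path("splicescape_out")
    baseline: Optional[str] = None           # default: first assembled label
    alpha_de: float = 0.01
    min_fc: float = 2.0
    alpha_metab: float = 0.05
    corr_threshold: float = 0.7
    branch_params: features.BranchParams = field(
        default_factory=features.BranchParams)
    allowed_codes: frozenset = annotation_io.DEFAULT_ALLOWED_CODES
    seed: int = 0

    def validate(self) -> None:
        paths = [self.genome, self.reference_gtf, *self.assembled_gtfs.values()]
        for p in (self.expression_tsv, self.metabolite_tsv, self.term_map_tsv):
            if p is not None:
                paths.append(p)
        for p in paths:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        for name, value in (("alpha_de", self.alpha_de),
                            ("min_fc", self.min_fc),
                            ("alpha_metab", self.alpha_metab),
                            ("corr_threshold", self.corr_threshold)):
            if value <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if not self.assembled_gtfs:
            raise ConfigurationError("at least one assembled GTF is required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_profile(config: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "alpha_de": config.alpha_de, "min_fc": config.min_fc,
            "alpha_metab": config.alpha_metab,
            "corr_threshold": config.corr_threshold,
            "bp_window_max": config.branch_params.window_max,
            "bp_window_min": config.branch_params.window_min,
            "ppt_min_len": config.branch_params.ppt_min_len,
            "allowed_codes": sorted(config.allowed_codes),
            "seed": config.seed,
        },
        "inputs": {},
        "stages": {},
    }
    report["inputs"]["genome"] = _sha256(config.genome)
    report["inputs"]["reference_gtf"] = _sha256(config.reference_gtf)
    for label, p in config.assembled_gtfs.items():
        report["inputs"][f"assembled_{label}"] = _sha256(p)

    t0 = time.time()
    genome = annotation_io.read_genome(config.genome)
    reference = annotation_io.read_gtf(config.reference_gtf, genome)
    samples: dict[str, list] = {}
    for label, path in config.assembled_gtfs.items():
        genes = annotation_io.read_gtf(path, genome)
        samples[label] = annotation_io.filter_isoforms(
            genes, config.allowed_codes, reference=reference)
    report["stages"]["annotation"] = {
        "contigs": len(genome.contigs),
        "reference_genes": len(reference),
        "samples": {s: sum(len(g.transcripts) for g in genes)
                    for s, genes in samples.items()},
    }
    log.info("annotation: %d reference genes, %d samples",
             len(reference), len(samples))

    # ---------------------------------------------------------------- events
    t0 = time.time()
    table, as_sets, venn = events.per_sample_summary(samples)
    all_events = {}
    for label, genes in sorted(samples.items()):
        for gene in genes:
            for ev in events.detect_gene_events(gene):
                all_events.setdefault(ev.identity(), (label, ev))
    ev_frame = events.events_to_frame([e for _, e in all_events.values()])
    _write(ev_frame.sort_values(list(ev_frame.columns)).reset_index(drop=True),
           out / "events.tsv")
    _write(table.rename_axis("sample"), out / "event_counts.tsv", index=True)
    (out / "as_summary.json").write_text(json.dumps({
        "venn": venn,
        "as_genes": {s: sorted(g) for s, g in as_sets.items()},
    }, indent=1, sort_keys=True))
    report["stages"]["events"] = {
        "distinct_events": len(all_events),
        "as_genes_union": venn["union"],
        "as_genes_conserved": venn["conserved"],
        "per_sample_events": {s: int(table.loc[s, "total"]) for s in table.index},
    }

    # ------------------------------------------------------------- junctions
    t0 = time.time()
    union_genes: dict[str, object] = {}
    for label in sorted(samples):
        for gene in samples[label]:
            if gene.gene_id not in union_genes:
                union_genes[gene.gene_id] = gene
            else:
                merged = union_genes[gene.gene_id]
                known = {t.transcript_id for t in merged.transcripts}
                for t in gene.transcripts:
                    if t.transcript_id not in known:
                        merged.transcripts.append(t)
                        known.add(t.transcript_id)
    junctions, incidences = features.collect_junctions(
        reference, list(union_genes.values()), genome)
    feats = features.find_branch_points(junctions, genome,
                                        config.branch_params)
    usage = features.dinucleotide_usage(junctions, genome)
    stats = features.intron_statistics(feats) if feats else {}
    logos = features.build_logos(feats, genome)
    _write(features.junctions_to_bed(junctions), out / "junctions.bed")
    _write(usage, out / "dinucleotide_usage.tsv")
    feat_rows = pd.DataFrame([{
        "contig": f.junction.contig, "strand": f.junction.strand,
        "start": f.junction.start, "end": f.junction.end,
        "intron_length": f.intron_length,
        "branch_a_position": f.branch_a_position,
        "bp_offset_3ss": f.bp_offset_3ss, "bp_offset_5ss": f.bp_offset_5ss,
        "bp_score": f.bp_score, "ppt_length": f.ppt_length,
        "reason_absent": f.reason_absent,
    } for f in feats])
    _write(feat_rows, out / "intron_features.tsv")
    for logo in logos:
        _write(logo.counts.rename_axis("offset"),
               out / f"logo_{logo.region}.tsv", index=True)
    hist = stats.pop("histogram", None)
    if hist is not None:
        _write(hist, out / "intron_length_histogram.tsv")
    (out / "junction_summary.json").write_text(
        json.dumps(stats, indent=1, sort_keys=True))
    novelty_counts = {c: sum(1 for j in junctions if j.novelty == c)
                      for c in features.NOVELTY_CLASSES}
    location_counts = {c: sum(1 for j in junctions if j.location == c)
                       for c in features.LOCATION_CLASSES}
    report["stages"]["junctions"] = {
        "distinct_junctions": len(junctions),
        "incidences": incidences,
        "novelty": novelty_counts,
        "location": location_counts,
        "with_branch_point": stats.get("n_with_branch"),
    }

    # ------------------------------------------------------------------ ORF
    t0 = time.time()
    frames = features.reference_cds_frames(reference)
    orf_rows = []
    for gid, gene in sorted(union_genes.items()):
        ref_t = frames.get(gid)
        if ref_t is None:
            continue
        for t in gene.transcripts:
            if t.junction_set() == ref_t.junction_set():
                continue
            r = orf.scan_orf(t, ref_t, genome)
            orf_rows.append({
                "transcript_id": r.transcript_id, "gene_id": gid,
                "cdna_length": r.cdna_length,
                "start_projected": r.start_projected,
                "protein_length": r.protein_length,
                "reference_protein_length": r.reference_protein_length,
                "is_ptc": r.is_ptc, "run_through": r.run_through,
                "nmd_candidate": r.nmd_candidate,
            })
    orf_frame = pd.DataFrame(orf_rows)
    _write(orf_frame, out / "orf_ptc.tsv")
    report["stages"]["orf"] = {
        "isoforms_scanned": len(orf_rows),
        "ptc_isoforms": int(orf_frame["is_ptc"].sum()) if len(orf_rows) else 0,
    }

    # ----------------------------------------------------------- differential
    if config.expression_tsv is not None:
        t0 = time.time()
        report["inputs"]["expression"] = _sha256(config.expression_tsv)
        expr = differential.read_expression(config.expression_tsv)
        baseline = config.baseline or next(iter(config.assembled_gtfs))
        contrasts = [(baseline, c) for c in expr.conditions() if c != baseline]
        de_frames = []
        dag_summary = {}
        dags_by_contrast = {}
        for contrast in contrasts:
            res = differential.call_de(expr, contrast,
                                       alpha=config.alpha_de,
                                       min_fc=config.min_fc)
            res = differential.call_dags(res, as_sets)
            dags_by_contrast[f"{contrast[0]}:{contrast[1]}"] = res
            de_frames.append(differential.de_results_to_frame(res))
            dag_summary[f"{contrast[0]}:{contrast[1]}"] = {
                "de": sum(r.is_de for r in res),
                "dag": sum(r.is_dag for r in res),
            }
        de_all = pd.concat(de_frames, ignore_index=True)
        _write(de_all, out / "differential_expression.tsv")
        overlap = differential.dag_overlap(dags_by_contrast)
        (out / "dag_overlap.json").write_text(
            json.dumps(overlap, indent=1, sort_keys=True))
        report["stages"]["differential"] = {
            "contrasts": dag_summary,
            "dag_common": overlap["common"],
            }
        if config.term_map_tsv is not None:
            term_map = differential.read_term_map(config.term_map_tsv)
            universe = {r.gene_id for r in next(iter(dags_by_contrast.values()))}
            dag_union = {r.gene_id
                         for res in dags_by_contrast.values()
                         for r in res if r.is_dag}
            if dag_union and universe:
                enr = differential.enrich(dag_union & universe, universe,
                                          term_map)
                _write(enr, out / "dag_enrichment.tsv")
                report["stages"]["differential"]["enriched_terms_fdr05"] = int(
                    (enr["fdr"] < 0.05).sum())

    # ------------------------------------------------------------ metabolites
    if config.metabolite_tsv is not None and config.expression_tsv is not None:
        t0 = time.time()
        report["inputs"]["metabolites"] = _sha256(config.metabolite_tsv)
        metab = metabolites.read_metabolites(config.metabolite_tsv)
        m_conds = metab.conditions()
        m_baseline = m_conds[0]
        diff_frames = []
        for cond in m_conds[1:]:
            diff_frames.append(metabolites.call_diff_metabolites(
                metab, (m_baseline, cond),
                min_fc=config.min_fc, alpha=config.alpha_metab))
        diff_all = pd.concat(diff_frames, ignore_index=True)
        _write(diff_all, out / "differential_metabolites.tsv")

        as_transcripts = sorted({
            t.transcript_id for gene in union_genes.values()
            for t in gene.transcripts
            if (t.class_code or "=") == "j" and t.transcript_id in expr.values.index
        })
        pairs = [(t, m) for t in as_transcripts for m in metab.values.index]
        assoc = metabolites.correlate(expr, metab, pairs=pairs,
                                      threshold=config.corr_threshold)
        assoc_frame = metabolites.associations_to_frame(assoc)
        _write(assoc_frame, out / "associations.tsv")
        if as_transcripts:
            cm = metabolites.correlation_matrix(
                expr, metab, transcripts=as_transcripts)
            _write(cm.rename_axis("transcript_id"),
                   out / "correlation_matrix.tsv", index=True)
        report["stages"]["metabolites"] = {
            "differential": {
                f"{m_baseline}:{c}": int(df["is_differential"].sum())
                for c, df in zip(m_conds[1:], diff_frames)
            },
            "associations_tested": len(assoc),
            "strong_associations": int(assoc_frame["is_strong"].sum()),
            }

    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return report
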