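"""End-to-end pipeline: sequence preprocessing -> QC -> integration -> reports.

``run_pipeline`` wires the module operations into the documented default
order and writes a report bundle: coverage TSV, gap report JSON, MapMan
mapping file, Venn partition JSON, and a JSON run summary carrying the
package version, seed, parameters, and per-stage in/out record counts.
Stages whose inputs are absent from the configuration are skipped; any stage
failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotation import enzyme_subset, read_annotations
from .fixtures import (
    demo_detected_ecs,
    demo_species_sets,
    fixture_path,
    table1_compound_map,
    table1_metabolites,
    table2_pathways,
)
from .interspecies import ec_venn, ingest_blast_tab, read_species_ec_sets, similarity_percent
from .metabolites import CompoundMap, assign_compound, family_counts, read_metabolite_table
from .pathways import (
    completeness_report,
    export_mapman_mapping,
    load_pathway_definitions,
    pathway_coverage,
    write_coverage_tsv,
)
from .quant import (
    consistency_filter,
    impute_missing,
    normalize_areas,
    read_quant_table,
    replicate_stats,
    unique_peptide_filter,
)
from .transcriptome import (
    build_search_db,
    cluster_redundancy,
    read_fasta_transcripts,
    read_fastq_reads,
    trim_reads,
    write_fastq_reads,
)

logger = logging.getLogger("orphanomics")

__all__ = ["run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        cfg = yaml.safe_load(handle) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _resolve(value: str | None, base: Path) -> Path | None:
    """Resolve a config path; the ``fixture:`` scheme names a packaged file."""
    if value is None:
        return None
    if str(value).startswith("fixture:"):
        return fixture_path(str(value).split(":", 1)[1])
    p = Path(value)
    return p if p.is_absolute() else base / p


def run_pipeline(config: Mapping[str, Any], outdir: str | Path,
                 config_dir: str | Path = ".") -> dict:
    """Execute the configured stages and write the report bundle to ``outdir``.

    Returns the run summary (also written as ``run_summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config_dir)
    inputs = dict(config.get("inputs", {}))
    params = dict(config.get("params", {}))
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "params": params,
        "stages": {},
    }

    def stage(name: str):
        def record(n_in: int, n_out: int, **extra: Any) -> None:
            summary["stages"][name] = {"in": n_in, "out": n_out, **extra}
            logger.info("stage %s: %d in, %d out", name, n_in, n_out)
        return record

    try:
        # --- sequence preprocessing (optional) -----------------------------
        reads_path = _resolve(inputs.get("reads"), base)
        if reads_path is not None:
            reads = read_fastq_reads(reads_path)
            trimmed, tstats = trim_reads(
                reads,
                min_quality=int(params.get("min_quality", 20)),
                max_n=int(params.get("max_n", 2)),
                trim5=int(params.get("trim5", 0)),
                trim3=int(params.get("trim3", 0)),
                min_len=int(params.get("min_read_len", 50)),
            )
            write_fastq_reads(trimmed, outdir / "trimmed_reads.fastq")
            (outdir / "trim_stats.json").write_text(
                json.dumps(tstats.to_dict(), indent=2) + "\n"
            )
            stage("trim")(tstats.reads_in, tstats.reads_out, **tstats.to_dict())

        transcript_ecs: frozenset[str] = frozenset()
        protein_ecs: frozenset[str] = frozenset()

        transcripts_path = _resolve(inputs.get("transcripts"), base)
        if transcripts_path is not None:
            transcripts = read_fasta_transcripts(transcripts_path)
            clusters = cluster_redundancy(
                transcripts, float(params.get("identity_threshold", 0.95))
            )
            reps = {c.representative_id for c in clusters}
            nonredundant = [t for t in transcripts if t.id in reps]
            stage("cluster")(len(transcripts), len(nonredundant),
                             n_clusters=len(clusters))
            n_peptides = build_search_db(
                nonredundant,
                outdir / "search_db.fasta",
                outdir / "search_db_provenance.tsv",
                min_len=int(params.get("min_orf_len", 51)),
            )
            stage("builddb")(len(nonredundant), n_peptides)

        # --- quantification QC (optional, per layer) -----------------------
        for layer in ("protein_quant", "metabolite_quant"):
            qpath = _resolve(inputs.get(layer), base)
            if qpath is None:
                continue
            table = read_quant_table(qpath)
            n_in = table.n_features
            table = consistency_filter(
                table, params.get("required_present")
            )
            if layer == "protein_quant" and "unique_peptides" in table.meta.columns:
                table = unique_peptide_filter(
                    table, int(params.get("min_unique", 1))
                )
            table = normalize_areas(table, params.get("normalize", "total"))
            table = impute_missing(table, params.get("impute", "half_row_min"))
            stats, stats_summary = replicate_stats(table)
            stats.to_csv(outdir / f"{layer}_stats.tsv", sep="\t")
            stage(layer)(n_in, table.n_features, **stats_summary)

        # --- annotation / EC layers ---------------------------------------
        annotations = None
        ann_path = _resolve(inputs.get("annotations"), base)
        if ann_path is not None:
            annotations = read_annotations(ann_path)
            enzymes = enzyme_subset(annotations)
            transcript_ecs = frozenset(
                ec for rec in enzymes for ec in rec.ec_numbers
            )
            stage("annotate")(len(annotations), len(enzymes))

        detected_path = inputs.get("detected_ecs")
        if detected_path == "fixture:demo_detected_ecs.tsv" or detected_path == "fixture:demo":
            protein_ecs, fixture_transcript_ecs = demo_detected_ecs()
            transcript_ecs = transcript_ecs or fixture_transcript_ecs
        elif detected_path is not None:
            import pandas as pd

            df = pd.read_csv(_resolve(detected_path, base), sep="\t",
                             dtype=str, comment="#")
            protein_ecs = frozenset(df.loc[df["layer"] == "protein", "ec"])
            transcript_ecs = transcript_ecs or frozenset(
                df.loc[df["layer"] == "transcript", "ec"]
            )

        # --- metabolite annotation ----------------------------------------
        metabolite_ids: frozenset[str] = frozenset()
        met_path = inputs.get("metabolites")
        if met_path is not None:
            if str(met_path).startswith("fixture:"):
                records = read_metabolite_table(_resolve(met_path, base))
                cmap = CompoundMap.load(_resolve(met_path, base))
            else:
                records = read_metabolite_table(_resolve(met_path, base))
                cmap_path = _resolve(inputs.get("compound_map",
                                                "fixture:table1_metabolites.tsv"), base)
                cmap = CompoundMap.load(cmap_path)
            assigned = [assign_compound(r, cmap) for r in records]
            metabolite_ids = frozenset(
                r.kegg_id for r in assigned if r.kegg_id is not None
            )
            families = family_counts(records, cmap)
            (outdir / "metabolite_families.json").write_text(
                json.dumps(families, indent=2) + "\n"
            )
            stage("metabolites")(len(records), len(metabolite_ids),
                                 families=families)

        # --- integration ---------------------------------------------------
        pw_path = _resolve(inputs.get("pathways"), base)
        if pw_path is not None:
            definitions = load_pathway_definitions(pw_path)
            rows = pathway_coverage(
                metabolite_ids, protein_ecs, transcript_ecs, definitions
            )
            write_coverage_tsv(rows, outdir / "coverage.tsv")
            gaps = {
                "all_zero_pathways": [
                    r.pathway_id for r in rows
                    if r.n_metabolites == 0 and r.n_protein_enzymes == 0
                    and r.n_transcript_enzymes == 0
                ],
                "missing_protein_enzymes": completeness_report(
                    definitions, protein_ecs
                ),
            }
            (outdir / "gap_report.json").write_text(
                json.dumps(gaps, indent=2) + "\n"
            )
            stage("integrate")(len(definitions), len(rows))

        if annotations is not None:
            n_rows = export_mapman_mapping(
                annotations, outdir / "mapman_mapping.tsv"
            )
            stage("mapman")(len(annotations), n_rows)

        # --- interspecies comparison (optional) ----------------------------
        species_path = inputs.get("species_ecs")
        if species_path is not None:
            sets = (
                demo_species_sets()
                if str(species_path).startswith("fixture:")
                and "species" in str(species_path)
                else read_species_ec_sets(_resolve(species_path, base))
            )
            partition = ec_venn(sets)
            (outdir / "venn_partition.json").write_text(
                json.dumps(partition.to_jsonable(), indent=2) + "\n"
            )
            stage("compare")(len(sets), partition.union_size)

        blast_path = _resolve(inputs.get("blast_tab"), base)
        if blast_path is not None:
            best = ingest_blast_tab(
                blast_path, float(params.get("evalue_max", 1e-10))
            )
            n_total = int(inputs.get("n_queries_total", 0)) or max(
                len(best), 1
            )
            pct = similarity_percent(best, n_total)
            (outdir / "blast_best_hits.tsv").write_text(
                best.to_csv(sep="\t", index=False)
            )
            stage("blast")(n_total, len(best), similarity_percent=pct)

    except PipelineError:
        raise
    except Exception as exc:  # attach the stage context
        done = ", ".join(summary["stages"]) or "none"
        raise PipelineError(
            f"pipeline failed after stage(s) [{done}]: {exc}"
        ) from exc

    (outdir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
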