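"""End-to-end orchestration: manifest in, catalog + integrated analyses out.

`run_all` consumes a manifest (YAML) naming the annotation, probe BEDs per
platform, TSS-seq reads, chromatin coverage/peak tracks, expression datasets
and TF peak files — the layout written by `simulate.simulate_universe` —
and executes every stage in dependency order:

probes -> lncRNA candidates -> TSS regions -> chromatin/ambiguity filters ->
positional classes -> expression integration (RRA) -> elncRNA/plncRNA ->
neighbor and TF association.

The run is deterministic given identical inputs; a funnel report records the
record counts after each filtering stage, and every tabular output carries a
header block with the package version, the manifest hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._bedio import BedGraphTrack, read_bed6, read_peaks
from .annotations import AnnotationSet, coding_gene_models, load_annotations, lncrna_candidates
from .catalog import LncRnaRecord, build_catalog, catalog_to_frame
from .chromatin import (
    chi_square_regulation, classify_catalog, mark_change_vs_expression,
    quantify_catalog, regulation_class_table,
)
from .expression import (
    ExpressionMatrix, FoldChangeTable, call_regulated, collapse_to_transcripts,
    fold_change_correlation, knn_impute, log2_fold_change, mean_fold_change,
    results_to_frame, rra_aggregate,
)
from .neighbors import (
    associate_tf_peaks, build_neighbor_pairs, distance_by_chromatin_class,
    gene_level_fold_change, neighbor_coexpression, tf_target_expression_shift,
)
from .probes import assign_probes, assignments_to_frame, read_probe_bed6, summarize_reannotation
from .tss import build_tss_regions

logger = logging.getLogger(__name__)


@dataclass
class FunnelReport:
    """Stage-by-stage record counts through the filtering pipeline."""

    counts: dict = field(default_factory=dict)

    def check_monotonic(self) -> bool:
        chain = [
            "lncrna_candidates", "probe_supported", "with_tss",
            "after_chromatin", "after_ambiguity",
        ]
        values = [self.counts[k] for k in chain if k in self.counts]
        return all(a >= b for a, b in zip(values, values[1:]))


@dataclass
class PipelineResult:
    funnel: FunnelReport
    catalog: list[LncRnaRecord]
    assignments: pd.DataFrame
    lnc_tables: list[FoldChangeTable]
    coding_tables: list[FoldChangeTable]
    up: list
    down: list
    up_results: list
    down_results: list
    densities: pd.DataFrame
    chromatin_calls: list
    ks_table: pd.DataFrame
    regulation_table: pd.DataFrame
    chi_square: tuple[float, float]
    neighbor_pairs: pd.DataFrame
    coexpression: pd.DataFrame
    distance_ttest: tuple[float, float]
    tf_binding: pd.DataFrame
    tf_summary: dict
    tf_expression_shift: pd.DataFrame
    dataset_correlation: pd.DataFrame
    lnc_mean_fc: pd.Series
    gene_fc: pd.Series


def _resolve(base: Path, name: str) -> Path:
    p = Path(name)
    return p if p.is_absolute() else base / p


def run_all(manifest_path, out_dir=None, alpha: float = 0.05,
            knn_k: int = 10, tf_window: int = 10_000,
            exclude_exonic_sense: bool = True) -> PipelineResult:
    """Execute the full pipeline from a manifest; optionally write TSV outputs."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    raw = manifest_path.read_bytes()
    config_hash = hashlib.sha256(raw).hexdigest()[:12]
    manifest = yaml.safe_load(raw)
    seed = manifest.get("seed", "NA")
    meta = {"tool": f"lncprobe {__version__}", "config_hash": config_hash, "seed": seed}

    # --- annotations & probes -------------------------------------------------
    annots = load_annotations(
        [_resolve(base, manifest["annotation"])], ["synthetic"]
    )
    candidates = lncrna_candidates(annots)
    probes = []
    for platform, path in sorted(manifest["platforms"].items()):
        probes.extend(read_probe_bed6(_resolve(base, path), platform))
    assignments = assign_probes(probes, annots)
    assign_df = assignments_to_frame(assignments)
    probe_supported_ids = set(
        assign_df.loc[assign_df["target_kind"] == "lncRNA", "target_id"]
    )
    probe_supported = [t for t in candidates if t.id in probe_supported_ids]

    # --- TSS regions ----------------------------------------------------------
    reads = read_bed6(_resolve(base, manifest["tss_reads"]))
    tss_regions = build_tss_regions(reads)

    # --- chromatin peak sets & catalog ---------------------------------------
    if not manifest.get("tracks"):
        raise ValueError(
            "manifest lists no chromatin tracks: filter_by_chromatin requires "
            "peak files for H3K4me3/H3K4me1/PolII"
        )
    peak_sets = {}
    for mark, conds in manifest["tracks"].items():
        for condition, entry in conds.items():
            peak_sets[(mark, condition)] = read_peaks(_resolve(base, entry["peaks"]))
    catalog, cat_funnel = build_catalog(
        probe_supported, tss_regions, annots, peak_sets,
        exclude_exonic_sense=exclude_exonic_sense,
    )
    if not catalog:
        raise RuntimeError("no lncRNA survived the TSS/chromatin/ambiguity filters")

    # --- expression integration ----------------------------------------------
    coding_ids = {t.id for t in annots.coding()}
    tested_ids = {
        r.lnc_id for r in catalog if not r.excluded_from_expression
    }
    lnc_tables, coding_tables = [], []
    for entry in manifest["datasets"]:
        values = pd.read_csv(
            _resolve(base, entry["path"]), sep="\t", index_col="probe_id"
        )
        mat = ExpressionMatrix(entry["platform"], values, dict(entry["conditions"]))
        mat = knn_impute(mat, k=knn_k)
        collapsed = collapse_to_transcripts(mat, assign_df)
        fc = log2_fold_change(collapsed, mat.conditions, entry["id"])
        lnc_entries = fc.entries[fc.entries.index.isin(tested_ids)]
        coding_entries = fc.entries[fc.entries.index.isin(coding_ids)]
        if not lnc_entries.empty:
            lnc_tables.append(FoldChangeTable(entry["id"], lnc_entries))
        if not coding_entries.empty:
            coding_tables.append(FoldChangeTable(entry["id"], coding_entries))
    up_results = rra_aggregate(lnc_tables, "up")
    down_results = rra_aggregate(lnc_tables, "down")
    up, down = call_regulated(up_results, down_results, alpha)
    lnc_mean_fc = mean_fold_change(lnc_tables)
    dataset_correlation = fold_change_correlation(lnc_tables)

    # --- chromatin signatures -------------------------------------------------
    tracks, library_sizes = {}, {}
    for mark, conds in manifest["tracks"].items():
        for condition, entry in conds.items():
            tracks[(mark, condition)] = BedGraphTrack.read(
                _resolve(base, entry["coverage"])
            )
            library_sizes[(mark, condition)] = float(entry.get("library_size", 1e7))
    densities = quantify_catalog(catalog, tracks, library_sizes)
    chromatin_calls = classify_catalog(catalog, densities)
    labels = {r.lnc_id: r.chromatin_class for r in catalog}
    ks_table = mark_change_vs_expression(densities, lnc_mean_fc, labels)
    up_ids = {a.transcript_id for a in up}
    down_ids = {a.transcript_id for a in down}
    regulation_table = regulation_class_table(up_ids, down_ids, labels)
    if regulation_table.to_numpy().sum() and (regulation_table.to_numpy().sum(axis=0) > 0).all():
        chi = chi_square_regulation(regulation_table)
    else:
        chi = (float("nan"), float("nan"))

    # --- neighbors & TF binding ----------------------------------------------
    genes = coding_gene_models(annots)
    tx_to_gene = {t.id: t.gene_symbol for t in annots.coding()}
    coding_tx_fc = mean_fold_change(coding_tables) if coding_tables else pd.Series(dtype=float)
    gene_fc = gene_level_fold_change(coding_tx_fc, tx_to_gene)
    pairs = build_neighbor_pairs(catalog, genes, lnc_mean_fc, gene_fc)
    coexpr = neighbor_coexpression(pairs, gene_fc, up_ids | down_ids)
    dist_ttest = distance_by_chromatin_class(pairs)
    tf_peak_sets = {
        (tf, condition): read_peaks(_resolve(base, path))
        for tf, conds in manifest.get("tf_peaks", {}).items()
        for condition, path in conds.items()
    }
    if tf_peak_sets:
        tf_binding, tf_summary = associate_tf_peaks(catalog, tf_peak_sets, tf_window)
        tf_shift = tf_target_expression_shift(tf_binding, lnc_mean_fc)
    else:
        tf_binding, tf_summary, tf_shift = pd.DataFrame(), {}, pd.DataFrame()

    funnel = FunnelReport(
        counts={
            "probes_total": len(probes),
            "probes_assigned": len(assignments),
            "lncrna_candidates": len(candidates),
            "probe_supported": len(probe_supported),
            "with_tss": cat_funnel["with_tss"],
            "after_chromatin": cat_funnel["after_chromatin"],
            "after_ambiguity": cat_funnel["after_ambiguity"],
            "catalog": len(catalog),
            **{k: v for k, v in cat_funnel.items() if k.startswith("class_")},
            "elncRNA": sum(r.chromatin_class == "elncRNA" for r in catalog),
            "plncRNA": sum(r.chromatin_class == "plncRNA" for r in catalog),
            "unclassified_chromatin": sum(
                r.chromatin_class == "unclassified" for r in catalog
            ),
            "up_regulated": len(up),
            "down_regulated": len(down),
            "tf_bound_any_core": tf_summary.get("bound_by_any_core", 0),
        }
    )

    result = PipelineResult(
        funnel=funnel, catalog=catalog, assignments=assign_df,
        lnc_tables=lnc_tables, coding_tables=coding_tables,
        up=up, down=down, up_results=up_results, down_results=down_results,
        densities=densities, chromatin_calls=chromatin_calls,
        ks_table=ks_table, regulation_table=regulation_table, chi_square=chi,
        neighbor_pairs=pairs, coexpression=coexpr, distance_ttest=dist_ttest,
        tf_binding=tf_binding, tf_summary=tf_summary,
        tf_expression_shift=tf_shift, dataset_correlation=dataset_correlation,
        lnc_mean_fc=lnc_mean_fc, gene_fc=gene_fc,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), meta)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, meta: dict) -> None:
    from ._bedio import write_tsv

    out_dir.mkdir(parents=True, exist_ok=True)
    write_tsv(catalog_to_frame(result.catalog), out_dir / "catalog.tsv", meta)
    write_tsv(result.assignments, out_dir / "assignments.tsv", meta)
    rra = pd.concat(
        [results_to_frame(result.up_results), results_to_frame(result.down_results)],
        ignore_index=True,
    )
    write_tsv(rra, out_dir / "rra.tsv", meta)
    write_tsv(
        result.densities.reset_index(), out_dir / "chromatin_densities.tsv", meta
    )
    write_tsv(result.ks_table, out_dir / "chromatin_ks.tsv", meta)
    write_tsv(result.neighbor_pairs, out_dir / "neighbors.tsv", meta)
    if not result.tf_binding.empty:
        write_tsv(result.tf_binding, out_dir / "tf_binding.tsv", meta)
    per_dataset = pd.DataFrame(
        {t.dataset_id: t.entries for t in result.lnc_tables}
    )
    per_dataset.index.name = "transcript_id"
    write_tsv(per_dataset.reset_index(), out_dir / "lnc_log2fc_per_dataset.tsv", meta)
    report = {
        **meta,
        "funnel": result.funnel.counts,
        "chi_square": {
            "statistic": result.chi_square[0], "p": result.chi_square[1],
        },
        "tf_summary": {
            k: v for k, v in result.tf_summary.items() if k != "venn"
        },
        "tf_venn": result.tf_summary.get("venn", {}),
    }
    with open(out_dir / "funnel.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
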