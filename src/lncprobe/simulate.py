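"""Synthetic input universe with planted truth for every pipeline stage.

The genome is a sequence of disjoint 60 kb blocks, each containing one
protein-coding gene (three exons on the + strand at a fixed block offset)
and one lncRNA placed so that its positional class is unambiguous:

  exonic_sense   lncRNA inside the middle coding exon, + strand
  intronic_sense lncRNA inside the first intron, + strand
  antisense      lncRNA overlapping the coding locus, - strand
  bidirectional  lncRNA head-to-head with the gene, - strand, 800 bp gap
  intergenic     lncRNA 13 kb upstream of the gene, + strand

Block spacing is chosen so that the +/-30 kb TSS association window of any
lncRNA never reaches a neighboring block's lncRNA TSS. A few extra "decoy"
blocks carry two overlapping coding genes; probes planted across their
shared exon boundary are ambiguous and must be removed by reannotation.

Planted signals:

* TSS-seq tags: Poisson-distributed counts within +/-10 bp of every true
  TSS, over a sparse Poisson background.
* Chromatin coverage (bedGraph) over +/-2 kb of each lncRNA TSS with an
  H3K4me1:H3K4me3 density ratio of 4:1 for planted enhancer-like loci and
  1:4 for promoter-like loci; H3K27Ac/H3K4me3/PolII coverage shifts under
  LPS concordant with the planted regulation direction.
* Expression: probe-level log2 intensities = transcript baseline U(4, 12)
  + platform offset N(0, 0.3) + condition effect + N(0, noise_sd), across
  12 datasets on 3 pseudo-platforms; each platform omits a random 20% of
  lncRNAs. The coding gene in a regulated lncRNA's block receives a
  concordant effect (lncRNA effect + N(0, 0.3)).
* TF peaks: a configurable number of regulated lncRNAs are bound by all
  four core factors (p65, IRF3, JunB, cJun) with summits staggered within
  2 kb; the rest of the regulated set gets random proper subsets; Bcl6
  peaks are planted to colocalize with core-factor sites.

Everything is derived from one numpy Generator seeded from the config, so a
fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from ._bedio import Bed6Record, write_bed6, write_bedgraph, write_peaks
from .expression import FoldChangeTable

POSITION_CLASSES = (
    "exonic_sense", "intronic_sense", "antisense", "bidirectional", "intergenic",
)

# per-block geometry (offsets within a block), coding gene on '+'
GENE_SPAN = (20_000, 30_000)
GENE_EXONS = ((20_000, 21_000), (24_000, 25_000), (29_000, 30_000))
LNC_GEOMETRY = {
    # class -> (start, end, strand)
    "exonic_sense": (24_200, 24_900, "+"),
    "intronic_sense": (22_000, 23_000, "+"),
    "antisense": (25_500, 27_000, "-"),
    "bidirectional": (18_500, 19_200, "-"),
    "intergenic": (5_000, 7_000, "+"),
}
DECOY_A = {"span": (20_000, 30_000), "exons": ((20_000, 21_000), (29_000, 30_000))}
DECOY_B = {"span": (29_500, 39_500), "exons": ((29_500, 30_500), (38_500, 39_500))}

MARKS = ("H3K4me3", "H3K4me1", "H3K27Ac", "PolII")
CONDITIONS = ("unstim", "LPS")
CORE_TFS = ("p65", "IRF3", "JunB", "cJun")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic universe; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 4
    block_bp: int = 60_000
    n_per_class: dict = field(
        default_factory=lambda: {
            "exonic_sense": 30, "intronic_sense": 30, "antisense": 160,
            "bidirectional": 160, "intergenic": 180,
        }
    )
    n_decoy_blocks: int = 8
    n_platforms: int = 3
    n_datasets: int = 12
    samples_per_condition: int = 3
    n_up: int = 15
    n_down: int = 12
    effect_up: float = 2.0
    effect_down: float = -2.0
    neighbor_noise_sd: float = 0.3
    noise_sd: float = 0.5
    platform_offset_sd: float = 0.3
    platform_dropout: float = 0.2
    missing_fraction: float = 0.02
    probe_length: int = 50
    probes_per_transcript_max: int = 3
    read_length: int = 30
    tss_tag_mean: float = 80.0
    background_tag_rate: float = 1e-6  # per bp per strand
    enhancer_ratio: tuple = (4.0, 1.0)  # (me1, me3) densities at elncRNA TSSs
    promoter_ratio: tuple = (1.0, 4.0)
    base_k27ac: float = 2.0
    base_polii: float = 2.0
    lps_shift_log2: float = 1.5  # mark coverage shift for regulated loci
    elnc_fraction: float = 0.4
    n_bound_all_four: int = 5
    ambiguous_probes_per_decoy: int = 1

    def validate(self) -> None:
        eligible = self.n_per_class["antisense"] + self.n_per_class["intergenic"]
        if self.n_up + self.n_down > eligible:
            raise ValueError("more regulated lncRNAs requested than eligible loci")
        if self.n_bound_all_four > self.n_up + self.n_down:
            raise ValueError("more all-four TF-bound lncRNAs than regulated lncRNAs")
        for key, n in self.n_per_class.items():
            if key not in POSITION_CLASSES or n < 0:
                raise ValueError(f"bad class count {key}={n}")
        if self.noise_sd < 0 or self.background_tag_rate < 0 or self.tss_tag_mean < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.n_datasets < 1 or self.n_platforms < 1:
            raise ValueError("need at least one dataset and platform")


@dataclass
class SimulatedUniverse:
    """Paths to every generated file plus the planted truth tables."""

    out_dir: Path
    config: SimulationConfig
    manifest_path: Path
    truth: pd.DataFrame          # one row per lncRNA
    probe_truth: pd.DataFrame    # one row per probe
    n_tss_tags: int


def _build_features(cfg: SimulationConfig):
    """Lay out coding genes and lncRNAs block by block."""
    transcripts = []
    lnc_meta = []  # dicts: lnc_id, class, tss, block info
    block = 0
    for cls in POSITION_CLASSES:
        for _ in range(cfg.n_per_class[cls]):
            chrom = f"chr{block % cfg.n_chromosomes + 1}"
            b = (block // cfg.n_chromosomes) * cfg.block_bp
            gene_id = f"GENE{block:04d}"
            transcripts.append(
                ann.TranscriptRecord(
                    id=f"tx_{gene_id}", source="synthetic", chrom=chrom,
                    start=b + GENE_SPAN[0], end=b + GENE_SPAN[1], strand="+",
                    exons=tuple((b + e0, b + e1) for e0, e1 in GENE_EXONS),
                    biotype="coding", gene_symbol=gene_id,
                )
            )
            s, e, strand = LNC_GEOMETRY[cls]
            lnc_id = f"lnc{block:04d}"
            lnc = ann.TranscriptRecord(
                id=lnc_id, source="synthetic", chrom=chrom,
                start=b + s, end=b + e, strand=strand,
                exons=((b + s, b + e),), biotype="noncoding", gene_symbol=lnc_id,
            )
            transcripts.append(lnc)
            lnc_meta.append(
                {
                    "lnc_id": lnc_id, "chrom": chrom, "start": b + s, "end": b + e,
                    "strand": strand, "true_tss": lnc.tss, "position_class": cls,
                    "neighbor_gene": gene_id, "gene_id": f"tx_{gene_id}",
                }
            )
            block += 1
    # decoy blocks: two overlapping coding genes, ambiguous probe territory
    decoys = []
    for _ in range(cfg.n_decoy_blocks):
        chrom = f"chr{block % cfg.n_chromosomes + 1}"
        b = (block // cfg.n_chromosomes) * cfg.block_bp
        for label, geom in (("A", DECOY_A), ("B", DECOY_B)):
            gid = f"DECOY{label}{block:04d}"
            transcripts.append(
                ann.TranscriptRecord(
                    id=f"tx_{gid}", source="synthetic", chrom=chrom,
                    start=b + geom["span"][0], end=b + geom["span"][1], strand="+",
                    exons=tuple((b + e0, b + e1) for e0, e1 in geom["exons"]),
                    biotype="coding", gene_symbol=gid,
                )
            )
        decoys.append({"chrom": chrom, "block_start": b, "block": block})
        block += 1
    return transcripts, lnc_meta, decoys


def _plant_regulation(cfg: SimulationConfig, lnc_meta, rng):
    eligible = [
        m["lnc_id"] for m in lnc_meta
        if m["position_class"] in ("antisense", "intergenic")
    ]
    chosen = rng.choice(np.array(sorted(eligible)), size=cfg.n_up + cfg.n_down,
                        replace=False)
    up = set(map(str, chosen[: cfg.n_up]))
    down = set(map(str, chosen[cfg.n_up:]))
    return up, down


def _plant_tf_binding(cfg: SimulationConfig, lnc_meta, regulated_ids, rng):
    """Return {lnc_id: tuple of core TFs}, with exactly n_bound_all_four full sets."""
    regulated = sorted(regulated_ids)
    all_four = regulated[: cfg.n_bound_all_four]
    binding = {lnc: CORE_TFS for lnc in all_four}
    for lnc in regulated[cfg.n_bound_all_four:]:
        mask = rng.random(len(CORE_TFS)) < 0.5
        if mask.all():
            mask[rng.integers(len(CORE_TFS))] = False  # keep all-four sets exact
        tfs = tuple(tf for tf, m in zip(CORE_TFS, mask) if m)
        if tfs:
            binding[lnc] = tfs
    return binding


def _emit_tss_reads(cfg, transcripts, rng, path):
    """TSS-seq reads: Poisson tag bundles at true TSSs plus sparse background."""
    records = []
    total_tags = 0
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
        n = int(rng.poisson(cfg.tss_tag_mean))
        total_tags += n
        offsets = rng.integers(-10, 11, size=n)
        for i, off in enumerate(offsets):
            pos = max(cfg.read_length, t.tss + int(off))
            if t.strand == "+":
                start, end = pos, pos + cfg.read_length
            else:
                start, end = pos - cfg.read_length + 1, pos + 1
            records.append(
                Bed6Record(t.chrom, start, end, f"read_{t.id}_{i}", 0, t.strand)
            )
    # background
    chrom_span = {}
    for t in transcripts:
        chrom_span[t.chrom] = max(chrom_span.get(t.chrom, 0), t.end + 40_000)
    for chrom in sorted(chrom_span):
        for strand in ("+", "-"):
            n_bg = int(rng.poisson(cfg.background_tag_rate * chrom_span[chrom]))
            total_tags += n_bg
            for i, pos in enumerate(
                sorted(rng.integers(cfg.read_length, chrom_span[chrom], size=n_bg))
            ):
                if strand == "+":
                    start, end = int(pos), int(pos) + cfg.read_length
                else:
                    start, end = int(pos) - cfg.read_length + 1, int(pos) + 1
                records.append(
                    Bed6Record(chrom, start, end, f"bg_{chrom}{strand}{i}", 0, strand)
                )
    records.sort(key=lambda r: (r.chrom, r.start, r.strand, r.name))
    write_bed6(records, path)
    return total_tags


def _events_to_intervals(events_by_chrom):
    """Sweep (pos, delta) events into non-overlapping constant-value intervals."""
    out = []
    for chrom in sorted(events_by_chrom):
        events = {}
        for pos, delta in events_by_chrom[chrom]:
            events[pos] = events.get(pos, 0.0) + delta
        level, prev = 0.0, None
        for pos in sorted(events):
            if prev is not None and level > 1e-12 and pos > prev:
                out.append((chrom, prev, pos, level))
            level += events[pos]
            prev = pos
    return out


def _emit_chromatin(cfg, lnc_meta, transcripts, truth_rows, out_dir):
    """Coverage bedGraphs and peak BEDs per (mark, condition)."""
    regulation = {r["lnc_id"]: r["regulation"] for r in truth_rows}
    chrom_label = {r["lnc_id"]: r["chromatin_class"] for r in truth_rows}
    coding_tss = [
        (t.chrom, t.tss) for t in transcripts if t.biotype == "coding"
    ]
    paths = {}
    for mark in MARKS:
        for condition in CONDITIONS:
            events: dict[str, list] = {}
            peaks: dict[str, list] = {}

            def add_window(chrom, tss, density, with_peak):
                lo, hi = max(0, tss - 2000), tss + 2000
                if density > 0:
                    events.setdefault(chrom, []).append((lo, density))
                    events.setdefault(chrom, []).append((hi, -density))
                if with_peak:
                    peaks.setdefault(chrom, []).append((max(0, tss - 500), tss + 500))

            for m in lnc_meta:
                label = chrom_label[m["lnc_id"]]
                reg = regulation[m["lnc_id"]]
                me1, me3 = (
                    cfg.enhancer_ratio if label == "elncRNA" else cfg.promoter_ratio
                )
                shift = 1.0
                if condition == "LPS" and reg != "none":
                    shift = 2.0 ** (
                        cfg.lps_shift_log2 if reg == "up" else -cfg.lps_shift_log2
                    )
                if mark == "H3K4me1":
                    add_window(m["chrom"], m["true_tss"], me1, label == "elncRNA")
                elif mark == "H3K4me3":
                    add_window(m["chrom"], m["true_tss"], me3 * shift, label == "plncRNA")
                elif mark == "H3K27Ac":
                    add_window(m["chrom"], m["true_tss"], cfg.base_k27ac * shift, False)
                else:  # PolII
                    add_window(m["chrom"], m["true_tss"], cfg.base_polii * shift, True)
            if mark in ("H3K4me3", "PolII"):
                # coding promoters contribute peaks (for the TSS filter) but no
                # coverage: their 2 kb windows would bleed into the TSS windows
                # of bidirectional/intronic lncRNAs and distort planted ratios
                for chrom, tss in coding_tss:
                    add_window(chrom, tss, 0.0, True)

            cov_path = out_dir / f"coverage_{mark}_{condition}.bedgraph"
            write_bedgraph(_events_to_intervals(events), cov_path)
            peak_path = out_dir / f"peaks_{mark}_{condition}.bed"
            write_peaks({c: sorted(iv) for c, iv in peaks.items()}, peak_path)
            paths[(mark, condition)] = (cov_path, peak_path)
    return paths


def _emit_tf_peaks(cfg, lnc_meta, binding, regulated_core_bound, rng, out_dir):
    """TF peak BEDs; summits staggered within 2 kb downstream of the TSS."""
    meta_by_id = {m["lnc_id"]: m for m in lnc_meta}
    peak_paths = {}
    tf_offsets = {tf: 3000 + 400 * i for i, tf in enumerate(CORE_TFS)}
    per_tf: dict[tuple[str, str], dict[str, list]] = {
        (tf, cond): {} for tf in (*CORE_TFS, "Bcl6") for cond in CONDITIONS
    }
    for lnc_id, tfs in sorted(binding.items()):
        m = meta_by_id[lnc_id]
        for tf in tfs:
            summit = m["true_tss"] + tf_offsets[tf]
            per_tf[(tf, "LPS")].setdefault(m["chrom"], []).append(
                (summit - 150, summit + 150)
            )
    # Bcl6: 5 unstim sites (4 colocalizing with core sites, 1 on an unbound lncRNA),
    # 1 LPS site colocalizing -> colocalization fractions 0.8 and 1.0
    core_bound = sorted(regulated_core_bound)
    unbound = sorted(m["lnc_id"] for m in lnc_meta if m["lnc_id"] not in binding)
    bcl6_unstim = core_bound[:4] + unbound[:1]
    bcl6_lps = core_bound[:1]
    for cond, targets in (("unstim", bcl6_unstim), ("LPS", bcl6_lps)):
        for lnc_id in targets:
            m = meta_by_id[lnc_id]
            summit = m["true_tss"] + 3200
            per_tf[("Bcl6", cond)].setdefault(m["chrom"], []).append(
                (summit - 150, summit + 150)
            )
    for (tf, cond), peaks in per_tf.items():
        path = out_dir / f"tf_{tf}_{cond}.bed"
        write_peaks({c: sorted(iv) for c, iv in peaks.items()}, path)
        peak_paths[(tf, cond)] = path
    return peak_paths, {"bcl6_unstim": bcl6_unstim, "bcl6_lps": bcl6_lps}


def _emit_probes(cfg, transcripts, decoys, rng, out_dir):
    """Probe BED6 per platform; decoy blocks get planted ambiguous probes."""
    lnc_ids = sorted(t.id for t in transcripts if t.biotype == "noncoding")
    probe_paths, probe_rows = {}, []
    platform_probes = {}
    # sample per-platform dropout up front; every lncRNA keeps >= 1 platform
    # (the catalog is the union over platforms, mirroring their overlap structure)
    dropout_sets = []
    for _ in range(cfg.n_platforms):
        dropout_sets.append(
            set(
                rng.choice(
                    np.array(lnc_ids),
                    size=int(round(cfg.platform_dropout * len(lnc_ids))),
                    replace=False,
                )
            )
        )
    for lnc in lnc_ids:
        if all(lnc in d for d in dropout_sets):
            dropout_sets[int(rng.integers(cfg.n_platforms))].discard(lnc)
    for p in range(cfg.n_platforms):
        platform = f"P{p + 1}"
        dropped = dropout_sets[p]
        records, counter = [], 0
        probe_to_target = {}
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            if t.id in dropped:
                continue
            n_probes = int(rng.integers(1, cfg.probes_per_transcript_max + 1))
            usable = [e for e in t.exons if e[1] - e[0] >= cfg.probe_length]
            if not usable:
                continue
            for _ in range(n_probes):
                e0, e1 = usable[int(rng.integers(len(usable)))]
                start = int(rng.integers(e0, e1 - cfg.probe_length + 1))
                counter += 1
                pid = f"{platform}_probe_{counter:06d}"
                records.append(
                    Bed6Record(t.chrom, start, start + cfg.probe_length, pid, 0, t.strand)
                )
                probe_to_target[pid] = t.id
                probe_rows.append(
                    {
                        "probe_id": pid, "platform": platform, "planted_target": t.id,
                        "ambiguous": False,
                    }
                )
        # ambiguous probes across the decoy genes' shared exon boundary
        for d in decoys:
            b = d["block_start"]
            for _ in range(cfg.ambiguous_probes_per_decoy):
                start = b + 29_500 + int(rng.integers(0, 500 - cfg.probe_length))
                counter += 1
                pid = f"{platform}_probe_{counter:06d}"
                records.append(
                    Bed6Record(d["chrom"], start, start + cfg.probe_length, pid, 0, "+")
                )
                probe_rows.append(
                    {
                        "probe_id": pid, "platform": platform, "planted_target": "",
                        "ambiguous": True,
                    }
                )
        records.sort(key=lambda r: (r.chrom, r.start, r.name))
        path = out_dir / f"probes_{platform}.bed"
        write_bed6(records, path)
        probe_paths[platform] = path
        platform_probes[platform] = probe_to_target
    return probe_paths, pd.DataFrame(probe_rows), platform_probes


def _emit_expression(cfg, transcripts, effects, platform_probes, rng, out_dir):
    """Per-dataset probe-level TSV matrices and the manifest dataset entries."""
    baseline = {
        t.id: rng.uniform(4.0, 12.0)
        for t in sorted(transcripts, key=lambda t: t.id)
    }
    plat_offset = {}
    for platform in sorted(platform_probes):
        for tid in sorted(baseline):
            plat_offset[(platform, tid)] = rng.normal(0.0, cfg.platform_offset_sd)
    s = cfg.samples_per_condition
    columns = [f"unstim_{i + 1}" for i in range(s)] + [f"LPS_{i + 1}" for i in range(s)]
    conditions = {c: ("LPS" if c.startswith("LPS") else "unstim") for c in columns}
    dataset_entries = []
    for d in range(cfg.n_datasets):
        platform = f"P{d % cfg.n_platforms + 1}"
        probe_map = platform_probes[platform]
        probe_ids = sorted(probe_map)
        values = np.empty((len(probe_ids), len(columns)))
        for i, pid in enumerate(probe_ids):
            tid = probe_map[pid]
            mu = baseline[tid] + plat_offset[(platform, tid)]
            eff = effects.get(tid, 0.0)
            for j, col in enumerate(columns):
                bump = eff if conditions[col] == "LPS" else 0.0
                values[i, j] = mu + bump + rng.normal(0.0, cfg.noise_sd)
        if cfg.missing_fraction > 0:
            mask = rng.random(values.shape) < cfg.missing_fraction
            # keep at least one observed value per probe row
            full_rows = mask.all(axis=1)
            mask[full_rows, 0] = False
            values = np.where(mask, np.nan, values)
        df = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=columns)
        dataset_id = f"D{d + 1:02d}"
        path = out_dir / f"expr_{dataset_id}.tsv"
        df.round(6).to_csv(path, sep="\t")
        dataset_entries.append(
            {
                "id": dataset_id, "platform": platform, "path": path.name,
                "conditions": conditions,
            }
        )
    return dataset_entries


def simulate_universe(cfg: SimulationConfig, out_dir) -> SimulatedUniverse:
    """Generate the full synthetic input universe under `out_dir`."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    transcripts, lnc_meta, decoys = _build_features(cfg)
    annot_set = ann.AnnotationSet(transcripts)
    annot_path = out_dir / "annotation.bed12"
    ann.write_annotations_bed12(annot_set, annot_path)

    up, down = _plant_regulation(cfg, lnc_meta, rng)
    elnc_draw = rng.random(len(lnc_meta)) < cfg.elnc_fraction

    effects = {}
    truth_rows = []
    for m, is_elnc in zip(lnc_meta, elnc_draw):
        reg = "up" if m["lnc_id"] in up else "down" if m["lnc_id"] in down else "none"
        eff = (
            cfg.effect_up if reg == "up" else cfg.effect_down if reg == "down" else 0.0
        )
        effects[m["lnc_id"]] = eff
        if reg != "none":
            effects[m["gene_id"]] = eff + rng.normal(0.0, cfg.neighbor_noise_sd)
        truth_rows.append(
            {
                **{k: m[k] for k in (
                    "lnc_id", "chrom", "start", "end", "strand", "true_tss",
                    "position_class", "neighbor_gene",
                )},
                "chromatin_class": "elncRNA" if is_elnc else "plncRNA",
                "regulation": reg,
                "effect": eff,
            }
        )

    binding = _plant_tf_binding(cfg, lnc_meta, up | down, rng)
    for row in truth_rows:
        row["tf_bound"] = ",".join(binding.get(row["lnc_id"], ()))

    n_tags = _emit_tss_reads(cfg, transcripts, rng, out_dir / "tss_reads.bed")
    chromatin_paths = _emit_chromatin(cfg, lnc_meta, transcripts, truth_rows, out_dir)
    tf_paths, _bcl6 = _emit_tf_peaks(
        cfg, lnc_meta, binding, regulated_core_bound=set(binding), rng=rng,
        out_dir=out_dir,
    )
    probe_paths, probe_truth, platform_probes = _emit_probes(
        cfg, transcripts, decoys, rng, out_dir
    )
    dataset_entries = _emit_expression(
        cfg, transcripts, effects, platform_probes, rng, out_dir
    )

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth_lncrna.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    probe_truth_path = out_dir / "truth_probes.tsv"
    probe_truth.to_csv(probe_truth_path, sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "annotation": annot_path.name,
        "tss_reads": "tss_reads.bed",
        "platforms": {p: path.name for p, path in sorted(probe_paths.items())},
        "datasets": dataset_entries,
        "tracks": {
            mark: {
                cond: {
                    "coverage": chromatin_paths[(mark, cond)][0].name,
                    "peaks": chromatin_paths[(mark, cond)][1].name,
                    "library_size": 1e7,
                }
                for cond in CONDITIONS
            }
            for mark in MARKS
        },
        "tf_peaks": {
            tf: {cond: tf_paths[(tf, cond)].name for cond in CONDITIONS}
            for tf in (*CORE_TFS, "Bcl6")
        },
        "truth": truth_path.name,
        "probe_truth": probe_truth_path.name,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return SimulatedUniverse(
        out_dir=out_dir, config=cfg, manifest_path=manifest_path,
        truth=truth, probe_truth=probe_truth, n_tss_tags=n_tags,
    )


def worked_toy() -> dict:
    """A hand-checkable micro-universe exercising each computation.

    Returns a dict with:

    * ``tags`` — three + strand TSS tags at 100, 115, 140: with a 20 bp gap
      they cluster as {100, 115} and {140}.
    * ``annotations`` — a coding gene at [10000, 15000) on + and a 700 bp
      lncRNA at [8500, 9200) on -, head-to-head with an 800 bp gap: class
      bidirectional.
    * ``fold_change_tables`` — two 2-transcript datasets where transcript T1
      has the better fold change in both: normalized ranks (0.5, 0.5), so
      rho = P(Bin(2, 0.5) >= 2) = 0.25 and p = min(1, 0.25 * 2) = 0.5.
    * ``densities`` — me1 = 4, me3 = 1 (ratio 4 -> elncRNA) and the reverse
      (ratio 0.25 -> plncRNA).
    """
    from .tss import TssTag

    tags = [TssTag("chr1", p, "+") for p in (100, 115, 140)]
    gene = ann.TranscriptRecord(
        id="tx_GeneT", source="synthetic", chrom="chr1", start=10_000, end=15_000,
        strand="+", exons=((10_000, 11_000), (14_000, 15_000)),
        biotype="coding", gene_symbol="GeneT",
    )
    lnc = ann.TranscriptRecord(
        id="lncT", source="synthetic", chrom="chr1", start=8_500, end=9_200,
        strand="-", exons=((8_500, 9_200),), biotype="noncoding", gene_symbol="lncT",
    )
    tables = [
        FoldChangeTable("toyA", pd.Series({"T1": 2.0, "T2": 0.0})),
        FoldChangeTable("toyB", pd.Series({"T1": 1.5, "T2": -0.5})),
    ]
    return {
        "tags": tags,
        "annotations": ann.AnnotationSet([gene, lnc]),
        "lnc": lnc,
        "fold_change_tables": tables,
        "densities": {"enhancer": (4.0, 1.0), "promoter": (1.0, 4.0)},
        "expected": {
            "clusters": [(100, 115), (140, 140)],
            "bidirectional_gap": 800,
            "rho_T1": 0.25,
            "p_T1": 0.5,
        },
    }
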