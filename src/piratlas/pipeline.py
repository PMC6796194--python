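"""End-to-end pipeline orchestration: config validation and stage driver.

``run_all`` executes classify -> discover -> pingpong -> quantify -> logo
on a set of aligned libraries, writing TSV/BED outputs plus a JSON run
report with the parameters used and per-stage read counts.  Stage outputs
are pure functions of (inputs, config); two runs on the same inputs are
diff-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from piratlas import __version__
from piratlas.classify import (
    ClassifierParams,
    classify_library,
    select_putative_pirnas,
)
from piratlas.cluster_discovery import (
    ClusterParams,
    compare_to_reference,
    discover_clusters,
    strandedness,
)
from piratlas.core_model import (
    GENOME,
    TE_CONSENSUS,
    AnnotationSet,
    ReadLibrary,
    read_alignments,
    read_fasta,
    read_gff3,
    read_spike_table,
    write_bed,
)
from piratlas.quantify import (
    CountMatrix,
    DGEParams,
    benjamini_hochberg,
    call_significant,
    count_features,
    cpm,
    expression_filter,
    group_log2fc,
    mirna_denominators,
    spikein_factors,
    te_expression,
    two_group_test,
    utr3_pirna_report,
)
from piratlas.signatures import (
    first10_frequency_matrix,
    ping_pong_histogram,
    ping_pong_scan,
    ping_pong_zscore,
)

logger = logging.getLogger("piratlas")


class ConfigError(ValueError):
    """Raised with every configuration violation listed at once."""


@dataclass
class SampleConfig:
    sample_id: str
    condition: str
    genome_sam: str
    te_sam: Optional[str] = None


@dataclass
class RunConfig:
    genome_fasta: str
    annotations_gff3: str
    samples: List[SampleConfig]
    spike_table: Optional[str] = None
    normalization: str = "spikein"      # mirna | spikein | total
    output_dir: str = "piratlas_out"
    seed: int = 0
    log_level: str = "INFO"
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    dge: DGEParams = field(default_factory=DGEParams)
    base_dir: Path = field(default_factory=Path)

    def resolve(self, path: Optional[str]) -> Optional[Path]:
        if path is None:
            return None
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, reporting all violations."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc

    errors: List[str] = []
    for key in ("genome_fasta", "annotations_gff3", "samples"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    samples: List[SampleConfig] = []
    for i, s in enumerate(raw.get("samples") or []):
        missing = [k for k in ("sample_id", "condition", "genome_sam")
                   if k not in s]
        if missing:
            errors.append(f"sample {i}: missing {missing}")
            continue
        samples.append(SampleConfig(
            s["sample_id"], s["condition"], s["genome_sam"], s.get("te_sam")
        ))
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        errors.append("duplicate sample ids")
    norm = raw.get("normalization", "spikein")
    if norm not in ("mirna", "spikein", "total"):
        errors.append(f"normalization must be mirna|spikein|total, got {norm}")
    if norm == "spikein" and not raw.get("spike_table"):
        errors.append("normalization=spikein requires spike_table")

    def build(cls, key):
        try:
            return cls(**(raw.get(key) or {}))
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
            return cls()

    classifier = build(ClassifierParams, "classifier")
    cluster = build(ClusterParams, "cluster")
    dge = build(DGEParams, "dge")

    cfg = RunConfig(
        genome_fasta=raw.get("genome_fasta", ""),
        annotations_gff3=raw.get("annotations_gff3", ""),
        samples=samples,
        spike_table=raw.get("spike_table"),
        normalization=norm,
        output_dir=raw.get("output_dir", "piratlas_out"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        classifier=classifier,
        cluster=cluster,
        dge=dge,
        base_dir=path.parent,
    )
    for label, p in [
        ("genome_fasta", cfg.genome_fasta),
        ("annotations_gff3", cfg.annotations_gff3),
        ("spike_table", cfg.spike_table),
    ] + [(f"sample {s.sample_id} genome_sam", s.genome_sam) for s in samples] \
      + [(f"sample {s.sample_id} te_sam", s.te_sam) for s in samples]:
        if p and cfg.resolve(p) is not None and not cfg.resolve(p).exists():
            errors.append(f"{label}: path does not exist: {p}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def load_libraries(cfg: RunConfig) -> List[ReadLibrary]:
    spikes = (
        read_spike_table(cfg.resolve(cfg.spike_table))
        if cfg.spike_table else {}
    )
    libs = []
    for s in cfg.samples:
        reads = read_alignments(cfg.resolve(s.genome_sam), space=GENOME)
        if s.te_sam:
            reads = reads + read_alignments(cfg.resolve(s.te_sam),
                                            space=TE_CONSENSUS)
        libs.append(ReadLibrary(
            s.sample_id, s.condition, reads,
            spikes.get(s.sample_id, {}), total_mapped=len(reads),
        ))
    return libs


def run_all(cfg: RunConfig) -> Dict[str, object]:
    """Execute classify -> discover -> pingpong -> quantify -> logo."""
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "classifier": asdict(cfg.classifier),
            "cluster": asdict(cfg.cluster),
            "dge": asdict(cfg.dge),
            "normalization": cfg.normalization,
        },
        "stages": [],
    }

    ann = read_gff3(cfg.resolve(cfg.annotations_gff3))
    genome = read_fasta(cfg.resolve(cfg.genome_fasta))
    libs = load_libraries(cfg)
    report["n_samples"] = len(libs)

    # ---- stage 1: classify -------------------------------------------------
    logger.info("stage classify: %d libraries", len(libs))
    biotype_rows = []
    by_label_per_sample: Dict[str, Dict[str, list]] = {}
    for lib in libs:
        by_label, counts = classify_library(lib, ann, cfg.classifier)
        by_label_per_sample[lib.sample_id] = by_label
        biotype_rows.append({"sample_id": lib.sample_id, **counts,
                             "total": len(lib.reads)})
    biotype_table = pd.DataFrame(biotype_rows).set_index("sample_id")
    biotype_table.to_csv(outdir / "biotype_counts.tsv", sep="\t")
    report["stages"].append("classify")
    report["classified_reads"] = {
        lib.sample_id: len(lib.reads) for lib in libs
    }
    report["biotype_counts"] = {
        r["sample_id"]: {k: v for k, v in r.items() if k != "sample_id"}
        for r in biotype_rows
    }

    # ---- stage 2: cluster discovery (pooled across samples) ---------------
    discovery_reads = [
        r for lib in libs
        for r in select_putative_pirnas(lib, ann, cfg.classifier, "discovery")
    ]
    clusters = discover_clusters(discovery_reads, cfg.cluster)
    logger.info("stage discover: %d clusters from %d reads",
                len(clusters), len(discovery_reads))
    cluster_ids = [f"cluster_{i + 1:04d}" for i in range(len(clusters))]
    write_bed([c.interval for c in clusters], outdir / "clusters.bed",
              names=cluster_ids, scores=[c.n_unique_reads for c in clusters])
    pd.DataFrame([
        {
            "cluster_id": cid,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "length": c.interval.length(),
            "n_unique_reads": c.n_unique_reads,
            "density_per_kb": c.density,
            "n_total_reads": c.n_total_reads,
            "plus_fraction": c.plus_fraction,
            "strandedness": strandedness(c, discovery_reads),
        }
        for cid, c in zip(cluster_ids, clusters)
    ]).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    if ann.canonical_clusters:
        ref_report = compare_to_reference(clusters, ann.canonical_clusters)
        report["canonical_covered_fraction"] = (
            ref_report["reference_covered_fraction"]
        )
        report["novel_call_fraction"] = ref_report["novel_call_fraction"]
    report["stages"].append("discover")
    report["n_clusters"] = len(clusters)
    report["n_discovery_reads"] = len(discovery_reads)

    # ---- stage 3: ping-pong ------------------------------------------------
    zs = {}
    for lib in libs:
        pirna_reads = select_putative_pirnas(lib, ann, cfg.classifier,
                                             "counting")
        table = ping_pong_scan(pirna_reads, clusters)
        table.insert(0, "sample_id", lib.sample_id)
        table.to_csv(outdir / f"{lib.sample_id}.pingpong.tsv", sep="\t",
                     index=False)
        in_clusters = [
            r for r in pirna_reads
            if any(r.interval.overlaps(c.interval) for c in clusters)
        ]
        z = ping_pong_zscore(ping_pong_histogram(in_clusters))
        zs[lib.sample_id] = None if z is None else float(z)
    report["stages"].append("pingpong")
    report["z10_per_sample"] = zs

    # ---- stage 4: quantify -------------------------------------------------
    features = {cid: c.interval for cid, c in zip(cluster_ids, clusters)}
    counting = {
        lib.sample_id: select_putative_pirnas(lib, ann, cfg.classifier,
                                              "counting")
        for lib in libs
    }
    sample_ids = [lib.sample_id for lib in libs]
    counts = np.column_stack([
        count_features(counting[sid], features).to_numpy()
        for sid in sample_ids
    ]) if clusters else np.zeros((0, len(sample_ids)), dtype=int)
    matrix = CountMatrix(cluster_ids, sample_ids, counts,
                         feature_lengths=np.array(
                             [c.interval.length() for c in clusters]))
    if cfg.normalization == "spikein":
        factors, eff = spikein_factors(
            {lib.sample_id: lib.spike_total() for lib in libs},
            {lib.sample_id: lib.total_mapped for lib in libs},
        )
        denominators = eff.loc[sample_ids].to_numpy()
        matrix.norm_factors = factors.loc[sample_ids].to_numpy()
    elif cfg.normalization == "mirna":
        mirna_features: Dict[str, object] = {}
        for i, iv in enumerate(ann.pre_mirna):
            mirna_features[f"mir_{i + 1:04d}"] = iv
        mirna_counts = np.column_stack([
            count_features(
                by_label_per_sample[sid]["miRNA"], mirna_features
            ).to_numpy()
            for sid in sample_ids
        ])
        mirna_matrix = CountMatrix(list(mirna_features), sample_ids,
                                   mirna_counts)
        groups = {lib.sample_id: lib.condition for lib in libs}
        denominators = mirna_denominators(
            mirna_matrix, n_exclude=2, groups=groups
        ).loc[sample_ids].to_numpy()
    else:
        denominators = np.array([float(lib.total_mapped) for lib in libs])
    matrix.norm_denominators = denominators
    cpm(matrix).to_csv(outdir / "cluster_cpm.tsv", sep="\t")
    matrix.to_frame().to_csv(outdir / "cluster_counts.tsv", sep="\t")

    conditions = {lib.sample_id: lib.condition for lib in libs}
    dge_table = None
    if len(set(conditions.values())) == 2 and len(matrix.feature_ids) > 0:
        filtered = expression_filter(matrix, cfg.dge.cpm_cutoff,
                                     cfg.dge.min_samples)
        if filtered.feature_ids:
            pvals = [
                two_group_test(
                    filtered.counts[i, :],
                    [conditions[s] for s in sample_ids],
                    denominators,
                )
                for i in range(len(filtered.feature_ids))
            ]
            qvals = benjamini_hochberg(pvals)
            lfc = group_log2fc(filtered, conditions, denominators,
                               cfg.dge.pseudo_count)
            calls = call_significant(lfc.to_numpy(), qvals, cfg.dge)
            dge_table = pd.DataFrame({
                "feature": filtered.feature_ids,
                "log2fc": lfc.to_numpy(),
                "pvalue_binomial_standin": pvals,
                "qvalue_bh": qvals,
                "call": calls,
            })
            dge_table.to_csv(outdir / "dge_clusters.tsv", sep="\t",
                             index=False)
            report["n_dge_tested"] = len(filtered.feature_ids)
            report["n_up"] = calls.count("up")
            report["n_down"] = calls.count("down")

    te_frames = []
    for lib in libs:
        te_reads = [r for r in lib.reads if r.space == TE_CONSENSUS]
        if not te_reads:
            continue
        te_names = ann.te_consensus_names or {r.target for r in te_reads}
        table = te_expression(te_reads, sorted(te_names))
        table.insert(0, "sample_id", lib.sample_id)
        te_frames.append(table.reset_index(names="te"))
    if te_frames:
        pd.concat(te_frames).to_csv(outdir / "te_counts.tsv", sep="\t",
                                    index=False)
    pooled_counting = [r for sid in sample_ids for r in counting[sid]]
    if ann.genes:
        utr3_pirna_report(
            pooled_counting, ann.genes, ann.te_insertions
        ).to_csv(outdir / "utr3_report.tsv", sep="\t")
    report["stages"].append("quantify")

    # ---- stage 5: logo -----------------------------------------------------
    if pooled_counting:
        matrix10 = first10_frequency_matrix(pooled_counting, genome)
        matrix10.freq.to_csv(outdir / "logo_matrix.tsv", sep="\t")
        report["logo_n_sites"] = matrix10.n_sites
        report["logo_u1_fraction"] = float(matrix10.freq.loc[1, "U"])
    report["stages"].append("logo")

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("completed %d stages", len(report["stages"]))
    return report
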