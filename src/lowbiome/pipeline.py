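"""One-command orchestration of the full contamination-aware analysis.

Given an OTU table, sample metadata, a tree and (optionally) qPCR records,
``run_pipeline`` applies the fixed preprocessing order, computes ensemble-
averaged alpha and beta diversity, the PBS-percentile exceedance test,
PCoA + PERMANOVA, matched-control distances (raw and within-fetus
normalized) with per-organ tests, the genus intensity screen, and the
log2FC + RPA differential enrichment.  Every parameter lands in a
machine-readable manifest so any number in the report can be recomputed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as lio
from .alpha import alpha_over_ensemble
from .beta import (
    average_distance_matrices,
    bray_curtis,
    pcoa,
    permanova,
    weighted_unifrac,
)
from .controls import (
    compare_tissue_vs_reference,
    exceedance_test,
    matched_control_distances,
    normalize_within_fetus,
    summarize_ct,
)
from .core import ValidationError, validate_dataset
from .enrichment import (
    aggregate_to_genus,
    classify_enriched_taxa,
    differential_enrichment,
    genus_mean_intensity,
)
from .preprocess import preprocess


@dataclass
class PipelineConfig:
    min_reads: int = 500
    depth: int = 1000
    reps: int = 10
    exceedance_q: float = 95.0
    beta_metric: str = "wunifrac"  # "wunifrac" | "braycurtis"
    unifrac_normalized: bool = True
    target_organ: str = "gut"
    internal_control: str = "spleen"
    lfc_cut: float = 2.0
    rpa_cut: float = 3.0
    pseudocount: float = 1.0
    theta: float = 0.5
    permutations: int = 999
    permanova_grouping: str = "sample_class"
    min_tissues: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("min_reads", "depth", "reps", "permutations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.seed is None:
            raise ValidationError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    manifest: dict
    alpha_shannon: object = None
    alpha_chao1: object = None
    exceedance: object = None
    distance_matrix: object = None
    pcoa: object = None
    permanova: object = None
    matched_raw: object = None
    matched_normalized: object = None
    organ_tests_unpaired: dict = field(default_factory=dict)
    organ_tests_paired: dict = field(default_factory=dict)
    genus_intensity: object = None
    taxa_screen: dict = field(default_factory=dict)
    enrichment: list = field(default_factory=list)
    ct_summary: object = None
    dropped: dict = field(default_factory=dict)


def _grouping(metadata, column: str, sample_ids) -> dict:
    out = {}
    for m in metadata:
        if m.sample_id in sample_ids:
            out[m.sample_id] = getattr(m, column)
    return out


def run_pipeline(table, metadata, tree=None, taxonomy=None, ct_records=None,
                 config: PipelineConfig | None = None) -> ReportBundle:
    config = config or PipelineConfig()
    report = validate_dataset(table, metadata, tree)
    if report.samples_without_metadata or report.taxa_missing_from_tree:
        raise ValidationError(f"stage validate: {report}")

    bundle = ReportBundle(manifest={"config": config.to_dict()})

    # preprocessing: singletons -> depth filter -> rarefaction ensemble
    ensemble = preprocess(
        table, min_reads=config.min_reads, depth=config.depth,
        reps=config.reps, seed=config.seed,
    )
    kept = set(ensemble.sample_ids)
    bundle.dropped["low_depth_samples"] = sorted(set(table.sample_ids) - kept)
    bundle.manifest["n_samples_analyzed"] = len(kept)

    # alpha diversity + exceedance
    bundle.alpha_shannon = alpha_over_ensemble(ensemble, "shannon")
    bundle.alpha_chao1 = alpha_over_ensemble(ensemble, "chao1")
    bundle.exceedance = exceedance_test(bundle.alpha_shannon, metadata, q=config.exceedance_q)

    # beta diversity per rep, element-wise averaged
    if config.beta_metric == "wunifrac":
        if tree is None:
            raise ValidationError("stage beta: weighted UniFrac requires a tree")
        mats = [
            weighted_unifrac(t, tree, normalized=config.unifrac_normalized)
            for t in ensemble.tables
        ]
    elif config.beta_metric == "braycurtis":
        mats = [bray_curtis(t) for t in ensemble.tables]
    else:
        raise ValidationError(f"unknown beta metric {config.beta_metric!r}")
    dm = average_distance_matrices(mats)
    bundle.distance_matrix = dm

    bundle.pcoa = pcoa(dm)
    bundle.permanova = permanova(
        dm,
        _grouping(metadata, config.permanova_grouping, kept),
        permutations=config.permutations,
        seed=config.seed,
    )

    # matched-control distances, raw and within-fetus normalized
    mds = matched_control_distances(dm, metadata)
    bundle.matched_raw = mds
    bundle.organ_tests_unpaired = compare_tissue_vs_reference(mds, paired=False)
    normalized = normalize_within_fetus(mds, min_tissues=config.min_tissues)
    bundle.matched_normalized = normalized
    bundle.organ_tests_paired = compare_tissue_vs_reference(normalized, paired=True)

    # taxa-level screens on the ensemble-mean table
    mean_table = ensemble.mean_table()
    if taxonomy is not None:
        bundle.genus_intensity = genus_mean_intensity(mean_table, taxonomy, metadata)
        bundle.taxa_screen = classify_enriched_taxa(bundle.genus_intensity, theta=config.theta)
        enrich_input = aggregate_to_genus(mean_table, taxonomy)
    else:
        enrich_input = mean_table
    bundle.enrichment = differential_enrichment(
        enrich_input, metadata,
        target_organ=config.target_organ,
        internal_control=config.internal_control,
        lfc_cut=config.lfc_cut, rpa_cut=config.rpa_cut,
        pseudocount=config.pseudocount,
    )

    if ct_records is not None:
        bundle.ct_summary = summarize_ct(ct_records, metadata)

    bundle.manifest["pbs_shannon_cutoff"] = bundle.exceedance.threshold
    bundle.manifest["permanova"] = {
        "pseudo_f": bundle.permanova.pseudo_f,
        "r2": bundle.permanova.r2,
        "p_value": bundle.permanova.p_value,
    }
    bundle.manifest["n_enriched_taxa"] = sum(1 for r in bundle.enrichment if r.enriched)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Serialize the bundle as TSV/JSON files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))
    for name in ("alpha_shannon", "alpha_chao1"):
        alpha = getattr(bundle, name)
        if alpha is not None:
            lines = ["sample_id\t" + alpha.metric] + [
                f"{s}\t{v:.12g}" for s, v in alpha.values.items()
            ]
            (out / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    if bundle.distance_matrix is not None:
        (out / "distance_matrix.tsv").write_text(
            lio.write_distance_matrix(bundle.distance_matrix)
        )
    if bundle.pcoa is not None:
        coords = bundle.pcoa.coordinates
        header = "sample_id\t" + "\t".join(f"PC{i + 1}" for i in range(coords.shape[1]))
        rows = [
            s + "\t" + "\t".join(f"{c:.12g}" for c in coords[i])
            for i, s in enumerate(bundle.pcoa.sample_ids)
        ]
        (out / "pcoa_coordinates.tsv").write_text("\n".join([header] + rows) + "\n")
        np.savetxt(out / "pcoa_explained.tsv", bundle.pcoa.proportion_explained)
    if bundle.enrichment:
        header = (
            "taxon_id\ta_target\tb_internal\tb_external\ts_target\ts_internal"
            "\ts_external\tlog2fc_vs_internal\tlog2fc_vs_external\trpa\tenriched"
        )
        rows = [
            f"{r.taxon_id}\t{r.a_target:.12g}\t{r.b_internal:.12g}\t{r.b_external:.12g}"
            f"\t{r.s_target}\t{r.s_internal}\t{r.s_external}"
            f"\t{r.log2fc_vs_internal:.12g}\t{r.log2fc_vs_external:.12g}"
            f"\t{r.rpa:.12g}\t{int(r.enriched)}"
            for r in bundle.enrichment
        ]
        (out / "enrichment.tsv").write_text("\n".join([header] + rows) + "\n")
    if bundle.taxa_screen:
        rows = [f"{g}\t{label}" for g, label in sorted(bundle.taxa_screen.items())]
        (out / "taxa_screen.tsv").write_text("genus\tlabel\n" + "\n".join(rows) + "\n")
    for name in ("matched_raw", "matched_normalized"):
        mds = getattr(bundle, name)
        if mds is not None:
            rows = [
                f"{r.sample_id}\t{r.fetus_id}\t{r.organ}\t{r.distance:.12g}"
                for r in mds.records
            ]
            (out / f"{name}.tsv").write_text(
                "sample_id\tfetus_id\torgan\tdistance\n" + "\n".join(rows) + "\n"
            )
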