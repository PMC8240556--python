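"""Taxa-level contaminant-vs-signal scoring.

Two complementary screens.  The intensity screen averages each genus's
abundance within every sample class and calls a genus a potential
contaminant ("control_enriched") when its PBS intensity is at least the
maximum fetal intensity, or a potential signal ("fetal_enriched") when PBS
is well below the fetal maximum.  The differential screen scores genus-level
OTUs in a target organ against an internal control (a low-signal fetal
organ) and the external PBS control:

    log2FC = log2((A_i + pc) / (B_i + pc))
    RPA    = 100 * S_target / (S_target + S_internal + S_PBS)

with A_i/B_i mean normalized counts, S_* the number of reads-positive
samples per class, and a taxon flagged enriched when both log2FC values
pass the cutoff (default 2) and RPA passes its cutoff (default 3%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OtuTable, Taxonomy, ValidationError, metadata_by_id, UNASSIGNED

DEFAULT_LFC_CUT = 2.0
DEFAULT_RPA_CUT = 3.0
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_THETA = 0.5


@dataclass
class GenusIntensityTable:
    """Mean per-class signal intensity per genus, plus class sizes."""

    intensities: pd.DataFrame  # genus x class
    class_sizes: dict

    def __post_init__(self):
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("negative intensity")


def aggregate_to_genus(table: OtuTable, taxonomy: Taxonomy) -> OtuTable:
    """Sum OTU counts within genus; unassignable lineages are dropped."""
    genus_map = taxonomy.genus_map(table.taxon_ids)
    frame = table.to_frame()
    frame.index = [genus_map[t] for t in table.taxon_ids]
    frame = frame[frame.index != UNASSIGNED]
    grouped = frame.groupby(level=0, sort=True).sum()
    return OtuTable.from_frame(grouped)


def _class_label(meta, per_organ: bool) -> str:
    if meta.sample_class == "fetal_tissue" and per_organ:
        return meta.organ
    return meta.sample_class


def genus_mean_intensity(
    table: OtuTable,
    taxonomy: Taxonomy,
    metadata,
    per_organ: bool = True,
) -> GenusIntensityTable:
    """Genus x class mean abundances; all-zero genera are removed.

    Counts are summed within genus per sample, then averaged across the
    samples of each class.  Fetal tissues form per-organ classes by default
    (pooled "fetal_tissue" with ``per_organ=False``).
    """
    by_id = metadata_by_id(metadata)
    genus_table = aggregate_to_genus(table, taxonomy)
    frame = genus_table.to_frame()
    labels = {s: _class_label(by_id[s], per_organ) for s in frame.columns if s in by_id}
    frame = frame[[s for s in frame.columns if s in labels]]
    classes = sorted(set(labels.values()))
    intensities = pd.DataFrame(index=frame.index, columns=classes, dtype=float)
    sizes = {}
    for cls in classes:
        cols = [s for s in frame.columns if labels[s] == cls]
        sizes[cls] = len(cols)
        intensities[cls] = frame[cols].mean(axis=1)
    nonzero = intensities.sum(axis=1) > 0
    return GenusIntensityTable(intensities=intensities.loc[nonzero], class_sizes=sizes)


FETAL_CLASSES = ("gut", "skin", "lung", "thymus", "spleen", "placenta", "liver", "mln", "fetal_tissue")
CONTROL_CLASSES = ("pbs", "reagent", "environment", "operator")


def classify_enriched_taxa(git: GenusIntensityTable, theta: float = DEFAULT_THETA) -> dict:
    """Label each genus control_enriched / fetal_enriched / indeterminate.

    control_enriched: PBS intensity >= max fetal intensity (the "higher or
    equal in PBS" contaminant rule).  fetal_enriched: PBS < theta * max
    fetal intensity with positive fetal signal.  Everything else is
    indeterminate.
    """
    cols = list(git.intensities.columns)
    if "pbs" not in cols:
        raise ValidationError("classification requires a PBS class")
    fetal_cols = [c for c in cols if c in FETAL_CLASSES]
    if not fetal_cols:
        raise ValidationError("classification requires at least one fetal class")
    out = {}
    for genus, row in git.intensities.iterrows():
        pbs = row["pbs"]
        fetal_max = row[fetal_cols].max()
        if pbs >= fetal_max:
            out[genus] = "control_enriched"
        elif fetal_max > 0 and pbs < theta * fetal_max:
            out[genus] = "fetal_enriched"
        else:
            out[genus] = "indeterminate"
    return out


def log2_fold_change(a: float, b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((a + pc)/(b + pc)); the pseudocount handles zero counts."""
    if a < 0 or b < 0:
        raise ValidationError("abundances must be >= 0")
    if pseudocount <= 0:
        if a <= 0 or b <= 0:
            raise ValidationError("zero abundance requires a positive pseudocount")
        return math.log2(a / b)
    return math.log2((a + pseudocount) / (b + pseudocount))


def relative_percentage_abundance(s_target: int, s_internal: int, s_external: int) -> float:
    """RPA = 100 * S_target / (S_target + S_internal + S_external)."""
    for s in (s_target, s_internal, s_external):
        if s < 0:
            raise ValidationError("prevalence counts must be >= 0")
    total = s_target + s_internal + s_external
    if total == 0:
        raise ValidationError("all prevalence counts are zero")
    return 100.0 * s_target / total


@dataclass(frozen=True)
class EnrichmentRecord:
    taxon_id: str
    a_target: float  # mean normalized count in the target organ
    b_internal: float
    b_external: float
    s_target: int
    s_internal: int
    s_external: int
    log2fc_vs_internal: float
    log2fc_vs_external: float
    rpa: float
    enriched: bool


def differential_enrichment(
    table: OtuTable,
    metadata,
    target_organ: str = "gut",
    internal_control: str = "spleen",
    lfc_cut: float = DEFAULT_LFC_CUT,
    rpa_cut: float = DEFAULT_RPA_CUT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_both: bool = True,
) -> list:
    """Score every taxon of a (genus-level) table for target-organ enrichment.

    A_i is the taxon's mean normalized count across target-organ samples,
    B_i the mean across the internal control (a low-signal organ) and the
    external PBS control; prevalence counts S_* are strictly-positive-count
    samples.  ``enriched`` requires both log2FC comparisons (or either, with
    ``require_both=False``) at ``lfc_cut`` plus RPA at ``rpa_cut``.
    Records are sorted by RPA descending, then log2FC vs internal.
    """
    by_id = metadata_by_id(metadata)
    groups = {"target": [], "internal": [], "external": []}
    for s in table.sample_ids:
        m = by_id.get(s)
        if m is None:
            continue
        if m.organ == target_organ:
            groups["target"].append(s)
        elif m.organ == internal_control:
            groups["internal"].append(s)
        elif m.sample_class == "pbs":
            groups["external"].append(s)
    for name, ids in groups.items():
        if not ids:
            raise ValidationError(f"no samples for the {name} class")
    sub = {k: table.select_samples(v) for k, v in groups.items()}
    means = {k: t.counts.mean(axis=1) for k, t in sub.items()}
    prevs = {k: (t.counts > 0).sum(axis=1).astype(int) for k, t in sub.items()}
    records = []
    for i, taxon in enumerate(table.taxon_ids):
        s_t, s_i, s_e = int(prevs["target"][i]), int(prevs["internal"][i]), int(prevs["external"][i])
        if s_t + s_i + s_e == 0:
            continue  # taxon absent from all three classes
        lfc_int = log2_fold_change(means["target"][i], means["internal"][i], pseudocount)
        lfc_ext = log2_fold_change(means["target"][i], means["external"][i], pseudocount)
        rpa = relative_percentage_abundance(s_t, s_i, s_e)
        passes = (lfc_int >= lfc_cut and lfc_ext >= lfc_cut) if require_both else (
            lfc_int >= lfc_cut or lfc_ext >= lfc_cut
        )
        records.append(
            EnrichmentRecord(
                taxon_id=taxon,
                a_target=float(means["target"][i]),
                b_internal=float(means["internal"][i]),
                b_external=float(means["external"][i]),
                s_target=s_t,
                s_internal=s_i,
                s_external=s_e,
                log2fc_vs_internal=lfc_int,
                log2fc_vs_external=lfc_ext,
                rpa=rpa,
                enriched=bool(passes and rpa >= rpa_cut),
            )
        )
    records.sort(key=lambda r: (-r.rpa, -r.log2fc_vs_internal))
    return records


def harmonize_genus(name: str, synonyms: dict | None = None) -> str:
    """Lowercase and strip strain/suffix decoration for overlap accounting."""
    base = name.strip().lower().split(" ")[0].split("_")[0]
    if synonyms:
        base = synonyms.get(base, base)
    return base


@dataclass
class OverlapReport:
    overlap_count: int
    cultured_count: int
    shared: set
    per_tissue: dict  # tissue -> (shared genera, cultured genera)


def culture_overlap(sequenced_genera: dict, cultured_genera: dict, synonyms: dict | None = None) -> OverlapReport:
    """Intersection of sequencing-detected vs culture-identified genera.

    Reports the global distinct-genus overlap (the "x of y cultured" count)
    and per-tissue intersections, on harmonized names.
    """
    def norm(sets):
        return {k: {harmonize_genus(g, synonyms) for g in v} for k, v in sets.items()}

    seq, cult = norm(sequenced_genera), norm(cultured_genera)
    all_seq = set().union(*seq.values()) if seq else set()
    all_cult = set().union(*cult.values()) if cult else set()
    shared = all_seq & all_cult
    per_tissue = {}
    for tissue, genera in cult.items():
        per_tissue[tissue] = (genera & seq.get(tissue, set()), genera)
    return OverlapReport(
        overlap_count=len(shared),
        cultured_count=len(all_cult),
        shared=shared,
        per_tissue=per_tissue,
    )
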