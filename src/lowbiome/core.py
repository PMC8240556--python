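"""Domain types shared by every pipeline stage.

The analysis starts from an OTU count table (taxa x samples), per-sample
metadata describing the contamination-control design (fetal tissue vs the
four negative-control classes), a rooted phylogeny for UniFrac, and qPCR
cycle-threshold replicates.  All types validate their invariants on
construction so downstream stages can assume consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

SAMPLE_CLASSES = ("fetal_tissue", "pbs", "reagent", "environment", "operator")
ORGANS = ("gut", "skin", "lung", "thymus", "spleen", "placenta", "liver", "mln", "none")

UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when a domain type's invariants are violated."""


class OtuTable:
    """Nonnegative abundance matrix over taxa (rows) x samples (columns).

    Counts are integers before rarefaction averaging and nonnegative reals
    afterwards.  Identifiers are opaque, case-sensitive strings; duplicates
    are rejected.
    """

    def __init__(self, taxon_ids, sample_ids, counts):
        taxon_ids = [str(t) for t in taxon_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape != (len(taxon_ids), len(sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxon_ids)} taxa x {len(sample_ids)} samples"
            )
        if len(set(taxon_ids)) != len(taxon_ids):
            raise ValidationError("duplicate taxon identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(counts)):
            raise ValidationError("non-finite counts")
        if np.any(counts < 0):
            raise ValidationError("negative counts")
        self.taxon_ids = list(taxon_ids)
        self.sample_ids = list(sample_ids)
        self.counts = counts

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OtuTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def is_integral(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.counts - np.round(self.counts)) <= tol))

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.taxon_ids, list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return OtuTable(list(taxon_ids), self.sample_ids, self.counts[idx, :])

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized proportions; errors on all-zero samples."""
        sums = self.sample_sums()
        if np.any(sums <= 0):
            bad = [s for s, t in zip(self.sample_ids, sums) if t <= 0]
            raise ValidationError(f"all-zero samples: {bad}")
        return self.counts / sums

    def __eq__(self, other):
        return (
            isinstance(other, OtuTable)
            and self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self):
        return f"OtuTable({self.n_taxa} taxa x {self.n_samples} samples)"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata driving grouping, matching and control logic.

    ``organ`` must be ``"none"`` for every non-tissue class and a real organ
    for fetal tissue.  PBS buffers intended for fetus-matched analysis carry
    the fetus identifier of their donor.
    """

    sample_id: str
    sample_class: str
    organ: str = "none"
    fetus_id: str | None = None
    ega_weeks: float | None = None
    facility: str | None = None

    def __post_init__(self):
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValidationError(
                f"unknown sample_class {self.sample_class!r}; "
                f"allowed: {', '.join(SAMPLE_CLASSES)}"
            )
        if self.organ not in ORGANS:
            raise ValidationError(f"unknown organ {self.organ!r}")
        if (self.sample_class == "fetal_tissue") != (self.organ != "none"):
            raise ValidationError(
                f"sample {self.sample_id!r}: organ={self.organ!r} inconsistent "
                f"with sample_class={self.sample_class!r}"
            )
        if self.ega_weeks is not None and not (
            math.isfinite(self.ega_weeks) and self.ega_weeks >= 0
        ):
            raise ValidationError("ega_weeks must be finite and >= 0")

    @property
    def is_late_ega(self) -> bool | None:
        """Early/late gestational-age split at 16 weeks (late = >= 16)."""
        if self.ega_weeks is None:
            return None
        return self.ega_weeks >= 16.0


class Taxonomy:
    """Mapping taxon_id -> ranked lineage with genus extraction.

    Lineages are semicolon-separated rank strings, either QIIME-style
    prefixed (``k__Bacteria; ...; g__Lactobacillus; s__``) or plain names in
    domain..species order.  Taxa whose genus cannot be resolved map to the
    ``"unassigned"`` token and are excluded from genus-level screens.
    """

    GENUS_INDEX = 5  # domain, phylum, class, order, family, genus

    def __init__(self, lineages: dict):
        self.lineages = {str(k): str(v) for k, v in lineages.items()}

    def genus(self, taxon_id: str) -> str:
        lineage = self.lineages.get(taxon_id)
        if lineage is None:
            return UNASSIGNED
        parts = [p.strip() for p in lineage.split(";")]
        prefixed = [p[3:].strip() for p in parts if p.lower().startswith("g__")]
        if prefixed:
            return prefixed[0] if prefixed[0] else UNASSIGNED
        if any("__" in p for p in parts):
            return UNASSIGNED
        if len(parts) > self.GENUS_INDEX and parts[self.GENUS_INDEX]:
            return parts[self.GENUS_INDEX]
        return UNASSIGNED

    def genus_map(self, taxon_ids) -> dict:
        return {t: self.genus(t) for t in taxon_ids}


class PhyloTree:
    """Rooted tree with nonnegative branch lengths, leaves labeled by taxon."""

    def __init__(self, tree: TreeNode):
        names = []
        for node in tree.postorder():
            if node.length is None:
                node.length = 0.0
            if not (math.isfinite(node.length) and node.length >= 0):
                raise ValidationError(
                    f"branch length {node.length!r} on node {node.name!r} "
                    "must be finite and >= 0"
                )
            if node.is_tip():
                if node.name is None:
                    raise ValidationError("unlabeled leaf")
                names.append(node.name)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        self.tree = tree
        self.leaf_names = names

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from io import StringIO

        try:
            tree = TreeNode.read(StringIO(newick), convert_underscores=False)
        except Exception as exc:  # skbio raises several parse-error types
            raise ValidationError(f"newick parse error: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        from io import StringIO

        buf = StringIO()
        self.tree.write(buf)
        return buf.getvalue()

    def __repr__(self):
        return f"PhyloTree({len(self.leaf_names)} leaves)"


class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    SYMMETRY_TOL = 1e-12

    def __init__(self, sample_ids, values):
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        n = len(sample_ids)
        if values.shape != (n, n):
            raise ValidationError(f"matrix shape {values.shape} != ({n}, {n})")
        if len(set(sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite distances")
        if np.any(values < 0):
            raise ValidationError("negative distances")
        if np.max(np.abs(values - values.T), initial=0.0) > self.SYMMETRY_TOL:
            raise ValidationError("matrix not symmetric within 1e-12")
        if np.any(np.diag(values) != 0):
            raise ValidationError("nonzero diagonal")
        # store the exactly symmetrized matrix
        self.sample_ids = sample_ids
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair):
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return self.values[i, j]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def __repr__(self):
        return f"DistanceMatrix({self.n_samples} samples)"


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle-threshold replicates for one sample (technical duplicates
    or more); the per-sample Ct used in analysis is their mean."""

    sample_id: str
    replicate_cts: tuple

    def __post_init__(self):
        object.__setattr__(self, "replicate_cts", tuple(float(c) for c in self.replicate_cts))
        if len(self.replicate_cts) < 1:
            raise ValidationError("at least one Ct replicate required")
        if not all(math.isfinite(c) for c in self.replicate_cts):
            raise ValidationError("non-finite Ct replicate")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicate_cts))


@dataclass(frozen=True)
class TaxonTruth:
    role: str  # "contaminant" | "signal"
    target_organs: frozenset = frozenset()
    mean_relative_abundance: float = 0.0

    def __post_init__(self):
        if self.role not in ("contaminant", "signal"):
            raise ValidationError(f"unknown role {self.role!r}")
        if self.role == "contaminant" and self.target_organs:
            raise ValidationError("contaminants have no target organs")
        object.__setattr__(self, "target_organs", frozenset(self.target_organs))


class TruthLabels:
    """Per-taxon ground truth emitted by the synthetic generator."""

    def __init__(self, labels: dict):
        self.labels = {str(k): v for k, v in labels.items()}
        for v in self.labels.values():
            if not isinstance(v, TaxonTruth):
                raise ValidationError("labels must map taxon_id -> TaxonTruth")

    def contaminants(self):
        return [t for t, v in self.labels.items() if v.role == "contaminant"]

    def signal_taxa(self, target_organ=None, exclude_organ=None):
        out = []
        for t, v in self.labels.items():
            if v.role != "signal":
                continue
            if target_organ is not None and target_organ not in v.target_organs:
                continue
            if exclude_organ is not None and exclude_organ in v.target_organs:
                continue
            out.append(t)
        return out

    def __getitem__(self, taxon_id):
        return self.labels[taxon_id]

    def __len__(self):
        return len(self.labels)


@dataclass
class ValidationReport:
    """Cross-consistency report for a dataset; empty iff consistent."""

    samples_without_metadata: list = field(default_factory=list)
    metadata_without_samples: list = field(default_factory=list)
    taxa_missing_from_tree: list = field(default_factory=list)

    @property
    def is_consistent(self) -> bool:
        return not (
            self.samples_without_metadata
            or self.metadata_without_samples
            or self.taxa_missing_from_tree
        )

    def __str__(self):
        if self.is_consistent:
            return "dataset consistent"
        lines = []
        if self.samples_without_metadata:
            lines.append(f"samples without metadata: {self.samples_without_metadata}")
        if self.metadata_without_samples:
            lines.append(f"metadata without table columns: {self.metadata_without_samples}")
        if self.taxa_missing_from_tree:
            lines.append(f"taxa absent from tree: {self.taxa_missing_from_tree}")
        return "; ".join(lines)


def validate_dataset(table: OtuTable, metadata, tree: PhyloTree | None = None) -> ValidationReport:
    """Cross-check a table, its metadata and (optionally) the UniFrac tree.

    Side-effect free and idempotent; downstream stages refuse datasets whose
    report is non-empty.
    """
    meta_ids = {m.sample_id for m in metadata}
    table_ids = set(table.sample_ids)
    report = ValidationReport(
        samples_without_metadata=sorted(table_ids - meta_ids),
        metadata_without_samples=sorted(meta_ids - table_ids),
    )
    if tree is not None:
        leaves = set(tree.leaf_names)
        report.taxa_missing_from_tree = sorted(set(table.taxon_ids) - leaves)
    return report


def metadata_by_id(metadata) -> dict:
    by_id = {}
    for m in metadata:
        if m.sample_id in by_id:
            raise ValidationError(f"duplicate metadata for sample {m.sample_id!r}")
        by_id[m.sample_id] = m
    return by_id
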