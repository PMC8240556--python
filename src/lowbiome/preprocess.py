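"""Count-table filters and the repeated-rarefaction ensemble.

Order is fixed: singletons are removed on the full dataset, then samples
with fewer than ``min_reads`` total reads are dropped, then each surviving
sample is rarefied (subsampled without replacement) to a common depth,
independently ``reps`` times.  Diversity metrics downstream are computed per
rarefaction and averaged across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OtuTable, ValidationError

DEFAULT_MIN_READS = 500
DEFAULT_DEPTH = 1000
DEFAULT_REPS = 10


def _require_integral(table: OtuTable, op: str):
    if not table.is_integral():
        raise ValidationError(f"{op} is defined on integer count tables")


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop taxa whose total count across the entire dataset equals 1."""
    _require_integral(table, "remove_singletons")
    totals = np.round(table.taxon_sums()).astype(np.int64)
    keep = totals != 1
    return OtuTable(
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.sample_ids,
        table.counts[keep, :],
    )


def filter_low_depth(table: OtuTable, min_reads: int = DEFAULT_MIN_READS) -> OtuTable:
    """Drop samples with fewer than ``min_reads`` total reads (boundary kept)."""
    sums = table.sample_sums()
    keep = sums >= min_reads
    return OtuTable(
        table.taxon_ids,
        [s for s, k in zip(table.sample_ids, keep) if k],
        table.counts[:, keep],
    )


def rarefy(table: OtuTable, depth: int = DEFAULT_DEPTH, seed: int | None = None) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped.  The draw is
    multivariate hypergeometric (uniform over read subsets), reproducible
    given ``seed``.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    _require_integral(table, "rarefy")
    rng = np.random.default_rng(seed)
    counts = np.round(table.counts).astype(np.int64)
    sums = counts.sum(axis=0)
    keep = sums >= depth
    out_cols = []
    out_ids = []
    for j in np.flatnonzero(keep):
        out_cols.append(rng.multivariate_hypergeometric(counts[:, j], depth))
        out_ids.append(table.sample_ids[j])
    if out_cols:
        new_counts = np.column_stack(out_cols).astype(float)
    else:
        new_counts = np.zeros((table.n_taxa, 0))
    return OtuTable(table.taxon_ids, out_ids, new_counts)


@dataclass
class RarefactionEnsemble:
    """``reps`` independent rarefactions of one table at a common depth."""

    depth: int
    tables: list
    seeds: list

    def __post_init__(self):
        sample_ids = None
        for t in self.tables:
            if sample_ids is None:
                sample_ids = t.sample_ids
            elif t.sample_ids != sample_ids:
                raise ValidationError("ensemble members must share the sample set")
            sums = t.sample_sums()
            if not np.all(np.round(sums).astype(np.int64) == self.depth):
                raise ValidationError("every rarefied column must sum exactly to depth")

    @property
    def n_reps(self) -> int:
        return len(self.tables)

    @property
    def sample_ids(self) -> list:
        return self.tables[0].sample_ids

    def mean_table(self) -> OtuTable:
        """Element-wise mean of the rarefied tables (real-valued counts)."""
        stacked = np.stack([t.counts for t in self.tables])
        return OtuTable(self.tables[0].taxon_ids, self.sample_ids, stacked.mean(axis=0))


def derive_rep_seeds(seed: int, reps: int) -> list:
    """Per-rep seeds from the master seed via numpy's SeedSequence spawning."""
    children = np.random.SeedSequence(seed).spawn(reps)
    return [int(c.generate_state(1, dtype=np.uint32)[0]) for c in children]


def make_ensemble(
    table: OtuTable,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> RarefactionEnsemble:
    if reps <= 0:
        raise ValidationError("reps must be positive")
    seeds = derive_rep_seeds(0 if seed is None else seed, reps)
    tables = [rarefy(table, depth=depth, seed=s) for s in seeds]
    return RarefactionEnsemble(depth=depth, tables=tables, seeds=seeds)


def preprocess(
    table: OtuTable,
    min_reads: int = DEFAULT_MIN_READS,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> RarefactionEnsemble:
    """The fixed pipeline order: singletons -> depth filter -> ensemble."""
    filtered = filter_low_depth(remove_singletons(table), min_reads=min_reads)
    if filtered.n_samples == 0:
        raise ValidationError("no samples survive the read-depth filter")
    return make_ensemble(filtered, depth=depth, reps=reps, seed=seed)
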