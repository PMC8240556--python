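"""Between-sample dissimilarity, ordination, and the PERMANOVA group test.

Weighted UniFrac follows the branch-weighted formulation: for each branch,
the absolute difference in the fraction of each sample's reads descending
through it, weighted by branch length.  The normalized variant divides by
the abundance-weighted sum of root-to-leaf distances, bounding the value by
1.  Bray-Curtis, classical-scaling PCoA and a seeded permutation PERMANOVA
(with the between-group R-squared of the distance sums of squares) complete
the layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix, OtuTable, PhyloTree, ValidationError


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """d(j,k) = 1 - 2 sum_i min(c_ij, c_ik) / (sum_i c_ij + sum_i c_ik)."""
    if table.n_samples < 2:
        raise ValidationError("bray_curtis needs at least 2 samples")
    if np.any(table.sample_sums() <= 0):
        raise ValidationError("bray_curtis undefined for all-zero samples")
    condensed = pdist(table.counts.T, metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


def _branch_structure(table: OtuTable, tree: PhyloTree):
    """Branch incidence matrix (branches x taxa), lengths, and leaf depths."""
    taxon_index = {t: i for i, t in enumerate(table.taxon_ids)}
    missing = set(table.taxon_ids) - set(tree.leaf_names)
    if missing:
        raise ValidationError(f"taxa missing from tree: {sorted(missing)}")
    rows, lengths = [], []
    n = len(taxon_index)
    # postorder accumulation of descendant-leaf index sets
    leafsets = {}
    for node in tree.tree.postorder():
        if node.is_tip():
            leafsets[id(node)] = (
                [taxon_index[node.name]] if node.name in taxon_index else []
            )
        else:
            acc = []
            for child in node.children:
                acc.extend(leafsets[id(child)])
            leafsets[id(node)] = acc
        if node.parent is not None and leafsets[id(node)]:
            row = np.zeros(n)
            row[leafsets[id(node)]] = 1.0
            rows.append(row)
            lengths.append(node.length)
    incidence = np.array(rows) if rows else np.zeros((0, n))
    lengths = np.asarray(lengths, dtype=float)
    depths = lengths @ incidence  # root-to-leaf distance per taxon
    return incidence, lengths, depths


def weighted_unifrac(table: OtuTable, tree: PhyloTree, normalized: bool = False) -> DistanceMatrix:
    """Pairwise weighted UniFrac over the table's samples.

    raw:        d = sum_branches b * |p_A(branch) - p_B(branch)|
    normalized: raw / sum_leaves depth(leaf) * (p_A(leaf) + p_B(leaf))
    """
    if table.n_samples < 2:
        raise ValidationError("weighted_unifrac needs at least 2 samples")
    p = table.relative_abundance()  # taxa x samples
    incidence, lengths, depths = _branch_structure(table, tree)
    branch_props = incidence @ p  # branches x samples
    weighted = branch_props * lengths[:, None]
    n = table.n_samples
    raw = np.zeros((n, n))
    for j in range(n):
        raw[j, :] = np.abs(weighted - weighted[:, j][:, None]).sum(axis=0)
    if normalized:
        leaf_weight = depths @ p  # per-sample abundance-weighted depth
        denom = leaf_weight[:, None] + leaf_weight[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(denom > 0, raw / denom, 0.0)
    np.fill_diagonal(raw, 0.0)
    raw = (raw + raw.T) / 2.0  # absorb float asymmetry
    return DistanceMatrix(table.sample_ids, raw)


def average_distance_matrices(matrices) -> DistanceMatrix:
    """Element-wise mean of matrices sharing one sample set and order."""
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("no matrices to average")
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ids:
            raise ValidationError("mismatched sample sets across matrices")
    return DistanceMatrix(ids, np.mean([m.values for m in matrices], axis=0))


@dataclass
class PcoaResult:
    sample_ids: list
    coordinates: np.ndarray  # samples x axes, positive-eigenvalue axes only
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling: eigendecomposition of the double-centered -d^2/2.

    Coordinates come from positive eigenvalues only; negative eigenvalues
    (non-Euclidean input) are reported but carry no coordinates, and the
    proportion explained is over the positive eigenvalues.
    """
    if n_axes is not None and n_axes < 1:
        raise ValidationError("n_axes must be >= 1")
    n = dm.n_samples
    if n < 2:
        raise ValidationError("pcoa needs at least 2 samples")
    d2 = dm.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    props = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        props = props[:n_axes]
    return PcoaResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=props,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    permutations: int


def _ss_within_batch(d2: np.ndarray, label_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """Within-group sum of squared distances for a batch of labelings.

    label_matrix is (batch x n) integer-coded; uses the identity
    SS_within(g) = (z_g' D2 z_g) / (2 n_g) with z_g the group indicator.
    """
    batch = label_matrix.shape[0]
    ssw = np.zeros(batch)
    for g in range(n_groups):
        m = (label_matrix == g).astype(float)
        n_g = m.sum(axis=1)
        quad = np.einsum("bi,ij,bj->b", m, d2, m) / 2.0
        ssw += np.where(n_g > 0, quad / np.maximum(n_g, 1.0), 0.0)
    return ssw


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, n_groups: int):
    """(pseudo-F, R2) for one integer-coded labeling on squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = float(_ss_within_batch(d2, labels[None, :], n_groups)[0])
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        f = np.inf
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    grouping: dict,
    permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with a seeded label-permutation p value.

    p = (1 + #{permuted F >= observed F}) / (permutations + 1); ties count
    as exceedances.  R2 is the between-group fraction of the total sum of
    squared distances and is permutation-free.
    """
    try:
        labels_raw = [grouping[s] for s in dm.sample_ids]
    except KeyError as exc:
        raise ValidationError(f"unlabeled sample: {exc.args[0]!r}") from exc
    uniq = sorted(set(labels_raw))
    if len(uniq) < 2:
        raise ValidationError("permanova needs at least 2 groups")
    code = {g: i for i, g in enumerate(uniq)}
    labels = np.array([code[g] for g in labels_raw])
    d2 = dm.values**2
    k = len(uniq)
    n = len(labels)
    f_obs, r2 = _permanova_stats(d2, labels, k)
    rng = np.random.default_rng(seed)
    perm_labels = np.array([rng.permutation(labels) for _ in range(permutations)])
    ssw = _ss_within_batch(d2, perm_labels, k)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ssw) / (k - 1)) / np.where(ssw > 0, ssw / (n - k), np.nan)
    f_perm = np.where(np.isnan(f_perm), np.inf, f_perm)
    exceed = int(np.sum(f_perm >= f_obs))
    p = (1 + exceed) / (permutations + 1)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p_value=float(p), permutations=permutations)
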