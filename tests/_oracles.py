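"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, exact rational arithmetic — and shares no code path with the
package implementations it checks.
"""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np


# ---------------------------------------------------------------- alpha

def shannon_oracle(counts, base=2.0):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p, base)
    return h


def chao1_oracle(counts):
    s_obs = sum(1 for c in counts if c > 0)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


# ----------------------------------------------------------------- beta

def bray_curtis_oracle(x, y):
    num = sum(min(a, b) for a, b in zip(x, y))
    den = sum(x) + sum(y)
    return 1.0 - 2.0 * num / den


def _collect_branches(tree, taxon_index):
    """(leaf-index set, length) per non-root branch, by recursive descent."""
    branches = []

    def descend(node):
        if node.is_tip():
            leaves = {taxon_index[node.name]} if node.name in taxon_index else set()
        else:
            leaves = set()
            for child in node.children:
                leaves |= descend(child)
        if node.parent is not None:
            branches.append((leaves, node.length))
        return leaves

    descend(tree)
    return branches


def weighted_unifrac_oracle(counts_a, counts_b, taxon_ids, skbio_tree, normalized=False):
    """Branch-by-branch accumulation for one sample pair."""
    taxon_index = {t: i for i, t in enumerate(taxon_ids)}
    pa = np.asarray(counts_a, float) / sum(counts_a)
    pb = np.asarray(counts_b, float) / sum(counts_b)
    raw = 0.0
    for leaves, length in _collect_branches(skbio_tree, taxon_index):
        wa = sum(pa[i] for i in leaves)
        wb = sum(pb[i] for i in leaves)
        raw += length * abs(wa - wb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in skbio_tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length
            node = node.parent
        i = taxon_index.get(tip.name)
        if i is not None:
            denom += depth * (pa[i] + pb[i])
    return raw / denom if denom > 0 else 0.0


def pcoa_gram_oracle(distances):
    """Double-centered Gram matrix by explicit loops, plus its eigenvalues."""
    d = np.asarray(distances, float)
    n = d.shape[0]
    d2 = d**2
    row = d2.mean(axis=1)
    grand = d2.mean()
    b = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            b[i, j] = -0.5 * (d2[i, j] - row[i] - row[j] + grand)
    eigvals = np.sort(np.linalg.eigvalsh(b))[::-1]
    return b, eigvals


def permanova_oracle(distances, labels):
    """(pseudo-F, R2) by direct double loops over pairs."""
    d = np.asarray(distances, float)
    n = d.shape[0]
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        acc = 0.0
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                acc += d[i, j] ** 2
        ss_within += acc / len(idx)
    k = len(groups)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, 1.0 - ss_within / ss_total


def permanova_exhaustive_p(distances, labels):
    """Exact permutation p over all distinct label orderings."""
    f_obs, _ = permanova_oracle(distances, labels)
    count = 0
    total = 0
    for perm in set(itertools.permutations(labels)):
        f, _ = permanova_oracle(distances, list(perm))
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return Fraction(count, total)


# ---------------------------------------------------------------- stats

def mann_whitney_enum(x, y):
    """Exact two-sided p: 2*min tail of the exhaustive U distribution."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = rankdata(pooled)

    def ustat(idx):
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    obs = ustat(range(n1))
    us = [ustat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    le = sum(1 for u in us if u <= obs + 1e-12)
    ge = sum(1 for u in us if u >= obs - 1e-12)
    return min(Fraction(1), Fraction(2 * min(le, ge), len(us)))


def signed_rank_enum(differences):
    """Exact two-sided p over all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(differences, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    le = sum(1 for w in ws if w <= obs + 1e-12)
    ge = sum(1 for w in ws if w >= obs - 1e-12)
    return min(Fraction(1), Fraction(2 * min(le, ge), len(ws)))


def fisher_enum(table):
    """Exact two-sided p by the probability-mass rule, in rationals."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return None
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(min(r1, c1) + 1):
        p = prob(k)
        if p is not None and p <= p_obs:
            total += p
    return total


def percentile_oracle(values, q):
    v = sorted(values)
    h = (len(v) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
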