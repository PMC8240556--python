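"""Within-sample diversity: Shannon entropy and the Chao1 richness estimate.

Shannon defaults to log base 2 and Chao1 to its bias-corrected form (both
QIIME 1.x conventions).  Ensemble values are the arithmetic mean of the
metric over rarefaction replicates, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .preprocess import RarefactionEnsemble


def shannon(counts, base: float = 2.0) -> float:
    """H = -sum p_i log_base p_i over positive entries."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValidationError("shannon undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)) (bias-corrected form).

    The classic form S_obs + F1^2/(2 F2) is available with
    ``bias_corrected=False`` (undefined at F2=0, where it falls back to the
    bias-corrected expression).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(np.abs(c - np.round(c)) > 1e-9):
        raise ValidationError("chao1 requires integer counts")
    c = np.round(c).astype(np.int64)
    if np.any(c < 0):
        raise ValidationError("negative counts")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


@dataclass
class AlphaTable:
    """Per-sample metric values, averaged over the rarefaction ensemble."""

    metric: str
    values: dict  # sample_id -> mean metric value
    reps_averaged: int = 1

    def __post_init__(self):
        for s, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"non-finite or negative alpha value for {s!r}")

    def __getitem__(self, sample_id):
        return self.values[sample_id]


_METRICS = {"shannon": shannon, "chao1": chao1}


def alpha_over_ensemble(ensemble: RarefactionEnsemble, metric: str = "shannon", **kwargs) -> AlphaTable:
    """Compute the metric on each rarefaction rep and average per sample."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    sample_ids = ensemble.sample_ids
    acc = np.zeros(len(sample_ids))
    for t in ensemble.tables:
        if t.sample_ids != sample_ids:
            raise ValidationError("sample retention differs across ensemble reps")
        acc += np.array([fn(t.counts[:, j], **kwargs) for j in range(t.n_samples)])
    acc /= ensemble.n_reps
    return AlphaTable(metric=metric, values=dict(zip(sample_ids, acc)), reps_averaged=ensemble.n_reps)
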