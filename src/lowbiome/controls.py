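"""Contamination-aware inference against the negative-control design.

Three layers: (1) exceedance testing — is a sample class's alpha diversity
above the PBS-control 95th percentile more often than PBS itself (Fisher
exact per class); (2) matched-control beta diversity — each tissue's mean
distance to its fetus-matched PBS blanks, optionally normalized within
fetus so organs can be compared on a common scale; (3) qPCR Ct summaries,
where a lower cycle threshold means more amplifiable bacterial DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alpha import AlphaTable
from .core import DistanceMatrix, ValidationError, metadata_by_id
from .stats import TestResult, fisher_exact_2x2, mann_whitney_u, percentile, signed_rank_paired

logger = logging.getLogger(__name__)


@dataclass
class ExceedanceReport:
    threshold: float
    q: float
    above: dict  # sample_id -> bool (strictly above threshold)
    class_tables: dict  # sample_class -> 2x2 [[above, below], [pbs_above, pbs_below]]
    class_pvalues: dict  # sample_class -> TestResult


def exceedance_test(alpha: AlphaTable, metadata, q: float = 95.0) -> ExceedanceReport:
    """Classify every sample against the PBS alpha-diversity percentile.

    The threshold is the q-th percentile of PBS values; "above" is strict
    (boundary samples count as below).  Each non-PBS class gets a Fisher
    exact test of its above/below split against the PBS split.
    """
    by_id = metadata_by_id(metadata)
    pbs_values = [
        v for s, v in alpha.values.items()
        if s in by_id and by_id[s].sample_class == "pbs"
    ]
    if len(pbs_values) < 2:
        raise ValidationError("exceedance_test needs >= 2 PBS samples with alpha values")
    threshold = percentile(pbs_values, q)
    above = {s: v > threshold for s, v in alpha.values.items() if s in by_id}
    pbs_above = sum(1 for s, a in above.items() if a and by_id[s].sample_class == "pbs")
    pbs_below = sum(1 for s, a in above.items() if not a and by_id[s].sample_class == "pbs")
    tables, pvals = {}, {}
    classes = sorted({by_id[s].sample_class for s in above} - {"pbs"})
    for cls in classes:
        c_above = sum(1 for s, a in above.items() if a and by_id[s].sample_class == cls)
        c_below = sum(1 for s, a in above.items() if not a and by_id[s].sample_class == cls)
        table = np.array([[c_above, c_below], [pbs_above, pbs_below]])
        tables[cls] = table
        pvals[cls] = fisher_exact_2x2(table)
    return ExceedanceReport(
        threshold=threshold, q=q, above=above, class_tables=tables, class_pvalues=pvals
    )


@dataclass(frozen=True)
class MatchedRecord:
    sample_id: str
    fetus_id: str
    organ: str
    distance: float


@dataclass
class MatchedDistanceSet:
    records: list  # of MatchedRecord
    pbs_reference: list = field(default_factory=list)  # all PBS-to-PBS distances
    normalized: bool = False

    def by_organ(self) -> dict:
        out = {}
        for r in self.records:
            out.setdefault(r.organ, []).append(r)
        return out

    def by_fetus(self) -> dict:
        out = {}
        for r in self.records:
            out.setdefault(r.fetus_id, []).append(r)
        return out


def matched_control_distances(dm: DistanceMatrix, metadata) -> MatchedDistanceSet:
    """Per tissue sample, mean distance to its fetus-matched PBS blanks.

    The reference set is every pairwise distance among PBS samples.  Tissues
    without a matched PBS are excluded with a warning.
    """
    by_id = metadata_by_id(metadata)
    in_dm = [s for s in dm.sample_ids if s in by_id]
    pbs = [s for s in in_dm if by_id[s].sample_class == "pbs"]
    tissues = [s for s in in_dm if by_id[s].sample_class == "fetal_tissue"]
    pbs_by_fetus = {}
    for s in pbs:
        if by_id[s].fetus_id is not None:
            pbs_by_fetus.setdefault(by_id[s].fetus_id, []).append(s)
    records = []
    for s in tissues:
        fid = by_id[s].fetus_id
        matched = pbs_by_fetus.get(fid, [])
        if not matched:
            logger.warning("tissue sample %r has no fetus-matched PBS; excluded", s)
            continue
        d = float(np.mean([dm[s, m] for m in matched]))
        records.append(MatchedRecord(sample_id=s, fetus_id=fid, organ=by_id[s].organ, distance=d))
    reference = [dm[a, b] for i, a in enumerate(pbs) for b in pbs[i + 1:]]
    return MatchedDistanceSet(records=records, pbs_reference=reference, normalized=False)


def normalize_within_fetus(mds: MatchedDistanceSet, min_tissues: int = 2) -> MatchedDistanceSet:
    """Divide each record by its fetus's mean record value.

    Restricted to fetuses contributing at least ``min_tissues`` tissue
    records; after normalization the per-fetus mean is exactly 1.
    """
    out = []
    for fid, recs in mds.by_fetus().items():
        if len(recs) < min_tissues:
            logger.warning("fetus %r has < %d tissue records; excluded", fid, min_tissues)
            continue
        mean = float(np.mean([r.distance for r in recs]))
        if mean == 0:
            raise ValidationError(f"fetus {fid!r} has zero mean matched distance")
        for r in recs:
            out.append(MatchedRecord(r.sample_id, r.fetus_id, r.organ, r.distance / mean))
    return MatchedDistanceSet(records=out, pbs_reference=list(mds.pbs_reference), normalized=True)


def compare_tissue_vs_reference(mds: MatchedDistanceSet, paired: bool = False) -> dict:
    """Per-organ tests of matched-control distances.

    Unpaired: organ tissue-to-PBS distances vs the PBS-to-PBS reference
    (Mann-Whitney U).  Paired: within-fetus normalized values vs 1
    (signed rank) — meaningful on a normalized set.
    """
    results = {}
    for organ, recs in sorted(mds.by_organ().items()):
        values = [r.distance for r in recs]
        if paired:
            if len(values) < 2:
                logger.warning("organ %r has < 2 records in paired mode; skipped", organ)
                continue
            diffs = np.asarray(values) - 1.0
            if np.all(diffs == 0):
                logger.warning("organ %r identical to within-fetus mean; skipped", organ)
                continue
            results[organ] = signed_rank_paired(diffs)
        else:
            if not mds.pbs_reference:
                raise ValidationError("no PBS-to-PBS reference distances")
            results[organ] = mann_whitney_u(values, mds.pbs_reference)
    return results


@dataclass
class CtSummary:
    mean_ct: dict  # sample_id -> mean of replicates
    class_vs_pbs: dict  # sample_class or organ -> TestResult vs PBS
    organ_vs_internal: dict  # organ -> TestResult vs internal-control organ
    internal_control: str = "thymus"


def summarize_ct(records, metadata, internal_control: str = "thymus") -> CtSummary:
    """Average Ct replicates per sample and compare groups.

    Each tissue organ (and each non-PBS control class) is compared with the
    PBS blanks, and each organ with the internal-control organ, by
    Mann-Whitney U on the per-sample mean Ct.  Lower Ct = more template DNA.
    """
    by_id = metadata_by_id(metadata)
    mean_ct = {r.sample_id: r.mean_ct for r in records if r.sample_id in by_id}

    def group(pred):
        return [v for s, v in mean_ct.items() if pred(by_id[s])]

    pbs = group(lambda m: m.sample_class == "pbs")
    internal = group(lambda m: m.organ == internal_control)
    organs = sorted({by_id[s].organ for s in mean_ct if by_id[s].organ != "none"})
    classes = sorted({by_id[s].sample_class for s in mean_ct} - {"pbs", "fetal_tissue"})
    class_vs_pbs, organ_vs_internal = {}, {}
    for organ in organs:
        vals = group(lambda m, o=organ: m.organ == o)
        if vals and pbs:
            class_vs_pbs[organ] = mann_whitney_u(vals, pbs)
        if vals and internal and organ != internal_control:
            organ_vs_internal[organ] = mann_whitney_u(vals, internal)
    for cls in classes:
        vals = group(lambda m, c=cls: m.sample_class == c)
        if vals and pbs:
            class_vs_pbs[cls] = mann_whitney_u(vals, pbs)
    return CtSummary(
        mean_ct=mean_ct,
        class_vs_pbs=class_vs_pbs,
        organ_vs_internal=organ_vs_internal,
        internal_control=internal_control,
    )
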