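"""Synthetic low-biomass 16S datasets with known contamination structure.

The generator emulates the contamination-control design of a fetal-tissue
microbiome study: a reagent "kitome" of contaminant taxa whose expected
relative abundance is identical in every sample — tissues and all negative
controls alike — plus organ-restricted signal taxa whose abundance follows
a surface-to-internal exposure gradient (skin/placenta high, thymus/spleen
low).  Each fetus contributes one sample per organ and matched PBS blanks;
reagent and environment controls carry kitome only.  Counts are
Dirichlet-multinomial at a per-sample depth drawn log-normally, and truth
labels record each taxon's role and target organs for recovery testing.

All randomness flows from a single master seed through named substreams,
so a config generates byte-identical data every time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .core import (
    CtRecord,
    OtuTable,
    PhyloTree,
    SampleRecord,
    TaxonTruth,
    Taxonomy,
    TruthLabels,
    ValidationError,
)

# surface-exposure ranks: 1 = most exposed
ORGAN_RANKS = {
    "skin": 1,
    "placenta": 1,
    "gut": 2,
    "lung": 2,
    "liver": 3,
    "mln": 3,
    "thymus": 4,
    "spleen": 4,
}

DEFAULT_ORGANS = ("skin", "placenta", "gut", "lung", "thymus", "spleen")


@dataclass
class SimConfig:
    """Study-condition knobs; defaults mirror the emulated design.

    ``signal_scale`` is the unnormalized compositional mass a signal taxon
    adds at exposure rank 1; each extra rank multiplies it by
    ``exposure_decay``.  ``signal_reaches`` assigns each signal taxon the
    deepest rank it colonizes (reach 1 = surface organs only, reach 4 =
    every organ), giving internal organs a small but nonzero signal load.
    ``dirichlet_concentration`` controls compositional overdispersion
    (larger = milder noise around the expected composition).
    """

    n_fetuses: int = 8
    organs: tuple = DEFAULT_ORGANS
    n_pbs_per_fetus: int = 2
    n_reagent: int = 3
    n_environment: int = 3
    n_contaminant_taxa: int = 10
    n_signal_taxa: int = 12
    contaminant_lognormal_sd: float = 0.5
    signal_scale: float = 0.16
    exposure_decay: float = 0.6
    signal_reaches: tuple = (1, 1, 1, 1, 2, 2, 2, 2, 4, 4, 4, 4)
    cross_contamination: float = 0.0
    dirichlet_concentration: float = 2000.0
    depth_log10_mean: float = 4.0
    depth_log10_sd: float = 0.15
    ega_weeks_range: tuple = (12.0, 22.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_fetuses < 1 or self.n_contaminant_taxa < 1:
            raise ValidationError("need >= 1 fetus and >= 1 contaminant taxon")
        if self.n_signal_taxa < 0 or self.cross_contamination < 0:
            raise ValidationError("counts and rates must be >= 0")
        if not (0 < self.exposure_decay <= 1):
            raise ValidationError("exposure_decay must lie in (0, 1]")
        if self.signal_scale < 0 or self.dirichlet_concentration <= 0:
            raise ValidationError("scales must be positive")
        for o in self.organs:
            if o not in ORGAN_RANKS:
                raise ValidationError(f"unknown organ {o!r}")
        if self.n_signal_taxa > 0 and len(self.signal_reaches) != self.n_signal_taxa:
            raise ValidationError("signal_reaches must have one entry per signal taxon")


def _substream(seed: int, name: str) -> np.random.Generator:
    token = int.from_bytes(name.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(token,)))


def generate_tree(taxon_ids, seed: int = 0) -> PhyloTree:
    """Random rooted bifurcating tree with exponential branch lengths."""
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValidationError("a tree needs >= 2 taxa")
    rng = _substream(seed, "tree")
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1))) for t in taxon_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]], length=float(rng.exponential(0.1)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes, length=0.0)
    return PhyloTree(root)


_GENUS_POOL = (
    "Micrococcus", "Ralstonia", "Bradyrhizobium", "Sphingomonas", "Cutibacterium",
    "Methylobacterium", "Burkholderia", "Pelomonas", "Acinetobacter", "Delftia",
    "Lactobacillus", "Staphylococcus", "Streptococcus", "Enterococcus",
    "Bifidobacterium", "Prevotella", "Finegoldia", "Bacteroides", "Veillonella",
    "Corynebacterium", "Escherichia", "Klebsiella", "Fusobacterium", "Gardnerella",
)


def _expected_compositions(config: SimConfig, reaches, scales):
    """Unnormalized expected mass per taxon for each organ and for controls."""
    n_c, n_s = config.n_contaminant_taxa, config.n_signal_taxa
    base = np.zeros(n_c + n_s)
    comps = {}
    for organ in config.organs:
        rank = ORGAN_RANKS[organ]
        mass = base.copy()
        for k in range(n_s):
            if rank <= reaches[k]:
                mass[n_c + k] = scales[k] * config.exposure_decay ** (rank - 1)
            elif config.cross_contamination > 0:
                mass[n_c + k] = config.cross_contamination * scales[k]
        comps[organ] = mass
    comps["control"] = base.copy()
    if config.cross_contamination > 0:
        comps["control"][n_c:] = config.cross_contamination * np.asarray(scales)
    return comps


def generate_dataset(config: SimConfig):
    """Returns (OtuTable, metadata, Taxonomy, PhyloTree, TruthLabels)."""
    n_c, n_s = config.n_contaminant_taxa, config.n_signal_taxa
    taxon_ids = [f"OTU{i + 1:03d}" for i in range(n_c + n_s)]

    comp_rng = _substream(config.seed, "composition")
    contaminant_shares = comp_rng.lognormal(0.0, config.contaminant_lognormal_sd, size=n_c)
    contaminant_shares /= contaminant_shares.sum()
    reaches = list(config.signal_reaches[:n_s])
    if n_s > 0:
        comp_rng.shuffle(reaches)
    scales = [config.signal_scale] * n_s

    comps = _expected_compositions(config, reaches, scales)

    # sample frame
    meta, columns = [], []
    for f in range(config.n_fetuses):
        fid = f"F{f + 1:02d}"
        ega = float(
            _substream(config.seed, f"ega-{fid}").uniform(*config.ega_weeks_range)
        )
        for organ in config.organs:
            sid = f"{fid}-{organ}"
            meta.append(
                SampleRecord(sid, "fetal_tissue", organ=organ, fetus_id=fid, ega_weeks=ega)
            )
            columns.append((sid, organ))
        for p in range(config.n_pbs_per_fetus):
            sid = f"{fid}-pbs{p + 1}"
            meta.append(SampleRecord(sid, "pbs", fetus_id=fid, ega_weeks=ega))
            columns.append((sid, "control"))
    for i in range(config.n_reagent):
        sid = f"reagent{i + 1}"
        meta.append(SampleRecord(sid, "reagent"))
        columns.append((sid, "control"))
    for i in range(config.n_environment):
        sid = f"env{i + 1}"
        meta.append(SampleRecord(sid, "environment"))
        columns.append((sid, "control"))

    count_rng = _substream(config.seed, "counts")
    depth_rng = _substream(config.seed, "depths")
    counts = np.zeros((n_c + n_s, len(columns)))
    for j, (sid, comp_key) in enumerate(columns):
        mass = comps[comp_key].copy()
        mass[:n_c] = contaminant_shares  # kitome identical everywhere
        expected = mass / mass.sum()
        alpha = expected * config.dirichlet_concentration
        positive = alpha > 0
        p = np.zeros_like(expected)
        p[positive] = count_rng.dirichlet(alpha[positive])
        depth = int(round(10 ** depth_rng.normal(config.depth_log10_mean, config.depth_log10_sd)))
        counts[:, j] = count_rng.multinomial(depth, p)

    table = OtuTable(taxon_ids, [c[0] for c in columns], counts)

    lineages = {}
    for i, t in enumerate(taxon_ids):
        genus = _GENUS_POOL[i % len(_GENUS_POOL)]
        lineages[t] = (
            f"k__Bacteria; p__P{i}; c__C{i}; o__O{i}; f__F{i}; g__{genus}"
            if i < len(_GENUS_POOL)
            else f"k__Bacteria; p__P{i}; c__C{i}; o__O{i}; f__F{i}; g__Genus{i}"
        )
    taxonomy = Taxonomy(lineages)

    tree = generate_tree(taxon_ids, seed=config.seed)

    # expected mean relative abundance across the whole sample frame
    mean_share = np.zeros(n_c + n_s)
    for _, comp_key in columns:
        mass = comps[comp_key].copy()
        mass[:n_c] = contaminant_shares
        mean_share += mass / mass.sum()
    mean_share /= len(columns)
    labels = {}
    for i, t in enumerate(taxon_ids):
        if i < n_c:
            labels[t] = TaxonTruth("contaminant", mean_relative_abundance=float(mean_share[i]))
        else:
            k = i - n_c
            targets = frozenset(
                o for o in config.organs if ORGAN_RANKS[o] <= reaches[k]
            )
            labels[t] = TaxonTruth(
                "signal", target_organs=targets, mean_relative_abundance=float(mean_share[i])
            )
    return table, meta, taxonomy, tree, TruthLabels(labels)


@dataclass
class CtModel:
    """Ct = baseline - slope * log10(load) + noise, duplicated replicates."""

    baseline: float = 34.0
    slope: float = 3.32  # cycles per 10-fold template change
    sample_noise_sd: float = 0.5
    replicate_noise_sd: float = 0.2
    n_replicates: int = 2


def generate_ct_records(metadata, truth: TruthLabels, config: SimConfig, model: CtModel = None):
    """qPCR records whose load tracks each sample's planted signal mass."""
    model = model or CtModel()
    n_c = config.n_contaminant_taxa
    reach_by_taxon = {
        t: truth[t].target_organs for t in truth.labels if truth[t].role == "signal"
    }
    rng = _substream(config.seed, "ct")
    records = []
    for m in metadata:
        signal_mass = 0.0
        if m.sample_class == "fetal_tissue":
            rank = ORGAN_RANKS[m.organ]
            for t, organs in reach_by_taxon.items():
                if m.organ in organs:
                    signal_mass += config.signal_scale * config.exposure_decay ** (rank - 1)
        load = 1.0 + signal_mass
        center = model.baseline - model.slope * np.log10(load) + rng.normal(0, model.sample_noise_sd)
        reps = center + rng.normal(0, model.replicate_noise_sd, size=model.n_replicates)
        records.append(CtRecord(sample_id=m.sample_id, replicate_cts=tuple(float(c) for c in reps)))
    return records


def null_config(seed: int = 0, **kwargs) -> SimConfig:
    """A no-signal configuration: every sample is pure kitome."""
    kwargs.setdefault("n_signal_taxa", 0)
    kwargs.setdefault("signal_reaches", ())
    return SimConfig(seed=seed, **kwargs)
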