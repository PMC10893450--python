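"""End-to-end convenience drivers tying the modules together.

These run the full inference path on an in-memory dataset: paralog-pair
Ks distributions with node weighting, mixture-model peak detection, and
gene-tree reconciliation with WGD calling.  They exist so that a planted
simulation can be pushed through exactly the code a user would run on
real CDS collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import kaks, peaks
from .reconcile import (
    GeneTree, ReconciliationSummary, SpeciesTree, TreeNode,
    build_nj_gene_tree, call_wgd, root_gene_tree,
    reconcile as reconcile_gene_tree, summarize_gd,
)
from .simulate import SyntheticDataset

log = logging.getLogger(__name__)

__all__ = ["intraspecific_ks", "interspecific_ks", "reconcile_dataset",
           "WGDInference", "infer_wgd"]


def _estimate_pairs(collection_lookup, pairs):
    """(family, a, b) or (a, b) tuples -> {(a, b): KaKsEstimate}."""
    estimates = {}
    for key in pairs:
        a, b = key[-2:]
        aln = kaks.align_codon_pair(collection_lookup[a], collection_lookup[b],
                                    gene_a=a, gene_b=b)
        estimates[(a, b)] = kaks.ng86(aln)
    return estimates


def intraspecific_ks(
    collection: dict,
    families: dict,
    species: str = "",
    ks_min: float = 0.1,
    ks_max: float = 5.0,
) -> tuple[kaks.KsDistribution, dict]:
    """Weighted intraspecific paralog Ks distribution for one species.

    Returns (distribution, estimates) so callers can reuse the per-pair
    Ka/Ks values (e.g. for the positive-selection screen)."""
    pairs = kaks.paralog_pairs(collection, families)
    estimates = _estimate_pairs(collection, pairs)
    ks_map = {k: est.Ks for k, est in estimates.items()}
    weights = kaks.weight_pairs_by_event(pairs, ks_map)
    dist = kaks.build_ks_distribution(
        pairs, estimates, weights, label=species or "intra",
        mode="intraspecific", ks_min=ks_min, ks_max=ks_max,
    )
    return dist, estimates


def interspecific_ks(
    collection_a: dict,
    collection_b: dict,
    label: str = "",
    scores: dict | None = None,
    ks_min: float = 0.1,
    ks_max: float = 5.0,
) -> tuple[kaks.KsDistribution, dict]:
    """Ortholog (reciprocal-best-hit) Ks distribution between two species."""
    pairs = kaks.ortholog_pairs(collection_a, collection_b, scores)
    lookup = dict(collection_a)
    lookup.update(collection_b)
    estimates = _estimate_pairs(lookup, pairs)
    dist = kaks.build_ks_distribution(
        pairs, estimates, None, label=label, mode="interspecific",
        ks_min=ks_min, ks_max=ks_max,
    )
    return dist, estimates


def reconcile_dataset(
    dataset: SyntheticDataset,
    species_tree: SpeciesTree,
    support_threshold: float = 50.0,
) -> tuple[list, int]:
    """Build, root and reconcile a gene tree for every family; 2-gene
    families are handled as trivially rooted cherries.  Returns
    (all GD events, number of families reconciled)."""
    all_genes: dict[str, str] = {}
    for genes in dataset.collections.values():
        all_genes.update(genes)
    by_family: dict[str, dict] = {}
    for gene, fam in dataset.families.items():
        by_family.setdefault(fam, {})[gene] = all_genes[gene]

    events = []
    n_families = 0
    for fam in sorted(by_family):
        fam_cds = by_family[fam]
        n_families += 1
        if len(fam_cds) < 2:
            continue
        if len(fam_cds) == 2:
            a, b = sorted(fam_cds)
            root = TreeNode()
            root.add(TreeNode(name=a))
            root.add(TreeNode(name=b))
            gtree = GeneTree(root=root, rooted=True)
        else:
            gtree = build_nj_gene_tree(fam_cds)
            gtree = root_gene_tree(gtree, species_tree)
        events.extend(
            reconcile_gene_tree(gtree, species_tree,
                                support_threshold=support_threshold, family=fam)
        )
    return events, n_families


@dataclass
class WGDInference:
    ks_distribution: kaks.KsDistribution
    model: peaks.MixtureModel
    peaks: list
    summary: ReconciliationSummary
    flagged_nodes: list = field(default_factory=list)


def infer_wgd(
    dataset: SyntheticDataset,
    species_tree_newick: str,
    focal_species: str,
    k_max: int = 4,
    n_restarts: int = 3,
    seed: int = 0,
    min_weight: float = 0.1,
    criteria: str = "scaled",
) -> WGDInference:
    """Full WGD inference on a dataset: intraspecific Ks peaks for the
    focal species plus tree-based duplication mapping and WGD calls."""
    stree = SpeciesTree(species_tree_newick)
    dist, _ = intraspecific_ks(
        dataset.collections[focal_species], dataset.families, species=focal_species
    )
    models = peaks.fit_gmm(dist, k_max=k_max, n_restarts=n_restarts, seed=seed)
    model = peaks.select_model(models)
    found = peaks.extract_peaks(model, min_weight=min_weight, source=focal_species)

    events, n_families = reconcile_dataset(dataset, stree)
    summary = summarize_gd(events, n_families, stree)
    summary = call_wgd(summary, criteria=criteria)
    flagged = sorted(summary.table.index[summary.table["wgd_flag"]])
    return WGDInference(dist, model, found, summary, flagged)
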