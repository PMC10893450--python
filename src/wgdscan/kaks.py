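"""Codon-level pairwise alignment, NG86 Ka/Ks estimation, pair selection
and Ks-age distributions.

The estimator is Nei–Gojobori (1986) site counting with the Jukes–Cantor
multiple-hit correction d = -(3/4) ln(1 - (4/3) p).  Sites are counted per
codon by enumerating the three alternatives at every position; alternatives
creating stop codons are excluded with the position's fractions
renormalised, and multi-difference codons are averaged over all stop-free
substitution orders (columns with no stop-free pathway are excluded from
both site and difference totals).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from . import codons as ct

log = logging.getLogger(__name__)

__all__ = [
    "AlignedCodonPair",
    "KaKsEstimate",
    "KsDistribution",
    "align_codon_pair",
    "ng86",
    "paralog_pairs",
    "weight_pairs_by_event",
    "ortholog_pairs",
    "build_ks_distribution",
]


@dataclass
class AlignedCodonPair:
    """A codon-resolved pairwise alignment: ``codons_a[i]``/``codons_b[i]``
    hold a codon string or ``None`` for a gap at column ``i``."""

    gene_a: str
    gene_b: str
    codons_a: list
    codons_b: list

    @property
    def n_ungapped_codons(self) -> int:
        return sum(
            1 for a, b in zip(self.codons_a, self.codons_b) if a is not None and b is not None
        )


@dataclass
class KaKsEstimate:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    ka_ks: float | None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.Ks is not None and self.Ka is not None


@dataclass
class KsDistribution:
    """Weighted Ks ages for one species (``intraspecific``) or one species
    pair (``interspecific``), after the retention filter."""

    label: str
    mode: str                       # "intraspecific" | "interspecific"
    entries: list = field(default_factory=list)   # (pair id, ks, weight)
    dropped: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)

    @property
    def n_eff(self) -> float:
        return float(self.weights.sum()) if self.entries else 0.0


def _validated_indices(cds: str, gene: str) -> list[int]:
    try:
        return ct.codon_indices(cds)
    except ValueError as exc:
        raise ValueError(f"{gene}: {exc}") from None


def align_codon_pair(
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignedCodonPair:
    """Globally align the two proteins (affine gaps) and map the alignment
    back onto codons.  Ties are broken deterministically by taking the
    aligner's first reported optimal alignment."""
    idx_a = _validated_indices(cds_a, gene_a)
    idx_b = _validated_indices(cds_b, gene_b)
    prot_a = ct.translate_indices(idx_a)
    prot_b = ct.translate_indices(idx_b)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(prot_a, prot_b)[0]

    codons_a: list = []
    codons_b: list = []
    pa, pb = 0, 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a == "-":
            codons_a.append(None)
        else:
            codons_a.append(ct.CODONS[idx_a[pa]])
            pa += 1
        if col_b == "-":
            codons_b.append(None)
        else:
            codons_b.append(ct.CODONS[idx_b[pb]])
            pb += 1
    return AlignedCodonPair(gene_a, gene_b, codons_a, codons_b)


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: AlignedCodonPair) -> KaKsEstimate:
    """NG86 counting on the ungapped codon columns of an alignment.

    Saturated (p >= 3/4) or degenerate (S = 0) estimates are returned with
    ``Ks``/``Ka`` set to ``None`` and a reason, never silently dropped.
    """
    S = N = Sd = Nd = 0.0
    n_cols = 0
    for ca, cb in zip(pair.codons_a, pair.codons_b):
        if ca is None or cb is None:
            continue
        ia, ib = ct.CODON_INDEX[ca], ct.CODON_INDEX[cb]
        if not ct.PAIR_OK[ia, ib]:
            continue  # stop codon or no stop-free pathway: column excluded
        n_cols += 1
        S += (ct.SYN_SITES[ia] + ct.SYN_SITES[ib]) / 2.0
        N += (ct.NONSYN_SITES[ia] + ct.NONSYN_SITES[ib]) / 2.0
        Sd += ct.SD[ia, ib]
        Nd += ct.ND[ia, ib]
    if n_cols == 0:
        raise ValueError(f"{pair.gene_a}/{pair.gene_b}: no comparable codon columns")

    est = KaKsEstimate(pair.gene_a, pair.gene_b, S, N, Sd, Nd, None, None, None)
    est.Ks = _jc(Sd / S) if S > 0 else None
    est.Ka = _jc(Nd / N) if N > 0 else None
    if est.Ks is None or est.Ka is None:
        est.undefined_reason = "saturated (p >= 3/4) or no countable sites"
        return est
    if est.Ks > 0:
        est.ka_ks = est.Ka / est.Ks
    elif est.Ka == 0:
        est.ka_ks = None
        est.undefined_reason = "Ka/Ks undefined at zero divergence"
    else:
        est.ka_ks = math.inf
    return est


# ---------------------------------------------------------------------------
# pair selection


def paralog_pairs(collection: dict, families: dict) -> list[tuple[str, str, str]]:
    """All within-species, within-family gene pairs as (family, gene_a,
    gene_b), lexicographically ordered.  Families contributing fewer than
    two genes of the species contribute nothing."""
    missing = [g for g in collection if g not in families]
    if missing:
        raise KeyError(f"genes missing from the family map: {missing[:5]}")
    by_family: dict[str, list[str]] = {}
    for g in sorted(collection):
        by_family.setdefault(families[g], []).append(g)
    pairs = []
    for fam in sorted(by_family):
        genes = by_family[fam]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                pairs.append((fam, genes[i], genes[j]))
    return pairs


def weight_pairs_by_event(pairs: list, ks: dict) -> dict:
    """Node weighting: down-weight redundant pairs so each duplication
    event contributes total weight 1.

    The genes of one family (one species) are single-linkage clustered on
    their pairwise Ks; each of the m - 1 merge nodes distributes weight 1
    equally over the gene pairs it joins.  Pairs with undefined Ks get
    weight 0.  Returns {(gene_a, gene_b): weight}."""
    by_family: dict[str, set] = {}
    for fam, a, b in pairs:
        by_family.setdefault(fam, set()).update((a, b))
    weights: dict[tuple, float] = {}
    for fam in sorted(by_family):
        genes = sorted(by_family[fam])
        m = len(genes)
        usable = all(
            (a, b) in ks and ks[(a, b)] is not None
            for i, a in enumerate(genes)
            for b in genes[i + 1:]
        )
        if m == 2:
            key = (genes[0], genes[1])
            weights[key] = 1.0 if usable else 0.0
            continue
        if not usable:
            # cannot cluster: fall back to equal split of (m - 1) events
            w = (m - 1) / (m * (m - 1) / 2)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    weights[(a, b)] = w if (a, b) in ks and ks[(a, b)] is not None else 0.0
            continue
        cond = [ks[(genes[i], genes[j])] for i in range(m) for j in range(i + 1, m)]
        Z = linkage(np.asarray(cond, dtype=float), method="single")
        clusters: dict[int, list[str]] = {i: [g] for i, g in enumerate(genes)}
        for step, (ia, ib, _, _) in enumerate(Z):
            left, right = clusters[int(ia)], clusters[int(ib)]
            joined = [(a, b) if a < b else (b, a) for a in left for b in right]
            w = 1.0 / len(joined)
            for key in joined:
                weights[key] = weights.get(key, 0.0) + w
            clusters[m + step] = left + right
    return weights


def _kmer_set(protein: str, k: int = 4) -> set:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def _internal_scores(collection_a: dict, collection_b: dict, k: int = 4) -> dict:
    """Shared amino-acid k-mer counts as a light similarity score for
    reciprocal-best-hit pairing (a user-supplied score table bypasses it)."""
    prots_a = {g: _kmer_set(ct.translate_indices(ct.codon_indices(s)), k)
               for g, s in collection_a.items()}
    prots_b = {g: _kmer_set(ct.translate_indices(ct.codon_indices(s)), k)
               for g, s in collection_b.items()}
    scores = {}
    for ga, sa in prots_a.items():
        for gb, sb in prots_b.items():
            c = len(sa & sb)
            if c > 0:
                scores[(ga, gb)] = float(c)
    return scores


def ortholog_pairs(
    collection_a: dict, collection_b: dict, scores: dict | None = None
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two species.

    ``scores`` maps (gene_a, gene_b) -> similarity; when absent an internal
    k-mer scorer is used.  Ties break lexicographically by gene id."""
    if scores is None:
        scores = _internal_scores(collection_a, collection_b)
    if not scores:
        log.warning("empty cross-species score table: no ortholog pairs")
        return []
    best_a: dict[str, tuple] = {}
    best_b: dict[str, tuple] = {}
    for (ga, gb), s in sorted(scores.items()):
        if ga not in best_a or s > best_a[ga][0]:
            best_a[ga] = (s, gb)
        if gb not in best_b or s > best_b[gb][0]:
            best_b[gb] = (s, ga)
    pairs = []
    for ga, (s, gb) in sorted(best_a.items()):
        if best_b.get(gb, (None, None))[1] == ga:
            pairs.append((ga, gb))
    return pairs


def build_ks_distribution(
    pairs: list,
    estimates: dict,
    weights: dict | None = None,
    label: str = "",
    mode: str = "intraspecific",
    ks_min: float = 0.1,
    ks_max: float = 5.0,
) -> KsDistribution:
    """Filter estimates into a weighted Ks distribution.

    The retention interval is closed: Ks values exactly at ``ks_min`` or
    ``ks_max`` are kept.  Undefined and out-of-range estimates are counted
    per reason in ``dropped``."""
    dist = KsDistribution(label=label, mode=mode,
                          dropped={"undefined": 0, "below_min": 0, "above_max": 0,
                                   "zero_weight": 0})
    for key in pairs:
        pair_key = key[-2:] if len(key) == 3 else tuple(key)
        est = estimates[pair_key]
        if est.Ks is None:
            dist.dropped["undefined"] += 1
            continue
        if est.Ks < ks_min:
            dist.dropped["below_min"] += 1
            continue
        if est.Ks > ks_max:
            dist.dropped["above_max"] += 1
            continue
        w = 1.0 if weights is None else weights.get(pair_key, 0.0)
        if w <= 0:
            dist.dropped["zero_weight"] += 1
            continue
        dist.entries.append((pair_key, est.Ks, w))
    if not dist.entries:
        log.warning("Ks distribution %r is empty after filtering", label)
    return dist
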