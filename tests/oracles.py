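"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(exhaustive enumeration, naive dynamic programming, grid search) without
sharing code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_CODE = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon: str) -> str:
    return _CODE.forward_table.get(codon, "*")


# ---------------------------------------------------------------------------
# NG86 by direct enumeration


def ng86_sites(codon: str) -> float:
    """Synonymous site count of one codon: per position, the fraction of
    stop-free single-base alternatives that are synonymous."""
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT" if b != codon[pos]]
        ok = [a for a in alts if _aa(a) != "*"]
        if ok:
            s += sum(1 for a in ok if _aa(a) == _aa(codon)) / len(ok)
    return s


def ng86_diffs(ca: str, cb: str):
    """Pathway-averaged (syn, nonsyn) differences, or None if every
    substitution order passes through a stop codon."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    outcomes = []
    for perm in permutations(positions):
        cur = ca
        sd = nd = 0
        ok = True
        for p in perm:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            outcomes.append((sd, nd))
    if not outcomes:
        return None
    return (sum(o[0] for o in outcomes) / len(outcomes),
            sum(o[1] for o in outcomes) / len(outcomes))


def ng86_oracle(codons_a, codons_b):
    """Full NG86 on paired codon lists (no gaps): returns
    (S, N, Sd, Nd, Ks, Ka); Ks/Ka are None when saturated."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        d = ng86_diffs(ca, cb)
        if d is None:
            continue
        S += (ng86_sites(ca) + ng86_sites(cb)) / 2
        N += (3 - ng86_sites(ca) + 3 - ng86_sites(cb)) / 2
        Sd += d[0]
        Nd += d[1]

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(Sd / S) if S > 0 else None
    ka = jc(Nd / N) if N > 0 else None
    return S, N, Sd, Nd, ks, ka


# ---------------------------------------------------------------------------
# affine-gap global alignment score (Gotoh), biopython gap convention:
# a gap of length L scores open + (L - 1) * extend


def affine_global_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + sub
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend,
                           Iy[i - 1][j] + gap_open)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend,
                           Ix[i][j - 1] + gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# brute-force LCA reconciliation


def _leafset(node):
    return [l.name for l in node.leaves()]


def _species_paths(species_root):
    """Map species label -> list of ancestor labels from the root down."""
    paths = {}

    def walk(n, path):
        path = path + [n.name]
        paths[n.name] = path
        for c in n.children:
            walk(c, path)

    walk(species_root, [])
    return paths


def reconcile_oracle(gene_root, species_root, species_of):
    """Naive LCA reconciliation: events as (frozenset of leaf names below
    the duplication node, mapped species node, type)."""
    paths = _species_paths(species_root)

    def lca(species_set):
        common = None
        for sp in species_set:
            p = paths[sp]
            common = p if common is None else [x for x, y in zip(common, p) if x == y]
        return common[-1]

    # species sets below each species-tree node
    below = {}

    def fill(n):
        below[n.name] = set(l.name for l in n.leaves())
        for c in n.children:
            fill(c)

    fill(species_root)

    events = []

    def walk(n):
        if n.is_leaf:
            return {species_of(n.name)}
        child_sets = [walk(c) for c in n.children]
        mine = set().union(*child_sets)
        my_map = lca(mine)
        if any(lca(cs) == my_map for cs in child_sets):
            snode = next(
                sn for sn in _walk_nodes(species_root) if sn.name == my_map
            )
            if snode.is_leaf:
                ev_type = "other"
            else:
                a = below[snode.children[0].name]
                b = below[snode.children[1].name]
                ev_type = "AB_AB" if all(
                    cs & a and cs & b for cs in child_sets[:2]
                ) and len(child_sets) >= 2 else "other"
            events.append((frozenset(_leafset(n)), my_map, ev_type))
        return mine

    walk(gene_root)
    return sorted(events)


def _walk_nodes(n):
    yield n
    for c in n.children:
        yield from _walk_nodes(c)


# ---------------------------------------------------------------------------
# hypergeometric upper tail by exact combinatorics


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


# ---------------------------------------------------------------------------
# weighted two-component mixture log-likelihood and grid search


def weighted_mixture_loglik(x, w, params):
    """params: list of (weight, mean, sd)."""
    x = np.asarray(x, dtype=float)
    dens = np.zeros_like(x)
    for pi, mu, sd in params:
        dens += pi * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    return float(np.sum(np.asarray(w) * np.log(dens)))


def grid_search_two_component(x, w):
    """Coarse exhaustive search over two-component mixtures."""
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, np.linspace(0.02, 0.98, 13))
    sds = np.std(x) * np.array([0.25, 0.5, 0.75, 1.0, 1.5])
    best = -math.inf
    for m1 in qs:
        for m2 in qs:
            if m2 <= m1:
                continue
            for s1 in sds:
                for s2 in sds:
                    for p in (0.2, 0.35, 0.5, 0.65, 0.8):
                        ll = weighted_mixture_loglik(
                            x, w, [(p, m1, s1), (1 - p, m2, s2)]
                        )
                        if ll > best:
                            best = ll
    return best
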