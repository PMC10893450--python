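"""Positive-selection screening and downstream gene-set statistics.

* ``screen_positive_selection`` flags duplicate pairs with Ka/Ks strictly
  above 1 (undefined ratios — zero or saturated Ks — are reported
  separately, never flagged).
* ``hypergeometric_enrichment`` is a standard over-representation test:
  for each annotation term the upper-tail hypergeometric probability
  P(X >= k) of seeing k set genes with the term, Benjamini–Hochberg
  adjusted across tested terms.  Annotation maps are taken as given; no
  GO-hierarchy propagation is performed.
* ``gene_fraction_test`` compares per-genus mean gene fractions (target
  genes / total genes per species) with a two-sample t-test (Welch by
  default) and renders the usual significance stars.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "SelectionScreenResult", "EnrichmentResult", "GeneFractionStat",
    "screen_positive_selection", "hypergeometric_enrichment",
    "gene_fraction_test", "significance_stars",
]


@dataclass
class SelectionScreenResult:
    pairs_total: int
    pairs_positive: int
    pairs_undefined: int
    fraction_positive: float
    per_pair: pd.DataFrame


@dataclass
class EnrichmentResult:
    term: str
    k: int          # set genes with the term
    K: int          # universe genes with the term
    n: int          # set size
    N: int          # universe size
    p_value: float
    q_value: float


@dataclass
class GeneFractionStat:
    fractions: dict
    genus_means: dict
    t_statistic: float
    p_value: float
    stars: str
    variant: str = "welch"


def screen_positive_selection(estimates) -> SelectionScreenResult:
    """Ka/Ks > 1 (strict) flags a duplicate pair as positively selected.

    ``estimates`` is an iterable of :class:`~wgdscan.kaks.KaKsEstimate`.
    Pairs with undefined Ka/Ks are excluded from the denominator."""
    estimates = list(estimates)
    if not estimates:
        log.warning("positive-selection screen on an empty pair list")
        return SelectionScreenResult(0, 0, 0, float("nan"),
                                     pd.DataFrame(columns=["gene_a", "gene_b", "Ka",
                                                           "Ks", "ka_ks", "selected"]))
    rows = []
    positive = undefined = 0
    for est in estimates:
        ratio = est.ka_ks
        if ratio is None or est.Ks is None or not math.isfinite(ratio):
            undefined += 1
            rows.append((est.gene_a, est.gene_b, est.Ka, est.Ks, None, False))
            continue
        sel = ratio > 1.0
        positive += sel
        rows.append((est.gene_a, est.gene_b, est.Ka, est.Ks, ratio, sel))
    total = len(estimates) - undefined
    frac = positive / total if total else float("nan")
    per_pair = pd.DataFrame(rows, columns=["gene_a", "gene_b", "Ka", "Ks",
                                           "ka_ks", "selected"])
    return SelectionScreenResult(total, positive, undefined, frac, per_pair)


def hypergeometric_enrichment(
    gene_set,
    annotation: dict,
    universe,
    min_term_size: int = 3,
) -> list[EnrichmentResult]:
    """Over-representation of annotation terms in ``gene_set`` against
    ``universe``; ``annotation`` maps gene -> iterable of terms.  Results
    are sorted by p-value (ties by term id)."""
    universe = set(universe)
    gene_set = set(gene_set)
    outside = sorted(gene_set - universe)
    if outside:
        raise ValueError(f"genes outside the universe: {outside[:10]}")
    term_universe: dict[str, set] = {}
    for g in universe:
        for t in annotation.get(g, ()):
            term_universe.setdefault(t, set()).add(g)
    N, n = len(universe), len(gene_set)
    results = []
    for term in sorted(term_universe):
        members = term_universe[term]
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, min(p, 1.0), 1.0))
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def gene_fraction_test(
    counts: dict,
    genus_map: dict,
    variant: str = "welch",
) -> GeneFractionStat:
    """Two-genus comparison of per-species gene fractions.

    ``counts`` maps species -> (target_count, total_count); ``genus_map``
    maps species -> genus.  Exactly two genera, each with >= 2 species,
    are required (the t statistic needs within-genus variance)."""
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    fractions = {}
    for sp, (target, total) in counts.items():
        if total <= 0:
            raise ValueError(f"{sp}: total gene count must be > 0")
        if not 0 <= target <= total:
            raise ValueError(f"{sp}: target count outside [0, total]")
        fractions[sp] = target / total
    genera: dict[str, list] = {}
    for sp, frac in fractions.items():
        genera.setdefault(genus_map[sp], []).append(frac)
    if len(genera) != 2:
        raise ValueError(f"need exactly two genera, got {sorted(genera)}")
    (ga, xs), (gb, ys) = sorted(genera.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each genus needs >= 2 species (variance undefined)")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.allclose(xs.var(), 0) and np.allclose(ys.var(), 0):
        # degenerate: no within-genus variance; identical means are a null
        # result, different means an arbitrarily strong one
        if np.isclose(xs.mean(), ys.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if xs.mean() > ys.mean() else -math.inf, 0.0
    else:
        t, p = stats.ttest_ind(xs, ys, equal_var=(variant == "student"))
        t, p = float(t), float(p)
        if np.isclose(xs.mean(), ys.mean()) and np.isclose(t, 0.0):
            t, p = 0.0, 1.0
    return GeneFractionStat(
        fractions=fractions,
        genus_means={ga: float(xs.mean()), gb: float(ys.mean())},
        t_statistic=t,
        p_value=p,
        stars=significance_stars(p),
        variant=variant,
    )
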