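"""Genetic-code tables for codon-level substitution counting.

Everything downstream of the standard nuclear genetic code is precomputed
here once at import time:

* per-codon synonymous/nonsynonymous *site* fractions, with mutational
  alternatives that would create a stop codon excluded and the remaining
  alternatives renormalised so every sense codon still contributes three
  sites;
* pathway-averaged synonymous/nonsynonymous *difference* counts for every
  ordered codon pair, where substitution pathways passing through a stop
  codon are discarded and the remainder averaged with equal weight.

These tables drive both the Nei–Gojobori (NG86) estimator and the forward
codon simulator, which keeps the two ends of the pipeline on exactly the
same model of the code.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS = ["".join(c) for c in product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
#: one-letter amino acid per codon index, ``*`` for stop
AA = np.array([_standard.forward_table.get(c, "*") for c in CODONS])
IS_STOP = AA == "*"
SENSE_CODONS = [i for i in range(64) if not IS_STOP[i]]

# MUT[c, pos, b] = codon index obtained by setting position pos of codon c
# to base b (identity when b is already the base at pos).
MUT = np.empty((64, 3, 4), dtype=np.int16)
for _ci, _c in enumerate(CODONS):
    for _pos in range(3):
        for _b in range(4):
            MUT[_ci, _pos, _b] = CODON_INDEX[_c[:_pos] + BASES[_b] + _c[_pos + 1:]]

# Site fractions. For each position of a sense codon the synonymous
# fraction is (#synonymous alternatives) / (#stop-free alternatives); the
# position still counts as one full site, so S + N = 3 per codon.
SYN_SITES = np.full(64, np.nan)
NONSYN_SITES = np.full(64, np.nan)
for _ci in SENSE_CODONS:
    s = 0.0
    for _pos in range(3):
        alts = [int(MUT[_ci, _pos, b]) for b in range(4) if int(MUT[_ci, _pos, b]) != _ci]
        ok = [a for a in alts if not IS_STOP[a]]
        if ok:
            s += sum(1 for a in ok if AA[a] == AA[_ci]) / len(ok)
    SYN_SITES[_ci] = s
    NONSYN_SITES[_ci] = 3.0 - s


def _pathway_counts(a: int, b: int) -> tuple[float, float, bool]:
    """Average (syn, nonsyn) step counts over stop-free substitution orders."""
    diff = [p for p in range(3) if CODONS[a][p] != CODONS[b][p]]
    if not diff:
        return 0.0, 0.0, True
    tot_s = tot_n = 0.0
    n_valid = 0
    for order in permutations(diff):
        cur = a
        path_s = path_n = 0
        blocked = False
        for pos in order:
            nxt = int(MUT[cur, pos, BASE_INDEX[CODONS[b][pos]]])
            if IS_STOP[nxt]:
                blocked = True
                break
            if AA[nxt] == AA[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if not blocked:
            tot_s += path_s
            tot_n += path_n
            n_valid += 1
    if n_valid == 0:
        return 0.0, 0.0, False
    return tot_s / n_valid, tot_n / n_valid, True


# SD/ND: pathway-averaged synonymous/nonsynonymous differences per codon
# pair; PAIR_OK is False when either codon is a stop or every substitution
# pathway between the two runs through a stop.
SD = np.zeros((64, 64))
ND = np.zeros((64, 64))
PAIR_OK = np.zeros((64, 64), dtype=bool)
for _a in SENSE_CODONS:
    for _b in SENSE_CODONS:
        s, n, ok = _pathway_counts(_a, _b)
        SD[_a, _b] = s
        ND[_a, _b] = n
        PAIR_OK[_a, _b] = ok

# Plain-python mirrors: the forward simulator's inner loop runs on these.
MUT_L = MUT.tolist()
AA_INDEX = [(-1 if IS_STOP[i] else ord(AA[i])) for i in range(64)]
IS_STOP_L = IS_STOP.tolist()


def codon_indices(cds: str) -> list[int]:
    """Codon index list for an in-frame CDS (validates frame and stops)."""
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        try:
            ci = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"non-ACGT codon {codon!r} at position {i}") from None
        if IS_STOP[ci] and i < len(seq) - 3:
            raise ValueError(f"internal stop codon {codon!r} at position {i}")
        out.append(ci)
    if out and IS_STOP[out[-1]]:
        out = out[:-1]  # trailing stop carries no substitution information
    return out


def indices_to_cds(idx: list[int]) -> str:
    return "".join(CODONS[i] for i in idx)


def translate_indices(idx: list[int]) -> str:
    return "".join(AA[i] for i in idx)
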