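"""Forward simulation of coding sequences with planted whole-genome duplications.

The generator produces the statistical structure the inference side of the
package consumes: several species on a known rooted tree, paralog pairs
whose synonymous ages cluster at planted WGD bursts on top of an
exponential-like background of small-scale duplications (SSDs), ortholog
pairs whose Ks reflects speciation depth, and lineage-specific synonymous
rate heterogeneity.

Substitution model
------------------
Per-site continuous-time substitution with equal exchange rates between
the four bases.  A proposed change that creates a stop codon is rejected
and redrawn; a nonsynonymous change is accepted with probability
``omega`` (the target Ka/Ks); synonymous changes are always accepted.
The attempt count per branch is calibrated from the branch's starting
sequence so that the expected number of accepted synonymous substitutions
per synonymous site equals the branch's Ks length.  No indels, no
codon-usage bias, no among-site rate variation.

Branch lengths of the species tree are *reference-scale* Ks per lineage;
a per-branch rate multiplier (given per tip label, default 1) scales them
into effective Ks, which is what the sequences actually accumulate.  A
planted WGD episode at species-tree node ``v`` with pair-age ``age_ks``
duplicates every extant gene copy at reference depth ``age_ks / 2`` on
the branch above ``v`` (or on a stem above the root), so surviving
duplicate pairs have true Ks equal to the episode age when rates are
homogeneous.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codons as ct

__all__ = [
    "SpeciesTreeSpec",
    "WGDEpisode",
    "SyntheticDataset",
    "simulate_codon_pair",
    "simulate_wgd_dataset",
    "write_dataset",
    "read_dataset",
]

# per-codon counts of synonymous and stop-free single-base alternatives,
# used to calibrate attempt numbers per branch
_N_SYN_ALT = np.zeros(64)
_N_NONSTOP_ALT = np.zeros(64)
for _ci in ct.SENSE_CODONS:
    for _pos in range(3):
        for _b in range(4):
            a = int(ct.MUT[_ci, _pos, _b])
            if a == _ci or ct.IS_STOP[a]:
                continue
            _N_NONSTOP_ALT[_ci] += 1
            if ct.AA[a] == ct.AA[_ci]:
                _N_SYN_ALT[_ci] += 1

_POW = (16, 4, 1)


def _evolve(seq: list[int], eff_ks: float, omega: float, rng: np.random.Generator):
    """Evolve a codon-index sequence by ``eff_ks`` expected synonymous
    substitutions per synonymous site; returns (new_seq, n_syn, n_nonsyn)."""
    seq = list(seq)
    if eff_ks <= 0.0 or not seq:
        return seq, 0, 0
    arr = np.asarray(seq)
    s_sites = float(ct.SYN_SITES[arr].sum())
    p_syn = float(_N_SYN_ALT[arr].sum() / _N_NONSTOP_ALT[arr].sum())
    m = int(rng.poisson(eff_ks * s_sites / p_syn))
    if m == 0:
        return seq, 0, 0
    L = 3 * len(seq)
    pos = rng.integers(0, L, size=m).tolist()
    step = rng.integers(1, 4, size=m).tolist()
    acc = rng.random(m).tolist()
    mut = ct.MUT_L
    aai = ct.AA_INDEX
    stop = ct.IS_STOP_L
    n_syn = n_non = 0
    for i in range(m):
        p = pos[i]
        ci, off = divmod(p, 3)
        cur = seq[ci]
        curb = (cur // _POW[off]) % 4
        new = mut[cur][off][(curb + step[i]) % 4]
        while stop[new]:  # rejected-and-redrawn: propose a fresh change
            p = int(rng.integers(0, L))
            ci, off = divmod(p, 3)
            cur = seq[ci]
            curb = (cur // _POW[off]) % 4
            new = mut[cur][off][(curb + int(rng.integers(1, 4))) % 4]
        if aai[new] == aai[cur]:
            seq[ci] = new
            n_syn += 1
        elif acc[i] < omega:
            seq[ci] = new
            n_non += 1
    return seq, n_syn, n_non


def _random_cds(length_codons: int, rng: np.random.Generator) -> list[int]:
    return [int(c) for c in rng.choice(ct.SENSE_CODONS, size=length_codons)]


def simulate_codon_pair(length_codons: int, target_ks: float, omega: float, seed: int):
    """Evolve two descendant CDS from a random stop-free ancestor.

    Each lineage accumulates an expected ``target_ks / 2`` synonymous
    substitutions per synonymous site, with nonsynonymous changes accepted
    with probability ``omega``.  Returns ``(cds_a, cds_b, true_ks, true_ka)``
    where the true values are computed from the recorded substitution
    events and the ancestor's site counts.
    """
    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    anc = _random_cds(length_codons, rng)
    arr = np.asarray(anc)
    s_anc = float(ct.SYN_SITES[arr].sum())
    n_anc = float(ct.NONSYN_SITES[arr].sum())
    half = target_ks / 2.0
    seq_a, sa, na = _evolve(anc, half, omega, rng)
    seq_b, sb, nb = _evolve(anc, half, omega, rng)
    true_ks = (sa + sb) / s_anc
    true_ka = (na + nb) / n_anc
    return ct.indices_to_cds(seq_a), ct.indices_to_cds(seq_b), true_ks, true_ka


# ---------------------------------------------------------------------------
# species tree / episodes


class _SNode:
    __slots__ = ("label", "length", "mult", "children", "parent", "depth")

    def __init__(self, label, length=0.0, mult=1.0):
        self.label = label
        self.length = float(length)
        self.mult = float(mult)
        self.children: list[_SNode] = []
        self.parent: _SNode | None = None
        self.depth = 0.0

    @property
    def is_leaf(self):
        return not self.children


@dataclass
class SpeciesTreeSpec:
    """A rooted binary species tree with branch lengths in reference-scale
    Ks per lineage (substitutions per synonymous site) and per-tip rate
    multipliers modelling heterogeneous synonymous rates.

    The tree must be ultrametric on the reference scale so that planted
    episode ages map onto unique branch positions.
    """

    newick: str
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        auto = 0

        def build(nd) -> _SNode:
            nonlocal auto
            if nd.is_leaf():
                label = nd.taxon.label.replace(" ", "_") if nd.taxon else nd.label
                if not label:
                    raise ValueError("unlabelled tip in species tree")
            else:
                label = nd.label
                if not label:
                    auto += 1
                    label = f"N{auto}"
            sn = _SNode(label, nd.edge.length or 0.0)
            if sn.length < 0:
                raise ValueError(f"negative branch length at {label}")
            for ch in nd.child_nodes():
                c = build(ch)
                c.parent = sn
                sn.children.append(c)
            if len(sn.children) not in (0, 2):
                raise ValueError("species tree must be binary and rooted")
            return sn

        self.root = build(tree.seed_node)
        self._nodes: dict[str, _SNode] = {}
        for sn in self._walk(self.root):
            if sn.label in self._nodes:
                raise ValueError(f"duplicate node label {sn.label!r}")
            self._nodes[sn.label] = sn
            if sn.is_leaf:
                sn.mult = float(self.rate_multipliers.get(sn.label, 1.0))
                if sn.mult <= 0:
                    raise ValueError(f"rate multiplier for {sn.label} must be > 0")

        def set_depth(sn) -> float:
            if sn.is_leaf:
                sn.depth = 0.0
                return 0.0
            d = [set_depth(c) + c.length for c in sn.children]
            if max(d) - min(d) > 1e-6:
                raise ValueError(
                    "species tree must be ultrametric on the reference Ks scale"
                )
            sn.depth = sum(d) / len(d)
            return sn.depth

        set_depth(self.root)

    @staticmethod
    def _walk(sn):
        yield sn
        for c in sn.children:
            yield from SpeciesTreeSpec._walk(c)

    @property
    def tips(self) -> list[str]:
        return [n.label for n in self._walk(self.root) if n.is_leaf]

    def node(self, label: str) -> _SNode:
        return self._nodes[label]


@dataclass
class WGDEpisode:
    """A planted polyploidy event: every gene copy extant at reference
    depth ``age_ks / 2`` on the branch above ``node`` duplicates; the new
    copy survives with probability ``retention_prob``."""

    node: str
    age_ks: float
    retention_prob: float
    id: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must lie in [0, 1]")
        if self.age_ks < 0:
            raise ValueError("age_ks must be non-negative")
        if self.id is None:
            self.id = f"wgd:{self.node}:{self.age_ks:g}"


@dataclass
class SyntheticDataset:
    collections: dict[str, dict[str, str]]      # species -> gene id -> CDS
    families: dict[str, str]                    # gene id -> family id
    true_gene_trees: dict[str, str]             # family id -> rooted newick
    truth: pd.DataFrame                         # gene_a, gene_b, origin, true_ks
    spec: SpeciesTreeSpec | None = None
    episodes: list[WGDEpisode] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene-family simulation


class _GNode:
    __slots__ = ("children", "name", "event", "edepth")

    def __init__(self, event, edepth, name=None):
        self.children: list[_GNode] = []
        self.event = event          # "root" | "speciation" | "ssd" | episode id | "tip"
        self.edepth = float(edepth)  # effective Ks accumulated from family origin
        self.name = name

    @property
    def is_leaf(self):
        return self.name is not None


class FamilyExtinctError(RuntimeError):
    pass


def _simulate_family(
    fam_id: str,
    spec: SpeciesTreeSpec,
    episodes_by_node: dict[str, list[tuple[WGDEpisode, float]]],
    stem_episodes: list[tuple[WGDEpisode, float]],
    ssd_rate: float,
    loss_rate: float,
    length_codons: int,
    omega: float,
    rng: np.random.Generator,
):
    """One family: returns (tips as list of (_GNode, species, seq), gene-tree root)."""
    total_rate = ssd_rate + loss_rate

    def evolve_segment(node_seq_pairs, ref_len, mult, snode_label):
        """Evolve each active copy over a reference-length segment, applying
        the SSD/loss Poisson process; returns the surviving copies."""
        out = []
        for gnode, seq in node_seq_pairs:
            stack = [(gnode, seq, ref_len)]
            while stack:
                gn, sq, remaining = stack.pop()
                eff_remaining = remaining * mult
                t = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
                if t >= eff_remaining:
                    sq2, _, _ = _evolve(sq, eff_remaining, omega, rng)
                    gn.edepth += eff_remaining
                    out.append((gn, sq2))
                    continue
                sq2, _, _ = _evolve(sq, t, omega, rng)
                gn.edepth += t
                ref_left = remaining - t / mult
                if rng.random() < ssd_rate / total_rate:
                    dup = _GNode("ssd", gn.edepth)
                    c1 = _GNode("pass", gn.edepth)
                    c2 = _GNode("pass", gn.edepth)
                    dup.children = [c1, c2]
                    gn.children = [dup]  # gn splices away during pruning
                    stack.append((c1, sq2, ref_left))
                    stack.append((c2, list(sq2), ref_left))
                # else: loss — copy dies, nothing appended
        return out

    def apply_episode(copies, ep: WGDEpisode):
        out = []
        for gn, sq in copies:
            if rng.random() < ep.retention_prob:
                dup = _GNode(ep.id, gn.edepth)
                c1 = _GNode("pass", gn.edepth)
                c2 = _GNode("pass", gn.edepth)
                dup.children = [c1, c2]
                gn.children = [dup]
                out.append((c1, sq))
                out.append((c2, list(sq)))
            else:
                out.append((gn, sq))
        return out

    tip_records: list[tuple[_GNode, str, list[int]]] = []
    copy_counter: dict[str, int] = {}

    def descend(snode: _SNode, copies):
        """Process the branch above ``snode`` then recurse or emit tips."""
        parent_depth = snode.parent.depth if snode.parent else None
        node_eps = episodes_by_node.get(snode.label, [])
        if snode.parent is not None:
            # split branch [snode.depth, parent.depth] at episode points
            # (ordered oldest first)
            points = sorted(node_eps, key=lambda t: -t[1])
            cur_top = parent_depth
            for ep, d in points:
                copies = evolve_segment(copies, cur_top - d, snode.mult if snode.is_leaf else 1.0, snode.label)
                copies = apply_episode(copies, ep)
                cur_top = d
            copies = evolve_segment(copies, cur_top - snode.depth, snode.mult if snode.is_leaf else 1.0, snode.label)
        if not copies:
            return
        if snode.is_leaf:
            for gn, sq in copies:
                copy_counter[snode.label] = copy_counter.get(snode.label, 0) + 1
                gn.name = f"{snode.label}|{fam_id}|{copy_counter[snode.label]}"
                gn.event = "tip"
                tip_records.append((gn, snode.label, sq))
            return
        left, right = snode.children
        lcopies = []
        rcopies = []
        for gn, sq in copies:
            gn.event = "speciation"
            cl = _GNode("pass", gn.edepth)
            cr = _GNode("pass", gn.edepth)
            gn.children = [cl, cr]
            lcopies.append((cl, sq))
            rcopies.append((cr, list(sq)))
        descend(left, lcopies)
        descend(right, rcopies)

    root_seq = _random_cds(length_codons, rng)
    groot = _GNode("root", 0.0)
    copies = [(groot, root_seq)]
    # stem above the species-tree root: episodes older than the root split,
    # evolving at the reference rate
    if stem_episodes:
        cur_top = max(d for _, d in stem_episodes)
        for ep, d in sorted(stem_episodes, key=lambda t: -t[1]):
            copies = evolve_segment(copies, cur_top - d, 1.0, "stem")
            copies = apply_episode(copies, ep)
            cur_top = d
        copies = evolve_segment(copies, cur_top - spec.root.depth, 1.0, "stem")
    descend(spec.root, copies)

    if not tip_records:
        raise FamilyExtinctError(fam_id)

    # prune dead lineages / splice unary pass-through nodes
    def prune(gn: _GNode):
        if gn.is_leaf:
            return gn
        kept = [prune(c) for c in gn.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        gn.children = kept
        return gn

    root = prune(groot)
    return tip_records, root


def _gene_tree_newick(root: _GNode) -> str:
    def rec(gn: _GNode, parent_edepth: float) -> str:
        blen = gn.edepth - parent_edepth
        if gn.is_leaf:
            return f"{gn.name}:{blen:.6g}"
        inner = ",".join(rec(c, gn.edepth) for c in gn.children)
        return f"({inner}){gn.event}:{blen:.6g}"

    if root.is_leaf:
        return f"({root.name}:0);"
    inner = ",".join(rec(c, root.edepth) for c in root.children)
    return f"({inner}){root.event};"


def _truth_rows(root: _GNode, tip_records):
    """Origin label and true Ks for every tip pair, via gene-tree MRCA."""
    # collect tips under each node
    rows = []

    def collect(gn):
        if gn.is_leaf:
            return [gn]
        tips_below = []
        childsets = [collect(c) for c in gn.children]
        for i in range(len(childsets)):
            for j in range(i + 1, len(childsets)):
                for a in childsets[i]:
                    for b in childsets[j]:
                        ga, gb = sorted((a, b), key=lambda t: t.name)
                        if gn.event in ("speciation", "root"):
                            origin = "speciation"
                        elif gn.event == "ssd":
                            origin = "ssd"
                        else:
                            origin = gn.event  # episode id
                        true_ks = (ga.edepth - gn.edepth) + (gb.edepth - gn.edepth)
                        rows.append((ga.name, gb.name, origin, true_ks))
        for cs in childsets:
            tips_below.extend(cs)
        return tips_below

    collect(root)
    return rows


def simulate_wgd_dataset(
    spec: SpeciesTreeSpec,
    episodes: list[WGDEpisode],
    n_families: int,
    ssd_rate: float = 0.05,
    loss_rate: float = 0.02,
    mean_length_codons: int = 200,
    omega: float = 0.2,
    seed: int = 0,
    max_retries: int = 100,
) -> SyntheticDataset:
    """Simulate ``n_families`` gene families down the species tree.

    Each family starts as one ancestral gene; planted WGD episodes
    duplicate every extant copy, small-scale duplications arrive as a
    Poisson process at ``ssd_rate`` per effective-Ks unit per copy, and
    losses at ``loss_rate``.  Families losing all lineages are regenerated
    (bounded retries).  Same seed, same arguments: byte-identical output.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    for ep in episodes:
        if ep.node != spec.root.label and ep.node not in [
            n.label for n in spec._walk(spec.root)
        ]:
            raise ValueError(f"episode references unknown node {ep.node!r}")

    episodes_by_node: dict[str, list[tuple[WGDEpisode, float]]] = {}
    stem_episodes: list[tuple[WGDEpisode, float]] = []
    for ep in episodes:
        sn = spec.node(ep.node)
        d = ep.age_ks / 2.0
        if sn.parent is None:
            if d < sn.depth - 1e-9:
                raise ValueError(
                    f"episode {ep.id} younger than the root split it is placed on"
                )
            stem_episodes.append((ep, d))
        else:
            if not (sn.depth - 1e-9 <= d <= sn.parent.depth + 1e-9):
                raise ValueError(
                    f"episode {ep.id}: depth {d:g} outside branch "
                    f"[{sn.depth:g}, {sn.parent.depth:g}] above {sn.label}"
                )
            episodes_by_node.setdefault(sn.label, []).append((ep, d))

    rng = np.random.default_rng(seed)
    collections: dict[str, dict[str, str]] = {t: {} for t in spec.tips}
    families: dict[str, str] = {}
    gene_trees: dict[str, str] = {}
    truth_rows = []
    n_regenerated = 0

    width = len(str(n_families))
    for i in range(1, n_families + 1):
        fam_id = f"F{i:0{width}d}"
        for attempt in range(max_retries):
            length = max(10, int(rng.poisson(mean_length_codons)))
            try:
                tips, root = _simulate_family(
                    fam_id, spec, episodes_by_node, stem_episodes,
                    ssd_rate, loss_rate, length, omega, rng,
                )
                break
            except FamilyExtinctError:
                n_regenerated += 1
        else:
            raise RuntimeError(f"family {fam_id} went extinct {max_retries} times")
        for gn, species, seq in tips:
            cds = ct.indices_to_cds(seq)
            collections[species][gn.name] = cds
            families[gn.name] = fam_id
        gene_trees[fam_id] = _gene_tree_newick(root)
        truth_rows.extend(_truth_rows(root, tips))

    truth = pd.DataFrame(truth_rows, columns=["gene_a", "gene_b", "origin", "true_ks"])
    ds = SyntheticDataset(collections, families, gene_trees, truth, spec, list(episodes))
    ds.n_regenerated = n_regenerated
    return ds


# ---------------------------------------------------------------------------
# on-disk layout


def write_dataset(dataset: SyntheticDataset, directory, overwrite: bool = False) -> dict:
    """Write one FASTA per species, ``families.tsv``, ``trees/``, and
    ``truth.tsv``; returns a manifest mapping relative path to record count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def target(relpath) -> Path:
        p = directory / relpath
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
        return p

    for species in sorted(dataset.collections):
        genes = dataset.collections[species]
        p = target(f"{species}.fasta")
        records = [
            SeqRecord(Seq(genes[g]), id=g, description="") for g in sorted(genes)
        ]
        SeqIO.write(records, p, "fasta")
        manifest[p.name] = len(records)

    p = target("families.tsv")
    fam = pd.DataFrame(
        sorted(dataset.families.items()), columns=["gene", "family"]
    )
    fam.to_csv(p, sep="\t", index=False)
    manifest[p.name] = len(fam)

    tdir = directory / "trees"
    tdir.mkdir(exist_ok=True)
    for fam_id in sorted(dataset.true_gene_trees):
        p = target(Path("trees") / f"{fam_id}.nwk")
        p.write_text(dataset.true_gene_trees[fam_id] + "\n")
        manifest[f"trees/{fam_id}.nwk"] = 1

    p = target("truth.tsv")
    dataset.truth.to_csv(p, sep="\t", index=False)
    manifest[p.name] = len(dataset.truth)
    return manifest


def read_dataset(directory) -> SyntheticDataset:
    """Re-read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    collections: dict[str, dict[str, str]] = {}
    for fp in sorted(directory.glob("*.fasta")):
        species = fp.stem
        collections[species] = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(fp, "fasta")
        }
    fam = pd.read_csv(directory / "families.tsv", sep="\t")
    families = dict(zip(fam["gene"], fam["family"]))
    gene_trees = {
        fp.stem: fp.read_text().strip()
        for fp in sorted((directory / "trees").glob("*.nwk"))
    }
    truth_path = directory / "truth.tsv"
    if truth_path.exists() and truth_path.stat().st_size > 0:
        truth = pd.read_csv(truth_path, sep="\t")
        if truth.empty:
            truth = pd.DataFrame(columns=["gene_a", "gene_b", "origin", "true_ks"])
    else:
        truth = pd.DataFrame(columns=["gene_a", "gene_b", "origin", "true_ks"])
    return SyntheticDataset(collections, families, gene_trees, truth)
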