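# wgdscan

Inference of whole-genome duplications (WGDs) from coding sequences, built
for transcriptome-scale plant datasets and validated end to end on
simulations with planted ground truth.

A polyploidy event duplicates every gene at once, leaving a burst of
paralog pairs of similar age. `wgdscan` detects and dates such bursts
through two independent lines of evidence, then screens the retained
duplicates for positive selection:

1. **Ks age distributions.** For every within-family paralog pair the
   synonymous distance Ks is estimated by Nei–Gojobori (1986) counting
   with the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p), after a
   protein-level alignment is back-translated to codons. Redundant pairs
   from one duplication event are down-weighted (node weighting) so each
   event contributes unit weight, values outside the closed interval
   [0.1, 5] are dropped, and Gaussian mixtures are fitted by weighted EM
   with the component count selected by BIC = −2 log L + p·ln(n_eff).
   Components above a weight cutoff are candidate WGD peaks; their
   position relative to the mode of an interspecific (ortholog) Ks
   distribution places each event before or after a speciation.
2. **Gene-tree / species-tree reconciliation.** Rooted gene trees are
   mapped onto the species tree by LCA reconciliation; per species-tree
   node the gene-duplication count (GD), GD ratio and the percentage of
   (AB)(AB)-type duplications (both copies retained in both descendant
   lineages) are tallied, and a node is called a WGD when
   GD > 450, ratio > 4.5% and (AB)(AB) > 50%, **or**
   GD > 1000, ratio > 5% and (AB)(AB) > 20% (strict inequalities; counts
   rescalable by n_families/10000 for small datasets).

Peaks convert to absolute ages via date = Ks/(2r) with r the synonymous
substitution rate per site per year, and a correction chain
(C_bridge = Ks_ref/Ks_bridge, C_b(x,y) = (C_x + C_y)/2,
C_target = 2·C_b(bridge,target) − C_bridge, Ks′ = C_target·Ks) rescales
slow- or fast-evolving lineages onto a common reference scale.
Downstream, duplicate pairs with Ka/Ks > 1 are flagged as positively
selected, gene sets are tested for functional enrichment
(hypergeometric upper tail, Benjamini–Hochberg), and per-genus gene
fractions are compared by Welch's t-test.

A forward simulator (`wgdscan.simulate`) generates multi-species CDS
collections down a rooted species tree with planted WGD episodes,
small-scale duplications, losses and lineage-specific rate multipliers —
with the full truth table — so every stage of the inference can be
checked against known answers.

## Worked example

```python
import wgdscan as w

# a 4-species tree with a WGD planted at the A+B ancestor (pair age Ks 1.1)
newick = "((A:0.3,B:0.3)AB:0.4,(C:0.5,O:0.5)CO:0.2)R;"
spec = w.SpeciesTreeSpec(newick)
episode = w.WGDEpisode("AB", age_ks=1.1, retention_prob=0.8, id="e1")
ds = w.simulate_wgd_dataset(spec, [episode], n_families=500, seed=5)

res = w.infer_wgd(ds, newick, focal_species="A", seed=1, criteria="scaled")
print("mixture components:", [(round(wt, 2), round(mu, 2)) for wt, mu, _ in res.model.components])
print(res.summary.table[["gd_count", "gd_ratio", "abab_percent", "wgd_flag"]])
print("flagged nodes:", res.flagged_nodes)
```

prints

```
mixture components: [(0.49, 1.02), (0.51, 1.16), (0.0, 3.52)]
      gd_count  gd_ratio  abab_percent  wgd_flag
node
R            0       0.0           NaN     False
AB         409      81.8     96.577017      True
A           15       3.0      0.000000     False
B            6       1.2      0.000000     False
CO          11       2.2     45.454545     False
C           14       2.8      0.000000     False
O            4       0.8      0.000000     False
flagged nodes: ['AB']
```

The two dominant mixture components straddle the planted age Ks = 1.1,
and the reconciliation flags exactly the planted node: 409 of 500
families show a duplication at AB (GD ratio 81.8%), 96.6% of them of
(AB)(AB) type, while background small-scale duplications at other nodes
stay far below the calling thresholds.

Dating the peak with the reference rate r = 11.04 × 10⁻⁹:

```bash
$ wgdscan date --ks 1.2
54.35
```

The same operations are available from the shell: `wgdscan simulate`,
`ks`, `fitpeaks`, `reconcile`, `date`, `correct`, `select`, `enrich`
(see `wgdscan --help`).

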