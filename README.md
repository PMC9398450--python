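# trophonet

Hypernetwork modelling of the trophectoderm–endometrial-epithelium
interface at human embryo implantation.

At implantation the outer cell layer of the blastocyst — the
trophectoderm (TE) — attaches to the receptive endometrial epithelium
(EEC) and must breach it, a step mediated by multinucleated
syncytiotrophoblast (STB). `trophonet` is an in-silico model of that
interface for systems biologists: it maps which TE surface genes can
engage receptivity-associated EEC ligands, asks how strongly those
interface genes are wired into the rest of the TE transcriptome
(separately for the polar and mural TE subpopulations), and tests whether
they carry a signature of STB differentiation.

## The method

1. **Interface construction.** Receptivity genes are called by per-gene
   one-way ANOVA between non-receptive (proliferative, n = 4) and
   receptive (mid-secretory, n = 4) EEC transcriptomes at strict
   p < 0.01, refined to products localized to the cell surface or
   extracellular space, mapped through a protein–protein interaction
   edge list to candidate TE binding partners, and kept when the partner
   is surface-localized and detected in Day 6 TE single cells.

2. **Hypernetworks.** For interface genes *S* and transcriptome *T*, the
   correlation matrix *r* (|S| × |T|) over a TE cell subset is binarized
   by its own distribution: M[i,j] = 1 iff |r[i,j] − mean(r)| > 1 SD
   (both tails). The hypernetwork **H = M·Mᵀ** counts the transcriptome
   genes each pair of interface genes shares strong correlations with.
   Hierarchical clustering of H exposes a central cluster whose
   *connectivity* (off-diagonal H values over within-cluster pairs) and
   *organization* (Shannon entropy of the normalized pair weights) are
   referenced against 1000 hypernetworks of random same-size gene sets.
   Polar and mural TE are analyzed separately and compared by Wilcoxon
   rank-sum.

3. **STB classifier.** Cluster genes expressed in a trophoblast stem
   cell (TSC) vs STB contrast (n = 4 + 4) are scored by iterated random
   forests with shadow features: each iteration adds a permuted copy of
   every gene, fits a bagged forest, and counts a "hit" when a gene's
   out-of-bag permutation importance beats the best shadow. Hits are
   tested against Binomial(n_iter, ½) with Bonferroni correction —
   confirmed / rejected / tentative.

4. **Velocity display.** Precomputed per-gene per-cell RNA velocities v
   are compressed with the signed-log transform f(v) = sign(v)·ln(1+|v|)
   and ordered by hierarchical clustering for heatmap export.

A synthetic-data module generates every input with planted ground truth
(planted DEGs, planted co-expression modules with known latent-factor
correlation ρ, planted informative classifier genes), so the whole
pipeline is testable end-to-end.

## Worked example

```python
>>> import trophonet as tn
>>> table = tn.load_interface_fixture()     # packaged 39-pair interface
>>> tn.summarize_interface(table)
{'n_rows': 39,
 'cluster_membership': {'neither': 14, 'mural': 14, 'polar_and_mural': 7, 'polar': 4},
 'classifier_status': {'yes': 16, 'nd': 14, 'nd_not_expressed': 5, 'no': 4},
 'classifier_percent': 80.0}
```

The packaged table pairs each EEC receptivity gene with its cognate TE
partner: 11 TE genes sit in the polar hypernetwork cluster (7 shared
with mural), 21 in the mural cluster, and 80% (16/20) of the cluster
genes testable in the TSC/STB contrast are confirmed classifiers of STB
differentiation.

Running the pipeline on synthetic data at the study's scale (86 polar
and 245 mural cells, 39 interface genes, planted module correlations
ρ = 0.8 vs 0.4):

```python
>>> from trophonet import simulate as sim, hypernetwork as hn
>>> te, truth = sim.generate_te_single_cells(seed=7)
>>> ifc = sim.default_interface_genes()
>>> polar = te.subset_obs(te.obs_in_group("polar"))
>>> hyper, vals, mean_c, ent = hn.analyze_subset(ifc, polar)
>>> len(hyper.central_cluster), round(mean_c, 1)
(11, 314.6)
```

The polar-analog central cluster recovers the 11 planted module genes
and its mean connectivity (314.6 shared correlations per gene pair) far
exceeds the mural-analog value (171.6 with the same seed); the rank-sum
comparison of the two connectivity distributions gives p < 10⁻²⁹,
mirroring the stronger EEC-coupling of polar TE.

There is also a CLI (`trophonet simulate | build-interface |
hypernetwork | classify | velocity | all --config cfg.yaml --out dir`)
that writes a complete result bundle — interface table, M and H
matrices, metrics with permutation nulls, importance table, connected
gene-set lists and the velocity heatmap — reproducible byte-for-byte
from the config's master seed.

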