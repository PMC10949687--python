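# nichespan

Multi-slice spatial transcriptome domain analysis from neighborhood
cell-type composition embeddings.

## What it does, and for whom

Spatial transcriptomics experiments increasingly produce **many slices**
of the same or related tissue — replicates, time courses, disease
conditions.  Most domain-detection tools work one slice at a time and
produce labels that cannot be compared across slices.  `nichespan` is for
analysts who already have per-observation cell-type annotations (a
categorical label per cell, or per-spot proportions from a deconvolution
tool) and want:

1. **Joint multi-slice domain detection** — spatial domains defined once
   across all slices, then backtracked to each slice;
2. **Reference-based domain annotation** — transfer domain labels from an
   annotated slice to new slices by nearest-centroid matching;
3. **Slice-level clustering** — group whole slices by their
   spatial-domain composition (e.g. recover developmental stages).

The core idea: represent every cell/spot by the **cell-type composition
of its spatial niche** (itself + its k nearest neighbors, or all spots
within a radius).  Each observation becomes a probability vector over
cell types — interpretable, comparable across slices without batch
correction, and robust to noise.  With niche composition vectors P and Q
compared by the Jensen–Shannon divergence

    JSD(P, Q) = ½ KL(P, M) + ½ KL(Q, M),   M = (P + Q)/2,
    KL(P, Q)  = Σᵢ Pᵢ ln(Pᵢ/Qᵢ),

hierarchical clustering of the pooled observations yields a dendrogram
whose cut at N₁ clusters defines domains `Domain_{N1}_{N2}` (N₂ by
decreasing size); the resolution N₁ can be set manually or chosen
adaptively from the tree shape.  Slice i is then summarized by its domain
composition `Cⁱ = [D_ij / M_i]` for slice-level clustering, and per-domain
centroids form a *spatial reference* for annotating new data.  See
`docs/methods.md` for the full model, parameters, and limitations.

## Worked example

Five synthetic tumor slices; four contain a small B/T-cell-enriched
focal domain (a tertiary-lymphoid-structure analogue), the fifth is a
negative control:

```python
import numpy as np
from nichespan import (detect_domains, simulate_multislice, domain_profile,
                       composition_from_assignment, ari)
from nichespan.scenarios import tls_multislice

mset, truths = simulate_multislice(tls_multislice(seed=11))
assignment, embedding, tree = detect_domains(mset, n_domains="auto", k=30)
print("domains:", assignment.n_domains)
print(domain_profile(assignment, embedding).to_frame().round(3).to_string(index=False))
print(composition_from_assignment(assignment, mset).to_frame().round(3).to_string(index=False))
truth = np.concatenate([truths[s] for s in mset.slice_ids])
print("ARI vs generator truth:", ari(assignment.labels, truth))
```

Output:

```
domains: 3
domain_name  count  B_cell  CD8_T  T_helper  Tumor  Fibroblast  Endothelial
 Domain_3_1    750   0.039  0.031     0.000  0.770       0.124        0.035
 Domain_3_2    750   0.000  0.049     0.052  0.049       0.520        0.330
 Domain_3_3    240   0.473  0.265     0.183  0.019       0.044        0.016
slice_id  Domain_3_1  Domain_3_2  Domain_3_3
 slice_1       0.417       0.417       0.167
 slice_2       0.417       0.417       0.167
 slice_3       0.417       0.417       0.167
 slice_4       0.417       0.417       0.167
 slice_5       0.500       0.500       0.000
ARI vs generator truth: 1.0
```

Reading it: the adaptive cut found three domains.  `Domain_3_1` is
tumor-dominated (77% Tumor) and `Domain_3_2` stroma-dominated;
`Domain_3_3` is the rare immune aggregate — 92% of its niche mass on
B cells and T cells — and its slice composition row shows it present in
slices 1–4 but absent (0.000) from the control slice 5.  Every
observation lands in its generating domain (ARI 1.0).

The same pipeline is available from the shell:

```bash
nichespan simulate --sim-config sim.yaml --out-dir data/
nichespan detect --coords data/coords.csv --annotation data/annotation.csv \
    --n-domains auto --out-dir run/
nichespan cluster-slices --input run/assignment.csv --n-groups 3 --out-prefix run/slices
nichespan evaluate --pred run/assignment.csv --truth data/truth.csv --metric ari
```

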