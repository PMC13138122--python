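# naivegate

Automated, cluster-based gating of **naive T cell subpopulations** in
high-dimensional spectral flow cytometry, with the nonparametric statistics
used to test their age-dependent remodeling, and a fully labeled synthetic
cohort generator that provides ground truth for every stage.

## The problem

Human naive T cells are not homogeneous: they contain CD38++ recent thymic
emigrants (RTEs) that decline with age, CXCR3hi cells that accumulate with
age in both CD8+ and CD4+ compartments, CD25lo naive CD4+ cells that
accumulate with age, and a dominant "mature" remainder. Quantifying these
subsets per donor across a large cohort requires reproducible gating of
~100,000-event, ~30-marker files — beyond what manual polygon gating can do
consistently. `naivegate` automates the gating hierarchy:

1. **Transform** — raw intensities x are variance-stabilized with
   `asinh(x / cofactor)`, cofactor 3000; each file is subsampled to a fixed
   event count (100,000 by default) and donors below that floor are excluded.
2. **Cluster** — events become nodes of a k-nearest-neighbor graph
   (squared Euclidean distance on the scaled marker subset of each step);
   edges are re-weighted by the Jaccard similarity of neighbor sets,
   `|N(i) ∩ N(j)| / |N(i) ∪ N(j)|`, and partitioned by Leiden modularity
   optimization at a per-step resolution.
3. **Hierarchical selection** — each gating step re-clusters only the
   events its parent kept and keeps/drops whole clusters by rules on
   cluster-median expression (high CD3 → T cells; high CD8 / high CD4 →
   compartments; CD45RA+ CCR7+ Fas− → naive CD8; Treg removal by CD25hi
   CD127lo; the debris/doublet/dead filter runs twice).
4. **Per-sample density thresholds** — naive CD4 cells are gated by fitting
   the CD45RA kernel density with two Gaussian peaks
   A·exp(−(x−μ)²/2σ²) and thresholding at their intersection, then fitting
   Fas (on the CD45RA+ subset) with one Gaussian and thresholding at μ + σ.
5. **Subset assignment** — within naive events, sequential thresholds with
   strict precedence: CXCR3hi first, then CD38++, then CD25lo (CD4 only);
   leftovers are mature naive.
6. **Statistics** — per-donor subset proportions are compared across five
   age groups (A–E, 25–85 years) by Kruskal–Wallis, Dunn's post hoc test
   (ties-corrected pooled-rank z), Holm step-down within each subset's
   pairwise family, and a final Bonferroni factor for the number of
   subsets compared side by side; age trends are Pearson r with an OLS
   confidence band.

Because real donor files are large and access-controlled, the package ships
a **synthetic cohort generator**: donors in five 10-year age groups (default
sizes 45/29/21/28/35, n=158) whose populations are Gaussian per marker on
the asinh scale and whose subset frequencies vary deterministically with age
(CD38++ declining 6% → 2.4% from 25 to 85 years). Every event carries a
truth label, so gating fidelity, proportion recovery, error calibration and
power are all measurable.

## Worked example

```python
import numpy as np
import naivegate as ng

config = ng.default_cohort_config(seed=9)
donor = ng.simulate_donor(("C001", 50.0, "C"), config, n_events=15_000, seed=10)
asinh = ng.asinh_transform(donor.events, config.cofactor)
result = ng.run_gating_tree(asinh, seed=11)

naive4 = asinh.select_events(np.where(result.naive_cd4)[0])
labels = ng.assign_naive_subsets(naive4, ng.default_subset_thresholds())
for subset in ("CD38++", "CXCR3hi", "CD25lo", "mature"):
    print(f"naive CD4 {subset:8s}: {100 * np.mean(labels == subset):5.1f}%")
```

prints (seeds as above):

```
naive CD4 CD38++  :   4.4%
naive CD4 CXCR3hi :   6.7%
naive CD4 CD25lo  :   7.6%
naive CD4 mature  :  81.4%
```

i.e. for this 50-year-old synthetic donor about 4.4% of naive CD4+ cells
are CD38++ RTEs — between the young (~6%) and old (~2.4%) extremes of the
built-in age trend — while CXCR3hi and CD25lo cells have begun to
accumulate. The scripts in `examples/` walk through each capability
(simulation, preprocessing, clustering, density thresholds, gating,
group statistics, the full pipeline) in the same style, and the `naivegate`
CLI (`simulate`, `cluster`, `gate`, `run`) wraps them for shell use.

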