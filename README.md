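# graftpath

Bioinformatic pipeline for asking *why a transplanted graft was lost* from
peripheral-blood expression profiles. The motivating setting is late-phase
islet xenotransplantation: one subject keeps stable graft function while
another loses its graft months after transplantation, both sampled at four
timepoints (t1 before transplantation, t2 stable, t3 at graft loss, t4
after overt failure). From a genes × (subject, timepoint) abundance matrix,
a pathway database with category labels, a protein–protein interaction
(PPI) network and per-hypothesis seed-gene lists, the pipeline:

1. **Pathway activation** — for each pathway, a one-sided competitive
   permutation test on the mean log2 fold change, run for two comparisons:
   graft-losing vs stable timepoint within the failing subject (t3 vs t2),
   and failing vs stable subject at t3. Genes with abundance < 1 in either
   sample are removed first.
2. **GLPAP selection** — *graft-loss-period-related activated pathways*:
   pathways up-regulated with p < 0.05 in **both** comparisons (set
   intersection, strict threshold).
3. **Category enrichment** — one-sided Fisher's exact test per pathway
   category on the 2×2 table (GLPAP status × category membership),
   reported in ascending p order.
4. **Crosstalk network** — pathways as nodes; the edge weight between P
   and Q is |shared genes| + |PPI edges bridging P∖Q and Q∖P|. Closeness
   centrality (Wasserman–Faust) and degree are computed, and pathways
   **strictly above both network-wide averages** are called central.
5. **Hypothesis evaluation** — each etiological hypothesis (e.g. chronic
   graft rejection, ER stress, lipotoxicity) is a seed-gene set; random
   walk with restart, `s ← (1−r)·W·s + r·s0`, diffuses seed influence over
   the PPI; the propagation ranking is correlated with the
   differential-expression ranking (Pearson on ranks = Spearman), and the
   coefficient c_R is tested against N random seed sets of equal size:
   `p = (1/N)·#{ c_j > c_R }`.

A synthetic-data module generates all inputs with the statistical
structure the analysis assumes (log-normal expression, multiplicative
pathway activation at one (subject, timepoint) cell, scale-free PPI,
causal seeds one PPI hop from the perturbed genes) plus a ground-truth
manifest, so the whole pipeline is testable end to end.

## Worked example

```sh
graftpath simulate --out-dir data --seed 7 --n-genes 2000 --n-pathways 50
graftpath show-config > config.yaml   # then point the paths at data/
graftpath run --config config.yaml
```

or, equivalently, from Python:

```python
import graftpath as gp

ds = gp.generate_dataset(gp.SimulationConfig(rng_seed=7))
within  = gp.score_pathways(ds.expression, ds.pathways, ("S1", "t3"), ("S1", "t2"), rng_seed=0)
between = gp.score_pathways(ds.expression, ds.pathways, ("S1", "t3"), ("S2", "t3"), rng_seed=1)
glpaps = gp.select_glpaps(within, between, alpha=0.05)
print(len(glpaps.pathway_ids), sorted(glpaps.pathway_ids & ds.truth.activated_pathway_ids))
deg = gp.build_deg_profile(ds.expression, ("S1", "t3"), ("S2", "t3"))
for r in gp.evaluate_hypotheses(ds.ppi, deg, ds.seeds, n_sim=0, rng_seed=0):
    print(f"{r.name:28s} coefficient={r.coefficient:+.4f} p={r.parametric_p:.3g}")
```

prints

```
6 ['P001', 'P011', 'P021', 'P031', 'P041']
chronic_graft_rejection      coefficient=+0.0351 p=0.116
ER_stress                    coefficient=+0.0172 p=0.443
lipotoxicity                 coefficient=+0.0163 p=0.466
islet_exhaustion             coefficient=+0.0157 p=0.483
immunosuppressant_toxicity   coefficient=-0.0256 p=0.253
```

The GLPAP stage recovered all five planted activated pathways (plus one
false positive), and the planted causal hypothesis — chronic graft
rejection — attains the highest propagation-vs-expression rank
correlation, exactly the read-out the method uses to call the cause of
graft loss.

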