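# connectodev

Longitudinal analysis of brain-network topology: build functional and
structural connectomes from per-scan inputs, threshold them into binary
graphs, compute regional graph metrics, and compare developmental
trajectories between a clinical and a control group with nested smooth
mixed models.

The package is aimed at developmental neuroimaging groups who have
parcellated, preprocessed data in hand — regional BOLD time series and
tractography streamline-count matrices — and want a reproducible,
desk-testable implementation of the whole downstream chain, from
connectivity matrices to FDR-corrected region-wise model selection. Because
multi-wave clinical cohorts are usually access-restricted, the package
ships a synthetic cohort generator with known planted effects, so every
stage (and the pipeline end-to-end) is validated without any data download.

## What it computes

**Connectomes.** Functional connectivity is the Pearson correlation
*r<sub>ij</sub>* between regional time series. Structural connectivity
scales each streamline count by the inverse of the two endpoint node
volumes, *w<sub>ij</sub> = c<sub>ij</sub> · 2/(v<sub>i</sub>+v<sub>j</sub>)*.
Scans whose mean framewise displacement exceeds 0.5 mm are excluded.

**Thresholding.** Functional matrices are binarized at a threshold τ chosen
from a grid (0–0.5, step 0.05) as the smallest value giving small-world
networks — global efficiency above a degree-matched ring lattice and local
efficiency above degree-preserving rewirings — at an admissible network
cost; sensitivity analyses repeat everything at τ = 0.1/0.15/0.2.
Structural matrices are thresholded by across-subject consistency: an edge
survives when the coefficient of variation of its weight lies at or below
the 75th percentile of the CV distribution over candidate edges, and nodes
left without connections are pruned.

**Graph metrics** on the binary undirected graph *G* with distances
*d<sub>ij</sub>* (hops) and geodesic counts σ<sub>ab</sub>:

- degree *k<sub>i</sub>* — number of edges at node *i*;
- global efficiency *E<sub>glob</sub> = 1/(N(N−1)) Σ<sub>i≠j</sub> 1/d<sub>ij</sub>*;
- local efficiency *E<sub>loc</sub>(i)* — efficiency of the subgraph induced
  by *i*'s neighbours with *i* removed;
- betweenness *B<sub>i</sub> = Σ<sub>a≠i≠b</sub> σ<sub>ab</sub>(i)/σ<sub>ab</sub>*
  (unordered pairs, endpoints excluded, unnormalized).

**Longitudinal models.** Per region and metric, four nested Gaussian mixed
models are fitted by maximum likelihood, all with framewise displacement,
scanner epoch, medication status and sex as covariates and a per-subject
random intercept: (i) a null model, (ii) + a penalized-dimension age smooth
(B-spline, basis dimension 4), (iii) + a group main effect, (iv) + a
group-specific age smooth. The winner is the most complex model whose added
term is significant (p < 0.05) **and** whose AIC undercuts every simpler
nested model by more than 2 units; group- and interaction-contrast p-values
are Benjamini–Hochberg corrected across regions at q = 0.05.

## Worked example

Simulate a 30-subjects-per-group, three-wave cohort with a group offset
planted in two regions, run it through QC → connectivity → binarization at
τ = 0.15 → metrics → region-wise model selection:

```python
import numpy as np
from connectodev import (CohortSpec, EffectSpec, ModelConfig, compute_functional_matrix,
                         binarize, node_metric_table, regionwise_analysis,
                         generate_phenotypes, generate_functional_timeseries,
                         default_template, qc_filter_scans)
from connectodev.pipeline import _observation_table

spec = CohortSpec(n_per_group=30, seed=42)
records, excluded = qc_filter_scans(generate_phenotypes(spec))
print(f"scans retained after motion QC: {len(records)} (excluded {len(excluded)})")

template = default_template(n_regions=60, n_modules=6, seed=59)
effects = [EffectSpec(target_regions=(0, 11), effect_kind="group_offset", magnitude=0.08)]
series = generate_functional_timeseries(records, template, effects, T=150, seed=43)

graphs = [binarize(compute_functional_matrix(ts), tau=0.15) for ts in series]
tables = [node_metric_table(g, scan_id=ts.scan_id) for g, ts in zip(graphs, series)]
obs = _observation_table(tables, records)

res = regionwise_analysis(obs[obs.metric_name == "degree"], ModelConfig())
sig = res[res.significant]
print(f"regions analysed: {len(res)}; significant after FDR: {len(sig)}")
print(sig[["region_label", "winner", "p_term", "q_value"]].to_string(index=False))
```

Output:

```
scans retained after motion QC: 136 (excluded 2)
regions analysed: 60; significant after FDR: 2
region_label winner       p_term      q_value
        R000  group 1.255590e-23 3.766770e-22
        R011  group 3.895959e-31 2.337575e-29
```

The two planted regions — and only those — are recovered: the group model
wins the AIC-plus-significance comparison there, and both survive FDR
across the 60 regions. `p_term` is the Wald p-value of the group
coefficient in the winning model and `q_value` its BH-adjusted value.

The same chain is available from the shell:

```bash
connectodev run --config config.yaml --out run_output --seed 1
```

which writes result TSVs per threshold, a ground-truth table, a
human-readable report and a provenance file carrying the config hash.

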