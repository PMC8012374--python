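# mrakit

Modular response analysis (MRA) for steady-state perturbation data.

MRA reconstructs the direct, signed interactions between the *modules* of a
biological network — genes, pathways or processes, each summarised by one
measured reporter (a transcript abundance, a luciferase readout, a
normalised RNA-seq count) — from systematic perturbation experiments. It is
aimed at systems biologists who can perturb each module once (an siRNA, a
ligand removal) and measure every reporter at steady state, and who want
the *local* wiring of the network rather than the confounded systems-level
responses they observe directly.

## The method

Perturbing module *k* alone (an elementary perturbation *q_k*) and
recording every reporter's relative change yields the **global response
matrix** *R*, with

&nbsp;&nbsp;&nbsp;&nbsp;*R<sub>j,k</sub>* = 2 (*x<sub>j</sub>'* − *x<sub>j</sub>*) / (*x<sub>j</sub>'* + *x<sub>j</sub>*),

the symmetric relative difference, bounded in (−2, 2) for positive
abundances. The **local response (connection-coefficient) matrix** *r* —
the network — and the perturbation magnitudes *P* follow by inversion:

&nbsp;&nbsp;&nbsp;&nbsp;*r* = −[diag(*R*⁻¹)]⁻¹ *R*⁻¹, &nbsp;&nbsp; *P<sub>i,i</sub>* = 1 / (*R*⁻¹)<sub>i,i</sub>,

with the convention *r<sub>i,i</sub>* = −1. The same linear model runs
forward: a combined perturbation with weight vector *c* changes module
activities by −*r*⁻¹ *P c*, which converts back to abundances through the
inverse symmetric relative difference *x₀* (2 + *v*) / (2 − *v*).

Around this core the package provides:

- **Confidence intervals for tiny designs** (`mrakit.bootstrap`,
  `mrakit.spc`): per-cell standard deviations of *R* estimated from
  subgroup ranges (statistical process control; mean range over Hartley's
  d2), a parametric bootstrap drawing whole *R* matrices from per-cell
  normal distributions, and percentile CIs with significance flags
  (CI excludes zero). A pooled gene-population variance estimator with
  iterative out-of-control exclusion handles RNA-seq-style duplicates.
- **Unidirectional MRA** (`mrakit.udmra`): append genes that were never
  perturbed, solve their incoming coefficients from their responses to the
  core perturbations, predict their expression under combined
  perturbations, optionally optimise the perturbation weights
  (udMRA.ab), and benchmark against mean/geometric-mean/max baselines.
- **Screening** (`mrakit.screening`): rank a gene panel by how closely the
  network re-inferred with each gene as a replacement reporter matches a
  reference network (Euclidean and 1−correlation distances on the
  connection coefficients).
- **Synthetic ground truths** (`mrakit.synthetic`): seeded generators for
  networks, replicate-structured datasets and gene panels, used by the
  entire test suite — no downloads needed.
- **Files and CLI** (`mrakit.io`, `mrakit` command): condition-map grammar
  (`CONDITION -> MODULE`, basal marked `-> 0`), long/wide measurement
  tables, TSV network tables, GraphML/GML export for Cytoscape or yEd.

## Worked example

Simulate a noisy 3-module dataset (3 biological × 2 technical replicates,
response-space noise sd 0.03), infer the network and attach bootstrap CIs:

```python
import mrakit as mk

truth = mk.random_ground_truth(3, seed=1, sigma_tech=0.03, space="response")
design = mk.design_for(truth, k_t=3, n_r=2)
data = mk.simulate_dataset(truth, design)

per_rep = mk.build_global_response(data, design, "per_replicate")
mean_R = mk.build_global_response(data, design, "pooled_mean")
sd = mk.replicate_sd_matrix(per_rep, design)

net = mk.infer_network(mean_R)
print(net.r_frame().round(3))

ci = mk.bootstrap_network(mean_R, sd, mk.BootstrapConfig(n_samples=10_000, seed=1))
print(ci.table[["parameter", "estimate", "lower", "upper", "significant"]].round(3))
```

Output:

```
       M1     M2     M3
M1 -1.000  0.541 -0.424
M2  0.559 -1.000 -0.085
M3  0.390 -0.099 -1.000

parameter  estimate  lower  upper  significant
 r[M1,M2]     0.541  0.514  0.569         True
 r[M1,M3]    -0.424 -0.502 -0.358         True
 r[M2,M1]     0.559  0.358  0.783         True
 r[M2,M3]    -0.085 -0.224  0.072        False
 r[M3,M1]     0.390  0.228  0.623         True
 r[M3,M2]    -0.099 -0.222 -0.009         True
    P[M1]    -0.315 -0.399 -0.232         True
    P[M2]    -0.972 -1.127 -0.799         True
    P[M3]    -0.803 -0.908 -0.709         True
```

Each off-diagonal `r[i,j]` is the direct effect of module *j* on module
*i* (positive = activation, negative = inhibition); the true generating
coefficients (0.541, −0.427, 0.538, −0.092, 0.393, −0.109) all fall inside
their intervals here. `significant` marks coefficients whose sign is
established at the chosen level — `r[M2,M3]`'s interval straddles zero,
so its sign is not resolved by this dataset. The negative `P` values
reflect knockdown-style perturbations that lower their own module's
activity.

The same pipeline is available from the shell:

```sh
mrakit simulate --design design.yaml --seed 1 --out-dir sim/
mrakit infer    --data sim/measurements.tsv --design design.yaml --out-dir out/
mrakit ci       --data sim/measurements.tsv --design design.yaml --seed 1 --out-dir out/
mrakit export   --r out/r.tsv --p out/P.tsv --format graphml --out net.graphml
```

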