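# msgnet

Why do savannah herbivores of different species graze side by side? `msgnet`
is a toolkit for studying **mixed-species group (MSG) formation** in
multi-species prey communities. It combines

1. a **survival model** of an individual joining conspecific or
   heterospecific groups, balancing predator-detection benefits, risk
   dilution and resource competition, and
2. a **multi-layer dyadic network pipeline** that builds interspecific
   social-affinity networks from census data, directs them with the model's
   payoffs, and tests which species traits drive affinity with
   MRQAP (multiple-regression quadratic assignment procedure) permutation
   inference,

plus a synthetic community generator with planted ground truth so the whole
pipeline can be exercised and validated without field data.

## The model

A focal individual of species *F* joins *N_T* individuals of target species
*T* under predation by predators *P* (each with community pressure *Q_P*,
Σ*Q_P* = 1). Four trait-driven processes set its survival:

- **Detection** ("many eyes" plus heterospecific informants):
  raw detection `x = V_F + V_T · A_PT · R_TF · N_T` saturates as
  `X = x / (x + c₁)`, where `V` is vigilance (proportion of time), `A_PT`
  the target's probability of alarm calling at predator *P*, and `R_TF` the
  relevance of the target's alarm call to the focal.
- **Dilution**: `Y = 1 − Z_PF / (Z_PF + Z_PT · N_T)` (and `Y = 1` when the
  denominator is zero), with `Z` the predator-specific vulnerability; the
  predator targets the group with probability `L_P = max(Z_PF, Z_PT)`.
- **Death by predation**: `D = 1 − ∏_P (1 − Q_P L_P (1 − X)(1 − Y))`.
- **Resource competition**: the group consumes
  `k = (C_F + N_T · C_T) / C_tot` of the patch, mapped through a logistic
  `K = 1 / (1 + e^{−c₂(k − c₃)})`.

Overall survival is `S = (1 − D)(1 − K)`. Scanning trait grids for focal and
target species yields, per focal phenotype, the *proportion of
heterospecifics worth joining* (vs. the same-size conspecific group) and the
*maximum survival gain* from the best heterospecific partner.

On the empirical side, the affinity between species *F* and *T* over a set
of censused groups is

`W_FT = Σ_i [N_iT/(N_i − 1) · N_iF] · 1/ΣN_F · (ΣN − 1)/ΣN_T`,

corrected for gregariousness as `w_FT = W_FT · ΣW / (ΣW_F ΣW_T)`, directed
by each species' model payoff share, and regressed on trait layers
(vigilance, alarm probability, alarm relevance, log body mass, log group
size, Pianka diet overlap, NDVI habitat difference, movement similarity,
phylogenetic relatedness) with double-semi-partialing (DSP) node-label
permutations. Community-wide heterogeneity is summarised by the Whitehead
social differentiation index (Poisson-corrected CV of dyadic association
rates).

## Worked example

Generate a deterministic synthetic community (12 herbivore species, 5
predators, 66 censuses, 651 alarm trials, 2434 playbacks) and run the full
pipeline:

```bash
msgnet fixtures --outdir demo --seed 0
msgnet all --indir demo --outdir demo_out --seed 1 --permutations 5000
```

which prints (this exact output, given those seeds):

```
social differentiation: 1.112 (well differentiated)
             term  coefficient         t        p
       mass_focal     0.310136  1.866154 0.005399
      mass_target    -0.338111 -2.034491 0.014997
 group_size_focal     0.402223  2.528965 0.000200
group_size_target    -0.380906 -2.394934 0.008598
```

The differentiation index of 1.11 classifies the community as socially
well-differentiated (0.5–2 band). The final MRQAP model (after backward
elimination) retains body-mass and group-size effects: in this synthetic
community, mixed groups were planted by a species-pair affinity kernel, so
the sampled network mostly reflects group-size bookkeeping — the planted
standout pair still shows up as the strongest reciprocal edge
(`demo_out/network_directed_edges.csv` has impala ⇄ thomson's gazelle among
the top dyads). Layer matrices, the undirected/corrected/directed networks
(CSV, GraphML, edge list), the regression tables and a provenance record
(input hashes, seed, version) are all written to `demo_out/`.

The deterministic theory scan (162 focal × 1875 target trait combinations ×
5 group sizes) runs with:

```bash
msgnet scan --outdir scan_out
```

## Layout

- `src/msgnet/survival.py` — survival-model kernels and scenario evaluation
- `src/msgnet/scan.py` — trait-grid enumeration and the deterministic scan
- `src/msgnet/layers.py` — trait indices and dyadic layers from records
- `src/msgnet/affinity.py` — affinity/gregariousness indices, payoffs,
  directed network, social differentiation
- `src/msgnet/mrqap.py` — OLS on dyads, DSP permutation test, backward
  selection
- `src/msgnet/synthetic.py` — planted-truth community generator
- `src/msgnet/pipeline.py`, `src/msgnet/cli.py` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical conventions.
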