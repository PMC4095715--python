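# mpinet

Network-based pathway identification for metabolite lists, with
correction for metabolomic detection bias.

## The problem

Over-representation analysis (ORA) of a metabolite list treats every
metabolite as exchangeable: a pathway's significance depends only on how
many of its members appear in the list. Real metabolites are not
exchangeable in two coupled ways:

1. **Global nonequivalence.** Metabolites differ in how strongly they
   interact with the rest of the metabolic network. A well-connected
   metabolite's dysfunction is easily compensated for by its functional
   partners; a pathway-specific metabolite's is not.
2. **Detection bias.** Metabolomic platforms preferentially measure — and
   differential screens preferentially flag — exactly those
   well-connected, well-studied metabolites.

Unless both are modelled, enrichment analysis systematically favours
"fundamental" pathways full of ubiquitous, easily detected metabolites
and ignores specific pathways whose members are hard to measure even
when the pathway is genuinely dysregulated. `mpinet` implements a
weighted enrichment test that corrects for this.

## The model

Given an edge-weighted metabolite network (weights in (0, 1], e.g.
chemical-association confidence scores / 1000):

- **GCS** (global connection strength) between metabolites *i, j*:
  a length-attenuated walk sum over the weighted adjacency *A*,
  GCS = Σ<sub>L=1..lmax</sub> β<sup>L−1</sup> A<sup>L</sup>
  (defaults β = 0.5, lmax = 6), counting both the number and the length
  of connecting walks.
- **GN score** of metabolite *i*: the mean GCS between *i* and the other
  M − 1 network metabolites. High GN = well connected, easily
  compensated, easily detected.
- **Bias curve.** With y<sub>j</sub> = 1 for interesting (differential)
  metabolites and 0 otherwise, fit Ŷ(x) = Σ β<sub>i</sub> b<sub>i</sub>(x),
  a cubic regression spline in the GN score x with k = 6 quantile knots,
  by penalized least squares ‖Y − Xβ‖² + λβᵀSβ subject to Ŷ
  nondecreasing (S = curvature penalty, λ by GCV). Ŷ<sub>j</sub> estimates
  the probability that metabolite j is detected-and-differential given
  its connectivity.
- **CGNB score** C<sub>j</sub> = 1 − Ŷ<sub>j</sub>: high for
  pathway-specific, hard-to-detect metabolites.
- **Pathway weight.** For pathway P among the K analysed pathways,
  W = mean<sub>j∈P</sub>(1 − C<sub>j</sub>) / ( (1/K) Σ<sub>k</sub>
  mean<sub>r∈P_k</sub>(1 − C<sub>r</sub>) ), and the odds weight
  w₁ = W⁶ (non-members have w₂ = 1).
- **Significance.** With N background metabolites, m₁ of them in the
  pathway, n interesting and g interesting members, the p-value is the
  upper tail of the Wallenius noncentral hypergeometric distribution:

  p = 1 − Σ<sub>x=0..g−1</sub> C(m₁,x) C(m₂,n−x)
  ∫₀¹ (1−t^{w₁/dₓ})ˣ (1−t^{w₂/dₓ})^{n−x} dt,
  dₓ = w₁(m₁−x) + w₂(m₂−(n−x)), m₂ = N − m₁.

  w₁ < 1 (pathway-specific members) makes an observed overlap more
  surprising, raising the pathway's competitiveness; w₁ = w₂ recovers
  exactly the central hypergeometric ORA. Benjamini–Hochberg FDR is
  applied across pathways.

## Worked example

The package ships a seeded synthetic generator that reproduces the
structure the method assumes: a scale-free weighted network, pathways
drawn from low-GN ("specific") or high-GN ("common") connectivity
strata, and an interesting-metabolite selection whose probability rises
with GN score, boosted 4× inside a planted pathway:

```python
from mpinet import (SimulationConfig, simulate_network, simulate_pathways,
                    simulate_interesting, run_mpinet)

cfg = SimulationConfig(seed=42, n_nodes=150, n_pathways=20,
                       planted_pathways=("pw1",), enrichment_multiplier=4.0)
net = simulate_network(cfg)                      # 150 nodes, 296 edges
coll = simulate_pathways(net, cfg)
interesting = simulate_interesting(net, coll, cfg)   # 36 metabolites
res = run_mpinet(interesting, net, coll)         # MPINetResults
print(res.summary(6))
```

```
MPINet pathway enrichment
  background N = 116, interesting n = 30, pathways K = 20
  GCS: beta = 0.5, lmax = 6; spline knots = 6; weight exponent = 6

pathway_id                  pathway_name  m1  g  relative_weight     w1    pvalue       fdr
       pw1  synthetic specific pathway 1  12  7           0.7909 0.2448 4.071e-06 8.143e-05
       pw6  synthetic specific pathway 6   5  2           0.7159 0.1346   0.01496    0.1496
      pw10 synthetic specific pathway 10   6  2           0.7502 0.1782   0.03706    0.2471
       pw9  synthetic specific pathway 9  10  2           0.7446 0.1704   0.09569    0.4785
       pw8  synthetic specific pathway 8  13  3           0.8455 0.3653    0.1648    0.5957
      pw14   synthetic common pathway 14   8  4            1.046  1.308    0.2218    0.5957
```

The planted pathway `pw1` tops the table (FDR 8.1e-05): 7 of its 12
members are interesting, and because its members sit in the low-GN
stratum its relative weight W = 0.79 gives w₁ = 0.24, amplifying the
overlap's surprise. `res.table` exposes the same rows as a DataFrame;
`res.bias_fit` holds the fitted spline; `res.to_tsv(path)` writes the
result table.

The same workflow is available from the shell:

```
mpinet simulate --output fixtures --seed 42
mpinet enrich --network fixtures/network.tsv --pathways fixtures/pathways.gmt \
              --metabolites fixtures/interesting.txt --output results.tsv
```

plus `mpinet build-network` (chemical-link TSV + background list →
network) and `mpinet scores` (network + list → GN / CGNB tables).

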