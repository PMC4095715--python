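# Methods

This note documents the models, numerical choices and open design
decisions behind `mpinet`, in the spirit of a statistical package's
methods appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Network construction

Chemical-association records (two compound identifiers plus an integer
combined confidence score on the 0–1000 scale) are parsed into a simple
undirected graph. Identifiers are canonicalized to bare PubChem CID
digit strings; `CIDs`/`CIDm` stereospecific and merged prefixes are
accepted and collapse to the same CID, so stereoisomer-level distinctions
are not preserved after canonicalization. Self links are dropped, and
for duplicate unordered pairs the maximum score is kept — both logged.
Edge weight = combined score / 1000 ∈ (0, 1]. No score threshold is
applied by default (`min_score = 0`); the flag exists because some
association databases are commonly thresholded at 400 ("medium
confidence"). Restriction to a user-supplied background metabolite
universe keeps an edge only when both endpoints are background members.

## Connectivity scores

**GCS.** The global connection strength between metabolites i and j is
the length-attenuated walk sum

    GCS = sum_{L=1..lmax} beta^(L-1) * A^L,    A = weighted adjacency,

with the diagonal zeroed afterwards. Walks (repeated vertices allowed)
rather than simple paths are summed: the family of communicability-style
connection-strength measures is walk-based, and matrix powers make the
computation exact and cheap, whereas simple-path enumeration is
exponential. `brute_force_gcs` re-derives the same quantity by explicit
recursive walk enumeration on graphs of ≤ 8 nodes and is the oracle in
the tests (agreement to 1e-10 on 50 random graphs).

Defaults `beta = 0.5`, `lmax = 6`: each extra step halves a walk's
contribution, and six steps exceed the typical diameter of the
small-world metabolite networks the method targets, so longer walks add
negligible weight. For `beta * spectral_radius(A) >= 1` the truncated
sum still converges (it is finite), but values become dominated by the
longest length class; the defaults keep the sum attenuation-dominated.
Dense matrices are used up to 5000 nodes, sparse accumulation beyond.

**GN score.** GN(i) = (1/(M−1)) Σ_{j≠i} GCS(i, j) over all other M−1
network metabolites, unreachable pairs contributing zero. Including the
zeros makes GN comparable across components; an isolated node scores
exactly 0.

## The monotone bias curve

The selection curve Ŷ(x) — the probability that a metabolite with GN
score x is detected-and-differential — is a natural cubic regression
spline with k = 6 knots at the (i−1)/(k−1) empirical quantiles
(linear-interpolation definition) of the GN distribution. The spline is
parameterized by its values at the knots (so the coefficient vector is
directly the curve heights), with natural boundary conditions and linear
extrapolation outside the knot range; the basis spans constants, which
makes the degenerate all-zero / all-one label fits exact. The penalty S
is the integrated squared second derivative in its Green–Silverman band
form, positive semidefinite with constants in its null space.

The fit minimizes ||Y − Xβ||² + λ βᵀSβ subject to first-difference
inequalities of the curve on a 200-point grid spanning the observed GN
range, solved as a small quadratic program (SLSQP with analytic
gradients, trust-constr fallback, then an exact KKT re-solve on the
active constraint set to remove solver slack). Monotonicity is exact on
the constraint grid; between grid points the cubic segments can dip by
~1e-7 at the fitted smoothness, which is why downstream assertions use a
1e-6 tolerance when evaluating off-grid. λ is chosen by generalized
cross-validation over a 40-point logarithmic grid (1e-6…1e6), computed
on the unconstrained ridge path — the standard practice of selecting
smoothness before applying shape constraints — with a fixed-λ override.
Because a least-squares fit to binary labels can leave [0, 1], Ŷ is
clamped post-fit; CGNB scores C = 1 − Ŷ are therefore proper
probability-like scores. Ties in GN receive equal Ŷ automatically since
the curve is a function of x.

## The weighted enrichment test

Pathway relative weight W and odds weight w₁ = W⁶ are computed as in the
README. The across-pathway mean of W is exactly 1 by construction (the
tests assert 1e-9). Pathway means and the denominator are floored at
1e-6; an all-C = 1 context (weights undefined) is an error. Background
members without a CGNB score (pathway metabolites outside the network
when an explicit background is supplied) contribute the background mean
of 1 − C, logged per pathway. The exponent 6 sharpens the weight
contrast between specific and common pathways and is exposed as
`weight_exponent`; 0 recovers unweighted ORA exactly.

The Wallenius noncentral hypergeometric upper tail is evaluated through
its integral representation. The raw integrand on t ∈ [0, 1]
concentrates its mass in a layer of width exp(−O(d)) near t = 0 once the
total remaining weight d is large, which defeats quadrature; the
substitution t = e^(−v) maps it to a smooth integrand on (0, ∞) bounded
by e^(−v) with its peak near v = n, where adaptive quadrature at
relative tolerance 1e-10 is reliable. Binomial factors are computed in
log space. Degenerate cases: g = 0 returns p = 1 (empty sum); n = N
returns p = 1 directly (every item drawn); configurations with a zero
binomial factor contribute nothing. The implementation is validated
three ways: exhaustive agreement with central hypergeometric tails for
all N ≤ 30 at equal weights (observed error ~1e-14), agreement with an
exact weighted-urn dynamic program (an independent route to the same
distribution), and Monte Carlo urn simulation.

Benjamini–Hochberg is implemented directly (it is part of the module
surface) and cross-checked against `statsmodels.stats.multitest` in the
tests. Output rows are sorted by ascending p with ties broken by pathway
id, making the pipeline byte-deterministic.

## Diagnostics

`pathway_gn_bias_test` compares member GN scores against the GN scores
of all network metabolites by Wilcoxon rank-sum (exact enumeration for
≤ 10 scored members, tie-corrected normal approximation otherwise).
Because the members also appear in the reference sample, the test is
slightly conservative when a pathway is a large fraction of the
universe; at realistic fractions (~1%, e.g. 10 members of 1000) null
p-values are indistinguishable from uniform (KS check in the acceptance
suite). `pathway_crosstalk` emits a pathway-pair edge when the mean GCS
over cross-set member pairs (same-node pairs excluded, so a duplicated
pathway reproduces its internal off-diagonal mean) exceeds the median of
all off-diagonal GCS entries. `overlap_pvalue` is the central
hypergeometric upper tail on the overlap of two pathway-id lists.

## Profile helpers

Differential selection uses the two-sided Wilcoxon rank-sum test per
metabolite (exact when the combined group size is ≤ 20 and tie-free,
tie-corrected normal otherwise; constant metabolites get p = 1 with a
warning) at the permissive default alpha = 0.1 appropriate for feeding
an enrichment analysis rather than reporting individual hits. The
drug-sensitivity screen correlates metabolite abundance with −log(GI50)
potency (Pearson, pairwise-complete, ≥ 3 shared samples; replicate
potency values averaged first) and applies BH at the deliberately
permissive default cutoff 0.6 — a screening threshold, not a
confirmatory one. Two-sided tests are used throughout.

## Synthetic data

The generator emulates the structure the method assumes, not raw
spectra: (i) a connected weighted network — Barabási–Albert scale-free
(m = 2) by default, matching the heavy-tailed degree distribution of
metabolite networks, or Erdős–Rényi on top of a random spanning tree —
with integer scores uniform on [150, 1000] scaled to weights; (ii)
pathways of 5–15 members drawn 80% from the low- or high-GN half of the
node ranking ("specific" vs "common" pathways, half each by default);
(iii) interesting metabolites selected independently with probability
clamp(base + bias_strength · GN_norm), defaults base 0.1 and slope 0.6,
multiplied inside planted pathways. Defaults (150 nodes, 20 pathways)
are desk-scale stand-ins for the thousands-of-nodes networks the method
targets; all stages derive their randomness from one integer seed via
numpy SeedSequence substreams `[seed, stage]`, so runs are reproducible
while stages stay independent.

The planted/decoy benchmark builds a purely low-GN planted pathway,
boosts its members' selection 4×, then assembles a decoy from high-GN
nodes with identical background-annotated size m₁ and identical
interesting-member count g. Plain ORA cannot separate the pair by
construction; the weighted test should. What passing this shows: the
weight mechanism correctly channels connectivity information into the
test. What it does not show: performance under annotation noise,
correlated selection, or ID-mapping loss, none of which the generator
models.

## Known limitations

- The exact functional form of the connection-strength modification and
  the spline basis/penalty used by the method's original authors are not
  fully specified in the published description; the walk-sum GCS and the
  natural-spline/curvature-penalty pair documented above are this
  package's defaults, chosen to be verifiable against independent
  oracles, and are configurable rather than asserted as the original
  choices. Likewise whether the original GN mean includes unreachable
  pairs (here: yes) and whether Ŷ is clamped (here: yes).
- The background universe defaults to the pathway member universe
  restricted to CGNB-scored (network) metabolites; with an explicit
  larger background, unscored members are mean-imputed, which dilutes
  weight contrast.
- K in the relative-weight denominator is the retained-pathway count of
  the loaded collection; analysing databases jointly vs separately
  changes W.
- The Wallenius tail is computed per pathway at quadrature tolerance
  1e-10; p-values below ~1e-12 should be read as orders of magnitude,
  not precise probabilities.
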