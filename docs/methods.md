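# Methods

## The problem

Circulating metabolite concentrations — here, fifteen mostly long-chain
fatty acids measured in serum — are strongly intercorrelated, and the
correlations alone cannot distinguish whether metabolite *A* regulates *B*,
*B* regulates *A*, or a third factor drives both. Inherited genetic
variation provides a natural experiment: genotypes are fixed at conception
and influence phenotypes, never the reverse. `gdagnet` exploits this
asymmetry at genome-wide scale. Strong instrumental variables are built as
principal components (PCs) of a pruned genome-wide SNP dosage matrix; a
constraint-based structure learner then infers a directed acyclic graph
(DAG) over {selected PCs} ∪ {traits} with the PC tier constrained to be
exogenous, and deleting the PC nodes leaves a fully directed causal network
over the traits. Network topology metrics and adjustment-based effect
estimates are computed from that network.

## Pipeline model and assumptions

**Traits.** The traits are assumed jointly Gaussian after normalization
(an optional rank-based inverse-normal transform is provided for raw input
tables), generated by a linear structural equation model (SEM) that is
acyclic and faithful: every conditional independence in the distribution
reflects d-separation in the generating DAG.

**Conditional-independence testing.** Fisher's z-transform of the sample
partial correlation: for variables *x*, *y* given set *S*,
`z = atanh(r_xy·S)` and `√(n − |S| − 3)·|z|` is compared with a standard
normal. The test level `alpha` defaults to 0.001 at every stage (skeleton
tests and instrument selection), so "edge" means an association surviving
p < 0.001. When `n < |S| + 3` the test is skipped with a warning and the
edge is retained (lack of data never removes an edge).

**Skeleton.** The stable variant of the PC algorithm: conditioning sets are
drawn from neighbourhoods frozen per level, and pairs are scanned in sorted
name order, making the result independent of input column order.
`max_cond` (default 3) bounds the conditioning-set size for tractability on
finite data; oracle runs use unbounded conditioning. Instrument–instrument
pairs are excluded a priori — PCs are mutually orthogonal by construction
and no edge between them is meaningful.

**Orientation.** Hard background knowledge first (every instrument–trait
edge leaves the instrument), then v-structures from separation sets, then
Meek's closure rules. The closure implements rules 1 and 3 in their
standard pattern form, replaces rule 2 by its acyclicity generalisation
(orient *x*→*y* whenever a directed path *x*⇝*y* already exists), and
implements rule 4 in the sound form: with an undirected edge *x*–*y*, a
chain *b*→*c*→*y*, *x* adjacent to *b*, and *b*, *y* nonadjacent, the
orientation *y*→*x* would force *b*→*x* and create the forbidden new
v-structure *b*→*x*←*y*, so *x*→*y* is compelled. If finite-sample errors
force both directions of an edge (conflicting v-structures), the edge is
dropped and logged rather than oriented arbitrarily.

**Fallback.** The final network must be fully directed. A trait–trait edge
left undirected after closure is oriented from the endpoint with more
selected instruments toward the other, ties broken lexicographically by
name; a fallback that would close a cycle is flipped. Every fallback is
logged and recorded in the orientation-provenance sidecar
(`constraint` / `v-structure` / `meek` / `fallback` per edge), so a user
can always distinguish data-identified directions from tie-breaks. On the
default synthetic cohort's exact covariance no fallback fires: two
instruments on the two source traits orient all 29 edges.

**Instrument construction.** LD pruning is a greedy left-to-right scan in
SNP order with a sliding window (default 100 SNPs): a SNP is dropped when
its dosage-scale r² with an already-retained upstream SNP exceeds the
threshold (default 0.80), the retained SNP acting as proxy. Monomorphic
SNPs and SNPs with call rate below 95% are dropped up front. Pruning is
idempotent and order-preserving. PCs are computed by SVD of the
standardized (mean-imputed) dosage matrix; each component's sign is fixed
by making its largest-magnitude loading positive. The candidate count `k`
defaults to 50. Selection runs a multiple regression of each trait on all
candidate PCs and removes the least significant PC until all remaining have
p < alpha; a PC is kept as an instrument if it survives for at least one
trait, and its per-trait associations are recorded. Joint-then-backward
selection per trait, with the union over traits, is this package's
reconstruction of "PCs remaining in the model" at a significance level; the
candidate count and the per-trait-versus-joint choice are both configurable
because neither is externally fixed.

**Effect estimation.** With the learned DAG taken as correct, the parents
of the exposure close every back-door path, so the OLS coefficient of the
exposure in `outcome ~ exposure + parents(exposure)` identifies the *total*
causal effect — in a linear SEM, the sum over all directed paths of the
products of edge weights. It equals the direct edge weight exactly when the
direct edge is the only directed path. Pairs with no directed path from
exposure to outcome are flagged structurally zero (the regression output is
still reported as a diagnostic). Standard errors are the usual homoscedastic
OLS ones. Exactly collinear adjustment covariates raise an error naming the
offending pair.

## Network parameters

For each node: out-degree, in-degree, connectivity = out + in, and the
maximum effect blocking step, formalised as the length in edges of the
longest directed path leaving the node, computed by the Bellman recursion
`steps(v) = 1 + max over children c of steps(c)` (0 at sinks) in one
topological sweep. The edge-count reading is used because it reproduces the
published worked example (a six-node chain gives its source 5 steps) and
every zero-out-degree row (steps 0). The published parameter table is not
internally consistent under *any* single-DAG reading of its steps column: a
node with 5 steps needs a child with 4, and no 4-step node is listed while
the two 5-step nodes both have in-degree 0 and therefore cannot parent each
other. The degree columns, which are self-consistent, are treated as the
table's authoritative content.

## The synthetic cohort

The generator emulates the study conditions: 2,479 samples, fifteen trait
variables named after the fatty acids, traits from a sparse acyclic
linear-Gaussian system, genotypes in LD blocks with some SNPs causally
upstream of the source traits.

* **Genotypes.** Dosages in {0,1,2} from two independent haplotype draws per
  person: within a block, each haplotype's latent Gaussians share an
  equicorrelation `within_block_r` (default 0.9), and an allele is minor
  when its latent falls below the MAF quantile (MAF uniform on
  [0.05, 0.5]). Blocks (default 10 SNPs; default 300 SNPs total, scaled far
  below a real array but preserving the block structure the pruning and PCA
  stages consume) are mutually independent. The dosage-scale correlation is
  a tetrachoric-type transform of the latent correlation — slightly below
  it except at the extremes 0 and 1, which are exact.
* **Traits.** Each trait is the weighted sum of its parent traits plus
  standardized dosages of its causal SNPs plus unit-variance Gaussian
  noise, evaluated in topological order. Edge weights are fixed positive
  values in [0.35, 0.8] cycling over the edge list: moderate effects that
  are detectable at n ≈ 2500 while keeping all paths mutually reinforcing,
  so no exact path cancellation can break faithfulness.
* **Genetic effects** attach to the two source traits, palmitoleate and
  margarate (two SNPs each, in distinct blocks, coefficients 0.6 and 0.45
  on the standardized-dosage scale), mirroring the premise that dietary
  source metabolites carry the strongest upstream (genetic + environmental)
  variation and letting genome-derived instruments orient everything
  downstream.
* **Reference networks.** Two 15-node, 29-edge DAGs ship with the package.
  `reported_degree_graph()` matches the published out-/in-degree profile row
  for row; its margarate node has a five-edge longest path terminating at
  laurylcarnitine and does not reach myristate. `default_trait_graph()`
  (the simulation default) reroutes one edge — margarate→oleate replacing
  margarate→eicosenoate — so that palmitoleate and margarate jointly reach
  all thirteen other traits. Both properties cannot hold in one DAG because
  the published table gives oleate in-degree 0 while the joint-influence
  claim requires every non-source node to be reachable; the package keeps
  both fixtures and is explicit about which is in use.

**What the simulation does not model:** population structure and admixture,
kinship, recombination-distance-dependent LD decay, haplotype phasing,
genotyping error, non-Gaussian or censored metabolite distributions,
batch effects, and selection bias. Passing recovery tests on this cohort
therefore demonstrates correctness of the algorithms under the model's
assumptions — not robustness of the method to the full complexity of a real
cohort.

## Numerical and design choices

* Partial correlations are computed from a correlation matrix via the
  precision of the 2+|S| submatrix (pseudo-inverse for safety); values are
  clipped to [−1, 1] and |r| = 1 is treated as dependent.
* Oracle mode declares independence when |partial correlation| < 1e−8.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (genotype and trait streams are
  separate children, so adding SNPs does not perturb trait noise).
* Determinism: sorted-name iteration everywhere in the learner, fixed PC
  sign convention, and a pipeline manifest carrying the config hash; two
  runs with equal seed and config produce byte-identical analysis
  artifacts.
* Test problem sizes (replicate counts of 20–50, n up to 8,000 for
  convergence checks, 300-SNP genotypes) are chosen so the full suite runs
  in about a minute while keeping Monte-Carlo standard errors well inside
  the asserted tolerances.

## Known limitations

* Constraint-based learning with `max_cond = 3` leaves extra edges around
  high-in-degree nodes at finite n; conflicts are resolved by dropping
  contested edges, so finite-sample networks can be sparser than the truth
  even while containing false positives elsewhere.
* The learned DAG is taken as fixed when estimating effects; uncertainty in
  the structure is not propagated into the standard errors.
* Robust/heteroscedasticity-consistent standard errors, latent-confounder
  models (FCI-style), and nonlinear CI tests are out of scope.
* VCF input supports biallelic GT-based dosages only.
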