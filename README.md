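# gdagnet

Genome-anchored causal network analysis for correlated metabolite traits.

Serum metabolite levels — the motivating case is a panel of fifteen mostly
long-chain fatty acids measured in ~2,500 individuals — covary strongly,
but correlation does not say whether metabolite *A* regulates *B*, *B*
regulates *A*, or something else drives both. Because inherited genotypes
influence phenotypes and never the reverse (the logic of Mendelian
randomization), genome-wide variation can anchor the *directions* of a
trait network. `gdagnet` implements that idea as a reusable pipeline for
statistical geneticists and systems biologists:

1. **LD pruning** — drop SNPs nearly perfectly correlated (r² > 0.80) with
   a nearby retained proxy;
2. **Instruments** — principal components of the pruned, standardized
   dosage matrix; keep PCs that survive per-trait backward elimination at
   p < 0.001;
3. **Structure learning** — a tiered PC-stable algorithm over
   {instruments} ∪ {traits} using Fisher-z partial-correlation tests, with
   instrument nodes constrained exogenous; v-structures and Meek closure
   orient the trait edges, and deleting the instrument nodes leaves a fully
   directed trait network;
4. **Topology metrics** — per node: out-degree, in-degree, connectivity
   (their sum), and the *maximum effect blocking step*, the length of the
   longest directed path leaving the node before every route is blocked at
   a sink;
5. **Effect sizes** — for exposure *X* and outcome *Y*, the OLS coefficient
   of *X* in *Y* ~ *X* + parents(*X*): the parents close every back-door
   path, so under the learned DAG this identifies the total causal effect
   (per-SD units when traits are standardized).

Under a linear-Gaussian structural equation model `x = Wᵀx + e` the implied
covariance is `(I − Wᵀ)⁻¹ D (I − Wᵀ)⁻ᵀ`; the package can run its learner
directly on that exact covariance ("oracle mode") to separate algorithmic
behaviour from sampling noise, and ships a synthetic-cohort generator
(LD-block genotypes, SEM traits, genetic effects on the source traits) with
serialized ground truth for recovery testing. Two 15-node, 29-edge
reference networks over the fatty-acid names are included; see
`docs/methods.md` for their construction and every modelling decision.

## Worked example

Learn the network from the exact covariance of the default synthetic
cohort, then inspect the outputs:

```sh
gdagnet run-all --oracle --out-dir run1 --seed 1
# learned 29 edges over 15 traits -> run1
```

`run1/metrics.tsv` (the network-parameter table):

```
metabolite         out_degree  in_degree  connectivity  max_effect_blocking_steps
Myristate                   3          1             4                          3
Myristoleate                1          2             3                          1
Palmitate                   3          2             5                          2
Palmitoleate                5          0             5                          5
Margarate                   5          0             5                          5
...
Dihomo-linoleate            0          6             6                          0
Laurylcarnitine             0          3             3                          0
```

Palmitoleate and margarate have the maximum out-degree (5), in-degree zero,
and the deepest reach (5 steps): interventions on them propagate through
the whole network, and jointly they influence all thirteen other
metabolites. Dihomo-linoleate, despite the highest connectivity (6), has
out-degree zero — a pure endpoint where effects are blocked.

Effect sizes of margarate on its local (child) metabolites, from
`run1/effects.tsv`:

```
 exposure         outcome  estimate       se     n
Margarate  Heptadecanoate     0.604   0.0227  2479
Margarate Laurylcarnitine     0.535   0.0255  2479
Margarate      Linolenate     0.502   0.0273  2479
Margarate          Oleate     0.685   0.0158  2479
Margarate       Palmitate     0.703   0.0185  2479
```

Each estimate is the total causal effect implied by the simulated system
(direct weight plus any parallel directed paths; e.g. 0.703 on palmitate ≈
direct 0.4 plus indirect routes), with its OLS standard error at n = 2479.

The same subcommands run on real data: `simulate`, `prune`, `instruments`,
`run-all`, `metrics`, `effects`, `export` (TSV/GraphML/DOT). Inputs are
plain TSV (samples × SNP dosages; samples × traits) or VCF genotypes.

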