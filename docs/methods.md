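# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `toxomix`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Study design emulated by the generator

`syndata.simulate_study` draws one synthetic inhalation study: six exposure
arms (Sham, 3R4F, CHTP, THS, Cessation, Switch) x three time points (3, 4,
6 months) x nine animals, five molecular layers measured on the same
animals. Proteomics is available for eight of the nine animals per arm,
metabolomics only at 3 and 6 months, and each (sample, modality) cell
additionally drops out completely at random with probability 0.02. Desk-
scale feature counts default to 2000 mRNAs, 500 proteins, 200 metabolites,
150 lipids and 100 miRNAs — a configurable scale-down of the full study
(~17,500 / 5,000 / 670 / 400 / 360).

Data follow a planted linear factor model per modality,
`Y_m = Z W_m' + e_m`, on log2 scale. Factor 1 is the shared exposure
factor: its score mean is 3.0 for the smoke arm at every time point, 50%
of that for Cessation/Switch at 3 months decaying to 25% at 6 months
(partial reversal), and 0 for Sham and the two heated-tobacco arms;
per-animal scores add N(0, 0.5^2). Factors 2 and 3 are metabolite- and
lipid-specific with zero group structure; the metabolite factor is made
slightly stronger (loading scale 0.7 vs 0.55) so the recovered ordering by
variance explained is stable across seeds. Loadings are Gaussian on a
random active subset per modality (35-50% of features). For genes measured
both as mRNA and protein the factor-1 loadings are correlated with
rho = 0.75; together with the per-modality noise levels (sd 0.5-0.7 in
log2 units) this calibrates the gene-matched mRNA/protein fold-change R^2
to a 20-seed mean inside [0.30, 0.47], the range reported for matched
transcriptome/proteome exposure responses. The calibration is a property
of the generator, not a claim about any real dataset.

Native scales: metabolite and lipid matrices are exponentiated (log-normal
abundances); lipids are additionally multiplied by a per-sample total
protein amount (Uniform(1.5, 2.5) mg), which preprocessing divides out
again. Metabolite entries below the per-feature 10th percentile are
censored at an elevated rate to emulate below-detection missingness (3%
overall). A BALF total immune-cell covariate is affine in the factor-1
score (intercept 200, slope 150, Gaussian noise sd 80, truncated at 0).
Planted truth (scores, loadings, active sets, covariate parameters,
perturbation directions) is always emitted; downstream validation reads
truth, never the data.

Companion resources: the interaction generator wires factor-1-active
features into (by default) 12 internally connected "signal" modules with
high-confidence STRING-style scores, active metabolites/miRNAs attached
inside one module each; background links are random, with each background
metabolite/miRNA used at most once and background links never joining two
signal genes directly (links touching a signal gene are capped below the
high-confidence threshold). This keeps distinct planted modules more than
one edge apart, which is what makes the tree count of the Steiner forest
informative at the grid-search stage; with `connectivity_enrichment=0`
planted features are wired exactly like background (verified by a degree
permutation test). Gene sets (sizes 10-200) include signal sets drawn from
the positive-loading active genes, so they are coherent in the signed
weight ranking that the GSEA stage consumes. Causal network models have a
20-node signed backbone (spanning tree plus 10 extra edges, edge sign
d_i * d_j for planted node directions d) and 25 disjoint downstream genes
per node drawn preferentially from active mRNAs, with downstream sign
d_i * sign(loading); simulated fold changes are therefore coherent with
the network.

## Differential abundance

Preprocessing: lipids are divided by the sample's total protein and log2
transformed; metabolite missing values in measured samples are imputed as
that metabolite's observed minimum before log2 (metabolites with no
observed value are dropped with a warning); mRNA/miRNA/protein are already
log2 and pass through. Imputation and normalization touch only the
documented entries and preserve feature/sample order.

Each exposure arm is compared with the Sham arm at the same time point by
a two-group equal-variance linear model per feature, pairwise-complete
over available samples; features missing in more than half of either arm
are excluded and logged. Variances are moderated by Smyth-style moment
matching on log s^2: d0 solves
`trigamma(d0/2) = max(0, var(log s^2) - trigamma(d/2))` by monotone Newton
iteration (tolerance 1e-8, <= 50 iterations; d0 = infinity when the excess
spread is at or below tolerance, and s0^2 equals the common value when the
variances are literally identical). Moderated t has d0 + d_g degrees of
freedom; p-values are two-sided; BH-FDR is applied within each
(modality, contrast) family and features with adjusted p < 0.05 are
flagged. The estimator agrees with limma's `eBayes` to machine precision
on shared data (tested via Rscript). At d0 = 0 the statistic reduces to
the ordinary pooled t; at d0 = infinity all posterior variances equal s0^2.

## Network perturbation amplitude

Backbone differential values are sign-adjusted means of measured
downstream log2 fold changes, `f_i = mean_g s_ig b_g`; nodes without
measured downstream genes get f_i = 0 with a warning. The amplitude is the
quadratic form

    NPA = (1/|E|) sum_{(i,j)} w_ij (f_i - s_ij f_j)^2 + (1/|V|) sum_i f_i^2,

a deliberate simplification of the published NPA methodology (whose exact
equations live in dedicated papers): a signed-edge disagreement energy
plus a node energy. It is zero exactly on zero input, invariant under node
relabeling, and scales as c^2 when fold changes scale by c. Companion
statistics (all alpha = 0.05, permutation count >= 100 enforced, default
500):

* O statistic — genes are randomly reassigned to downstream slots (sizes
  and signs preserved); p_O is the upper tail. Tests that the amplitude
  depends on which genes sit downstream of which node.
* K statistic — the backbone is rewired degree-preservingly (edge swaps,
  signs riding with the edge slots); because a coherent perturbation
  minimizes the signed disagreement term, topological coherence appears in
  the lower tail, and p_K is defined as the lower-tail probability.
* replicate statistic — a ContrastTable carries standard errors, not
  animals, so the default is parametric: the 95% CI comes from resampling
  beta* ~ N(beta_hat, se^2) and p_replicates is the noise floor
  P(NPA(beta* ~ N(0, se^2)) >= NPA_obs). An animal-level bootstrap is used
  when the raw layer and sample sheet are supplied.

Both permutation p-values are uniform under an i.i.d. Gaussian null
(KS-tested over 20 seeds). BIF sums each network's NPA normalized by that
network's maximum over contrasts, with equal weight per network;
non-significant NPAs (any companion statistic) contribute zero — the
original aggregation's treatment of non-significant scores is not
documented, so this rule is a package choice, flagged as such.
RBIF = 100 * BIF / max BIF.

## Latent factor model

`MultiOmicsFactorModel` is Gaussian group factor analysis with ARD:
`y_mjn ~ N(w_mj' z_n, 1/tau_m)`, `z_n ~ N(0, I)`,
`w_mjk ~ N(0, 1/alpha_mk)`. Inference is variational EM with closed-form
coordinate updates for q(W) (one K x K solve per view), q(Z) (one solve
per missing-data pattern), and point updates for alpha (ARD) and tau.
Samples absent from a view contribute nothing to that view's updates —
missing sample-modality blocks are exact, and injecting garbage into a
masked block provably changes nothing (tested). Entry-level holes inside
an observed column are mean-imputed after centering. Each view is centered
per feature and scaled to unit total variance so no layer dominates (the
original report does not state its view scaling; this is our default).

Defaults: K_init = 10, tolerance 1e-6 on the relative ELBO change, at most
500 iterations, factors with < 0.1% variance explained in every view
dropped at convergence, factors ordered by total variance explained, sign
fixed so the largest-|weight| entry is positive. Initialization is an SVD
of the concatenated zero-filled views plus a seeded 1e-6 jitter; fits are
deterministic given the seed. The ELBO is computed exactly each iteration
and is non-decreasing (asserted in tests); tau is capped at 1e10 to keep
noiseless fixtures finite. This is a reimplementation with its own
defaults, not a port of any released factor-analysis package.

Variance explained is `R2_mk = 1 - SS(Y_m - z_k w_mk') / SS(Y_m)` over
observed entries, clipped at 0. sGCCA uses complete-case samples (rows
missing any view are dropped and logged), per-feature standardization, a
fully connected design, alternating updates hard-thresholded to the
`keep = 30` largest absolute entries (ties broken by feature index),
tolerance 1e-6 / 200 iterations, and canonical-mode deflation of each
block by its own score. PCA mean-imputes missing entries per feature, for
the PCA only.

## Association network and PCSF

Interaction records are filtered per source (STRING combined score
strictly > 0.7; mirTarBase >= 2 publications and >= 2 non-high-throughput
methods; KEGG unconditional), then costed (0.1 for KEGG/mirTarBase,
(1 - score) + 0.1 for STRING), with self-loops dropped and parallel edges
collapsed to the minimum cost (the duplicate policy is our choice). mRNA
and protein features of one gene collapse onto a single gene node.

Terminals: per modality, |weights| of the chosen factor are normalized by
the modality maximum; "expected by chance" is the mean normalized weight
within the modality (the normalization and the null are not defined in the
original description; both are configurable here); features at >= 2x the
expectation are kept, truncated to the top 200, with the normalized weight
as prize. When mRNA and protein nominate the same gene the larger prize
wins.

The solver minimizes
`sum_e c_e + mu sum_v deg(v) + omega #trees - beta sum_v p_v` over forests.
Instances with <= 12 nodes are solved exactly by subset enumeration (for a
fixed node set the optimal edges are the induced MST with every edge
costlier than omega split into a new tree). Larger instances use
Goemans-Williamson moat growth on a virtual-root graph (root edges cost
omega; at event-time ties root edges merge first), followed by strong
pruning with the same edge-splitting rule, a metric-closure Steiner-MST
candidate on instances up to 400 nodes, profitable-singleton completion,
and a polish step (optimal edges for the final node set, removal of
unprofitable leaves). The best candidate by exact objective wins; ties
break by node count then lexicographic node ids. On 50 random <= 12-node
instances the heuristic is within 5% of the optimum on all and exact on
>= 90% (in the shipped run, 249/250 across seeds). The reported objective
is re-derived from the node/edge lists to 1e-9 on every solve.

Grid search records coverage and tree count over omega in {0.2..1.0} x
beta in {100..2000} with mu fixed; "saturation of percent covered with a
decent number of trees" is formalized as: per omega whose tree count lies
in [3, 30], the smallest beta whose coverage gain over the previous beta
step is < 2 percentage points (the smallest beta qualifies when the next
step adds nothing); across omegas the highest coverage wins, ties to
smaller omega then smaller beta; if no grid point is in the band the
best-coverage point is returned with a warning. The ensemble multiplies
each edge cost by (1 + u), u ~ Uniform(-r, r) i.i.d. per run (the
published randomized variant's noise law is unstated; multiplicative
uniform is our choice), and unions the 10 runs with per-node/edge
selection frequencies. Clustering is Girvan-Newman edge betweenness
(igraph, costs as distances) with the dendrogram cut at maximal
unweighted modularity; singleton communities are allowed and disconnected
components are never merged.

## Enrichment

Preranked GSEA uses the weighted KS running sum with weight exponent 1,
ranking by the signed factor weight vector (mRNA and protein analyzed
separately); ties in the statistic are broken by gene id with a warning.
The null permutes gene labels preserving set size — simpler than the
multilevel split refinement of the fgsea algorithm and adequate for
n_perm <= 1e5; the minimum attainable p is 1/(n_perm + 1). NES divides ES
by the mean |null ES| of matching sign; BH is applied across sets;
set-size bounds default to [10, 500]. ORA is the one-sided hypergeometric
tail with Haldane-corrected odds ratios, verified against direct
enumeration on all universes <= 30.

## Pipeline

One global seed is expanded into named per-stage substreams
(`SeedSequence([seed, crc32(stage)])`), so adding a stage never perturbs
another stage's randomness and identical config+seed reproduce the report
bit-identically (hash-asserted). Default problem sizes are the desk-scale
dims above with 500 NPA permutations, 2 causal networks, 300 factor-model
iterations, 1000 GSEA permutations, the full 5 x 5 grid and 10 ensemble
runs; a full run takes well under a minute on one CPU and the test suite
runs in about half a minute.

## Limitations

* The generator plants linear Gaussian factor structure; it does not
  emulate count noise, batch effects, probe-level artifacts, or any raw
  instrument processing, so passing tests demonstrate correctness of the
  analysis machinery, not robustness to real-data pathologies.
* The NPA quadratic form, the BIF zeroing rule, the PCSF saturation
  criterion, the view scaling and the ORA/GSEA input conventions are
  documented package choices where the original description is silent;
  results at those points are not comparable to the original pipeline
  beyond qualitative behaviour.
* The real KEGG/STRING/mirTarBase databases and Reactome release are out
  of scope; interaction tables are synthetic emulations of their schemas
  and filter semantics.
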