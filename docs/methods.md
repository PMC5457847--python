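# Methods

## Scope

`riskmir` turns case/control expression matrices (mRNA and miRNA), a
pathway collection (GMT), a validated miRNA→target table and a PPI edge
list into: differentially expressed genes and miRNAs, consensus risk
pathways, risk genes, significant miRNA–pathway pairs, a tripartite
regulatory network with topology ranking, cross-validated single-feature
AUCs, and a cross-species DE-miRNA comparison. Matrices are assumed to be
log2-scale, normalized intensities; raw-array (CEL) processing, identifier
conversion and target prediction are out of scope.

## Preprocessing

At load time each matrix is screened for missing values (default: drop any
feature with ≥1 missing cell; a tolerated fraction is configurable, with
surviving gaps imputed by the feature mean) and rows sharing a feature id
(multiple probes per gene) are averaged element-wise into a unique value.
Identifier matching is exact and case-sensitive for genes; miRNA case and
species prefixes are handled only in the cross-species stage.

## Differential expression

*Per study.* Default is the Welch unequal-variance *t* with
Welch–Satterthwaite degrees of freedom; log2FC is case mean − control
mean. Welch is preferred because the miRNA cohort is strongly unbalanced
(33 vs 58). Degenerate zero-variance contrasts yield t = 0, p = 1 when the
means agree, and p = the smallest representable double with a `degenerate`
flag when they differ.

*Moderated alternative.* An empirical-Bayes moderated *t* shrinks the
pooled per-feature variance toward a prior (d₀, s₀²) estimated by moment
matching of the log sample variances: with e_g = ln s²_g,
Var(e) − ψ′(d/2) estimates ψ′(d₀/2) (solved by Newton on the inverse
trigamma) and the mean of e, digamma-corrected, gives s₀². When the log
variances show no excess spread the prior df is infinite and s₀² is taken
as the common sample variance, so the moderated statistic reduces to the
pooled-variance *t* — the shrinkage fixed point. Fewer than 10 features
fall back to Welch with a logged warning.

*Meta-analysis.* Studies are combined per feature with Fisher's method,
X² = −2Σ ln pᵢ referred to χ² with 2k df. The method is fixed as the
package default because it is classical and closed-form; the consensus
log2FC is the inverse-variance weighted mean, and features whose per-study
fold changes disagree in sign are flagged discordant.

*Calling rules.* Human rule: raw p strictly below .05, no fold-change
filter (BH-adjusted p is reported alongside). Rat rule: p ≤ .05 AND linear
|fold change| ≥ 2.0, both inclusive. The strictness of each inequality is
deliberate and pinned by boundary tests.

## GSEA

Genes are ranked by signal-to-noise, (μ꜀ − μₙ)/(σ꜀ + σₙ), each group σ
floored at max(0.2·|μ|, 0.2); ties are broken lexicographically by feature
id so rankings are deterministic. The running sum advances at set members
by |metric|^w normalized over the set's hits (w = 1 by default; if all hit
metrics are zero, equal weights are used) and retreats at non-members by
1/(N − N_hits); the enrichment score is the signed extremum of the walk
(the larger of |max| and |min|, ties to the positive side). The leading
edge — the set's "core genes" — is the members at or before the walk
maximum for ES > 0 and strictly after the minimum for ES < 0.

Nominal significance uses phenotype permutation (default 1000 label
shuffles, shared across pathways so each permutation re-ranks once) with a
sign-aware pseudo-count estimator:
p = (1 + #{|ES_perm| ≥ |ES_obs|, same sign}) / (1 + #{same-sign perms}).
If the design admits fewer distinct label assignments than permutations,
sampling is with replacement and logged. A pathway is a risk pathway when
its nominal p is below .1 in strictly more than half of the datasets; with
two mRNA studies this means both. NES normalization and FDR q-values are
intentionally omitted — the consensus rule operates on nominal p.

## Risk genes, pairs, triples, network

Risk genes are the exact intersection of the leading-edge genes of the
risk pathways (union over datasets and pathways) with the DEGs. For each
DEmiR *i* and risk pathway *A*, the overlap *x* between the K background
targets of *i* and the M background members of *A* is scored by the
upper-tail hypergeometric probability P(X ≥ x | N, K, M), computed with
log-gamma terms and a log-sum-exp for stability. The background N defaults
to the genes measured on the mRNA platform intersected with the union of
the target-map and pathway universes. BH adjustment spans the whole
miRNA × pathway table; pairs with adjusted p < .05 are significant (a flag
restores the raw-p reading); the number of miRNAs tested (I) is carried as
bookkeeping.

Triples (m, g, A) require m ∈ DEmiRs with (m, g) in the target map,
g a risk gene and member of A, and A a risk pathway; a miRNA–gene pair is
*opposite* when the two directions differ. The network has typed nodes
(miRNA/gene/pathway) and edges (targets/member_of/ppi); PPI edges are
overlaid only between risk genes that appear in at least one triple.

Topology follows the Cytoscape NetworkAnalyzer conventions: unnormalized
betweenness with each unordered pair counted once, component-wise
closeness (n_reachable − 1)/Σd, local clustering 2T/(k(k−1)), per-node
mean shortest-path length over reachable nodes, and the topological
coefficient TC_v = mean over nodes u sharing ≥1 neighbor with v of
(shared(v,u) + [u~v])/deg(v), zero below degree 2. Because it is ambiguous
whether published topology tables are computed on the composite network or
the whole PPI network, both are available; the default ("mixed") measures
gene nodes in the whole PPI network and miRNA/pathway nodes in the
composite network. Hubs are the top 3 nodes by degree, ties broken by
betweenness then id.

## Biomarker evaluation

Stratified 5-fold cross-validation per feature, seeded and deterministic:
a univariate logistic score is fit per training fold and applied held-out;
the pooled (not fold-averaged) out-of-fold scores give the ROC and the
Mann–Whitney AUC (ties counted half). The logistic score was chosen as the
simplest model that makes cross-validation meaningful for one feature; a
raw-expression mode (no fitting) is provided, and since AUC is invariant
under monotone transforms the two agree up to the sign learned by the
fold models. Gene features are evaluated on the studies pooled over their
shared features (the combined 18v18 design); miRNA features on the miRNA
study.

## Cross-species comparison

Matching is purely lexical: lowercase, strip a three-letter species prefix
(hsa-, rno-, mmu-, …) when the remainder is a miR/let name, preserve the
-5p/-3p arm suffix verbatim. Arm suffixes must match exactly by default
(a collapse flag exists) because arm-resolved ids denote distinct mature
strands. No ortholog database is consulted.

## Synthetic data generator

The generator emulates the cohort structure the analysis targets: two
9 vs 9 mRNA studies, one 33 vs 58 miRNA study and an optional 2 vs 2 rat
miRNA experiment, Gaussian log2-intensity noise (sd 0.5) around per-feature
baselines (N(7, 1.5²)), and additive signed log2 effects (1.0) for planted
DE features — 10% of genes and of miRNAs by default. Each planted risk
pair consists of a pathway (12–18 members) whose genes all share a common
case-shift, making the set detectable by GSEA, and a DE miRNA targeting
80% of that pathway on top of a Poisson(20) background target set — an
inside-pathway target density far above 5× background. The PPI network is
Barabási–Albert preferential attachment (m = 2) over the gene universe.
The rat arm plants 4 shared miRNA families, up-regulated in both species
(effect 2.5, sd 0.3), plus rat-only DE families; with only 2 arrays per
group the rat *t* test has limited power, which the pipeline inherits by
design — small animal cohorts genuinely constrain such comparisons.

Two structural choices keep the planted truth uniquely recoverable: null
pathways are drawn (with overlap among themselves) from genes that are
neither planted-DE nor members of planted pathways, and background miRNA
targets avoid planted-pathway genes. Otherwise scattered DE genes or
chance targets inside null pathways would create legitimate risk signal
absent from the truth record, and no pipeline could match the truth
exactly. The price is realism: in real data DE genes do sit in unrelated
pathways and miRNAs do target enriched pathways by chance, so passing the
plant-recovery tests demonstrates correctness of the machinery under
identifiable conditions, not field performance on real cohorts. The
generator also omits probe-level artifacts, batch effects and correlation
structure beyond the pathway-coherent shifts.

## Determinism and numerics

A single global seed fans out into per-stage seeds through a seed
sequence; every stochastic component (simulation, permutations, CV folds)
is reproducible bit-for-bit for a fixed seed. Hypergeometric tails are
exact to ~1e-12 against combinatorial enumeration for small populations;
the GSEA walk ends at 0 within 1e-9 by construction; BH adjustment is the
step-up definition with a cumulative minimum. Degenerate inputs (empty DE
sets, empty risk-pathway sets, disjoint cores) downgrade downstream stages
to warned no-ops rather than errors.

## Problem sizes

The default bundle (2000 genes, 150 miRNAs, 15 pathways, 1000 GSEA
permutations) fits in well under a minute on one core; the test suite's
calibration checks use reduced designs (hundreds of features, 100–200
permutations, 50–200 replicates) chosen so each check retains clear
statistical resolution.
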