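# Methods

`kinfold` implements a genomic-prediction analysis for pedigreed, SNP-genotyped
livestock populations: marker effects are estimated from weighted deregressed
breeding values with a BayesC Gibbs sampler, cross-validation folds are built
by K-means clustering of pedigree dissimilarities so that training and
validation sets are as unrelated as the population allows, and the resulting
direct genomic values (DGV) are scored for accuracy, bias, blending value and
genetic correlation with the trait. This note records the model, its
parameters, the synthetic study population, and the numerical choices.

## Input preparation

**EBV and reliability.** Published expected progeny differences are doubled to
the EBV scale; Beef Improvement Federation accuracies convert to reliabilities
as r² = 1 − (1 − BIF)².

**Genotype QC.** Animals with call rate < 95% are removed first. Loci are
removed if call rate < 90%, minor allele frequency < 1%, or the
Hardy-Weinberg Pearson χ² (1 df, expectations p², 2pq, q² from sample allele
frequencies) exceeds 300; the three criteria overlap and the QC report counts
each separately. Remaining missing dosages (<1% in the intended regime) are
replaced by the per-locus mean — at that missingness the choice of imputation
method is immaterial downstream, and real-valued dosages are accepted by the
sampler.

**Deregression.** An animal's EBV mixes its own information with its parent
average (PA). Training on raw EBV would double-count family information, so
each record is deregressed: with λ = (1 − h²)/h², the two-equation
mixed-model system in (PA, individual) has coefficient matrix

    C = [[Z'Z_PA + 4λ, −2λ], [−2λ, Z'Z_i + 2λ]],

where the effective data contents Z'Z_PA, Z'Z_i are solved (numerically, with
the classical closed forms α = 1/(0.5 − r²_PA), δ = (0.5 − r²_PA)/(1 − r²_i)
as exact starting values) so that the model-implied reliabilities match the
published ones: r²_PA = 0.5 − λ(C⁻¹)₁₁ and r²_i = 1 − λ(C⁻¹)₂₂. The
right-hand side y = C·(g_PA, EBV)′ then yields the deregressed proof
DEBV = y_i / Z'Z_i with reliability r*² = Z'Z_i/(Z'Z_i + λ) and analysis
weight

    w = (1 − h²) / ((c + (1 − r*²)/r*²) · h²),

where c is the fraction of genetic variance not captured by markers
(default 0.5, a common choice for 50K panels; with c = 0 the weight reduces
exactly to the effective record count Z'Z_i). Records whose own reliability
does not exceed the PA reliability carry no individual information and are
excluded. When r²_i > 4·r²_PA the exact solution has Z'Z_PA < 0 (the PA
carries less information than the cross-equation prior implies); the
deregressed proof remains well defined but the adjusted PA does not and is
flagged. Unknown parents contribute zero information; with both parents
unknown the EBV passes through unshrunk.

**Adjusted parent average.** PA_adj = y_PA / Z'Z_PA is the PA-side
deregressed information — the parental evidence with the genotyped animal's
own contribution excluded. In the limit of an animal with no own information
it converges to the *de-shrunk* parent average g_PA(Z'Z_PA + 2λ)/Z'Z_PA, not
to g_PA itself: an EBV equal to its PA contains no Mendelian-sampling
deviation to remove, and what remains is the PA pseudo-record with BLUP
shrinkage undone. Its reliability is reported by the clipped heuristic
2·Z'Z_PA/(Z'Z_PA + 4λ); the construction is one defensible reading of the
deregression machinery and is labelled as such.

## Relationship structure and folds

The numerator relationship matrix A is built by the tabular method over the
complete ancestor pedigree and then restricted to the genotyped animals, so
all ancestral pathways are accumulated; unknown parents are unrelated,
non-inbred founders. Founders appearing only once as a parent are pruned to a
fixed point (pruning cannot change relationships among the remaining
animals, which a test asserts). The pedigree distance is
d_ij = 1 − a_ij/√(a_ii·a_jj), which removes inbreeding from the scale and
zeroes the diagonal.

K-means clustering uses the Hartigan-Wong transfer algorithm (written here,
with k-means++-style seeding and best-of-`n_start` restarts, default 25)
on the rows of D: each animal's feature vector is its distance profile to
every other animal. Fold quality is diagnosed with a_max — each animal's
maximum relationship to each group — which should be high within and low
between groups under K-means and show no contrast under random folds.
Random folds split a permutation into near-equal groups; the age split
chooses the smallest birth-year threshold putting at least 20% of animals in
the validation (younger) side, ties going to training. Every scheme yields
leave-one-group-out folds, so each animal's DGV is predicted without its own
DEBV.

## Marker-effect model

For training records y_i (DEBV) with weights w_i:

    y_i = μ + Σ_j z_ij u_j + e_i,   Var(e_i) = σ_e²/w_i,
    u_j = 0 with probability π;  u_j ~ N(0, σ_u²) with probability 1 − π,

with scaled inverse-χ² priors on σ_u² (ν_u = 4) and σ_e² (ν_e = 10). Prior
scales are seeded from a preliminary full-data chain: σ̂_g² (the posterior
mean across-animal variance of fitted genetic values) spread over the
expected (1 − π)·k included markers, and σ̂_e² directly. That same
preliminary analysis supplies σ̂_p² = σ̂_g² + σ̂_e², the phenotypic variance
used later for accuracy. Defaults follow routine practice for 50K panels:
π = 0.995, 41 000 iterations, 1 000 burn-in; the test suite and the bundled
analyses run scaled-down chains (1 500–4 000 iterations) and π = 0.98 on the
1 000-marker panel, keeping the same expected number of included markers per
map length.

Each Gibbs sweep updates μ from its weighted normal full conditional, each
marker in fixed map order (inclusion via the marginal-likelihood odds, then a
normal draw), and the two variances from their full conditionals; the
residual vector is updated incrementally and the numerics run in a compiled
(numba) kernel with a seeded generator, so chains are bit-reproducible.

**Dosage centering.** Marker columns are centered at their training means
before sampling. This is a pure reparameterization — (μ, u) →
(μ + Σ_j z̄_j u_j, u) leaves the model unchanged — but without it the
intercept and the marker-mean sum form a nearly flat likelihood direction
that random-walks, leaving each fold's DGV with an arbitrary additive offset
large enough to destroy statistics pooled across folds. Predictions subtract
the same training means, so within a fold DGV differ from the raw
Σ z_ij û_j score only by a constant.

DGV are the linear scores of posterior-mean effects; validation loci must
match training loci exactly.

## Validation statistics

Genetic variance is σ_g² = h²σ_p² with h² the published trait heritability
and σ_p² from the preliminary analysis. Accuracy is the pooled estimator

    ρ̂ = cov(DEBV, DGV) / sqrt(σ_g² · var(DGV)),

with covariance and DGV variance centered within contemporary groups (5-year
birth bins anchored at the minimum birth year; groups with fewer than two
animals dropped) and pooled by degrees of freedom, so genetic trend across
birth cohorts cannot inflate the correlation. Bias is the plain OLS slope of
DEBV on DGV (expected 1; no contemporary groups, matching the reporting
convention of the analysis this follows). Blending regresses DEBV on
(PA_adj, DGV) with fold-group × birth-bin classes as fixed effects, giving
GEBV = b₁·PA_adj + b₂·DGV.

The bivariate animal model treats (DEBV, DGV) as two traits sharing the
pedigree: fixed effects are a mean for DEBV and fold-group classes for DGV;
additive effects have covariance G0 ⊗ A; the DEBV residual carries the
reliability weights (σ_e1²/w_i) and the DGV residual is homoscedastic, the
two uncorrelated. Weights are normalized to mean 1 at input so σ_e1² is on
the record scale (heritability under heterogeneous weights is otherwise not
well defined). Estimation is EM-REML with average-information acceleration:
EM steps guarantee a non-decreasing restricted likelihood; AI (Newton) steps
are attempted after three EM warm-up iterations and accepted only if the
likelihood does not decrease, with step halving and projection of the genetic
covariance onto the positive-definite cone (eigenvalue floor 10⁻⁶·trace).
Convergence is |ΔlogL| < 10⁻⁶; boundary problems (DGV residual → 0) converge
slowly and may need a larger iteration cap. Standard errors come from the
inverse AI matrix at the optimum; r_g, h²_DGV and h²_T standard errors by the
delta method. Because DGV are linear combinations of other folds' DEBV, the
joint covariance can approach singularity; the fit surfaces a condition
warning rather than attempting a remedy.

## The synthetic study population

Real national-evaluation data of this kind are proprietary, so the package
ships a generator that emulates the features the analysis depends on. The
default ("tiny") scale is chosen for a complete desk-scale study:

| parameter | default | role |
|---|---|---|
| mainstream population | 10 sires/generation × 192 offspring, 5 generations | large patrilineal half-sib families in one interconnected population |
| immigrant dams | 35% of matings | keeps mainstream inbreeding near observed levels (F ≈ 0.02–0.04) |
| closed herd | 12 founders → 30 head, 10 closed generations | isolated inbred subpopulation, mean F ≈ 0.1–0.2, zero relationship to the mainstream |
| genome | 10 chromosomes × 1 Morgan, 100 panel markers each | Haldane crossovers, LD from 32-haplotype ancestral mosaics |
| trait | 400 QTL, hidden (off-panel), effects N(0,1) rescaled to σ_g² = 1 | polygenic; the panel tags QTL only through LD |
| closed-herd ancestry | private haplotype pool (same frequencies) | distinct LD phase, so marker effects do not transfer into the herd |
| records | reliability ~N(0.7, 0.15²) clipped to (0.05, 0.95) | a well-recorded trait; h² = 0.5 |
| panel | youngest 3 generations (~666 animals) | genotyped bulls skew to recent birth years |

EBV records are generated by the forward model that deregression inverts:
an animal's own information is x_i = TBV_i + e_i with Var(e_i) = λσ_g²/Z'Z_i
(so its deregressed reliability is exactly the target), and the published EBV
blends x_i with the parent average of the parents' generated EBVs through the
same two-equation system. Deregressing a generated record therefore recovers
TBV plus reliability-calibrated noise with no de-shrinkage pathologies.
`resample_trait` draws fresh effects on the same hidden QTL, giving multiple
traits on one population the way recorded traits share one genotyped herd.

What the generator does **not** emulate: multi-generation EBV consistency
beyond the immediate parent average (each animal's own information is drawn
independently, so PA_adj accuracies are not comparable to field values);
genotyping error and pedigree errors; selection (matings are random within
the design, so there is no genetic trend for the contemporary groups to
remove — the pooling machinery is exercised but not stressed); mutation;
and realistic marker ascertainment. Passing tests on this population show
the estimators and the relatedness mechanism behave correctly, not that any
particular field accuracy would be achieved.

Two generator choices deserve emphasis because the headline contrast depends
on them. First, the trait is polygenic with QTL *off* the panel: if causal
variants sit on the panel (or are few and large), the sampler finds them and
prediction transfers into unrelated animals, erasing the dependence of
accuracy on relatedness that the analysis exists to measure. Second, the
closed herd descends from a private ancestral haplotype pool: pedigree
isolation alone leaves population-wide LD intact, and ten closed generations
are not enough to decouple marker-QTL phase on a small simulated genome.
Both choices encode, at desk scale, the regime the real analysis operates
in — dense-panel effects that mostly capture family structure, and one herd
of distinct origin closed for decades.

## Numerical and reporting conventions

- All randomness flows through seeded generators (numpy `default_rng`;
  `np.random.seed` inside the numba kernel); reruns are bit-identical.
- Deregression solve tolerance 10⁻¹⁰ on reliability residuals; round-trip
  asserted to 10⁻⁸ per record.
- A-matrix recursion is exact (no approximation); PSD asserted to −10⁻⁸ in
  tests.
- K-means ties break toward the incumbent cluster (a move must improve the
  objective by > 10⁻¹²); cluster labels are renumbered by first appearance so
  restarts are comparable.
- Pooled accuracy drops singleton contemporary groups (zero df); the age
  split validates only animals with an out-of-fold prediction.
- Rounding in reports: accuracies and correlations to 2–3 decimals, variances
  to the precision of their inputs.

## Known limitations

- The per-group pooled accuracy is noisy at group sizes below ~100; the
  directional group comparisons in the tests aggregate over seeds for this
  reason.
- PA_adj reliability uses an acknowledged heuristic scaling; PA_adj itself is
  one reading of the deregression machinery (see above).
- EM-REML near a zero residual boundary converges slowly; the AI acceleration
  mitigates but does not remove this.
- The CLI covers the file-to-file stages and an end-to-end `run`; multi-trait
  orchestration is done through the analysis scripts rather than a single
  monolithic command.
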