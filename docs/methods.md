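# Methods

## Model structure

A homologous pair `(A, B)` consists of two genomic regions plus `H` binary
histone-mark tracks per region.  The joint likelihood marginalizes the
unobserved alignment:

    P(A, B) = Σ_path P(path) Π_{h=1..H} P(A^h, B^h | path)
    P(A^h, B^h | path) = Π_k P(b_hk | a_hk, a_0k, b_0k) · P(a_hk | a_0k, b_0k)

Mark changes on different marks are conditionally independent given the
path.  The model assumes binary mark states (inside/outside a peak — peak
calling upstream absorbs the dependence between neighbouring bases), and
reversibility of all processes (pulley principle), so either species can be
treated as the "ancestor" of the pairwise comparison.

Component processes:

* **Indels** — TKF91 birth–death chain with insertion (birth) rate λ and
  deletion (death) rate μ, λ < μ.  Closed forms used throughout:
  β(t) = (1−e^{(λ−μ)t})/(μ−λe^{(λ−μ)t}), survival p₁ = e^{−μt}(1−λβ),
  death-without-descendant p₀′ = μβ, death-with-one-descendant
  p₁′ = (1−e^{−μt}−μβ)(1−λβ), immortal-link p″_n = (1−λβ)(λβ)^{n−1}.
* **Substitution** — a single-rate reversible kernel of F81 form,
  f_ab(t) = e^{−st}1[a=b] + π_b(1−e^{−st}).  The framework only requires
  some reversible nucleotide kernel with one free rate; the F81 form
  mirrors the mark-switch kernel and reduces to Jukes–Cantor under the
  uniform base frequencies used in simulation.
* **Mark switch** — two-state kernel g_xy(t) with rate κ_h and stationary
  on-probability π1_h.

Time is fixed at t = 1 (`DEFAULT_TIME`); the rates are per-branch expected
event counts, so s, μ, κ absorb the branch length.

## The four dependence models

Per aligned column, the mark factors are set by the hypothesis in force
(N: independent; M: substitution-dependent; I: indel-dependent; B: both):

* match columns: g in all four models;
* mismatch columns: g under N and I; global equilibrium π^h under M and B;
* indel columns: under N and M the marginal
  Φ(y) = (1−φ1)g_{0y} + φ1·g_{1y}, where φ1 is the *local* (per-region)
  mark equilibrium; under I and B the global π^h.

Local equilibria φ are per-region mark frequencies, estimated by counting
and treated as mixture weights (0 and 1 are legal).  Global equilibria
(base frequencies, π1_h) are pooled frequency estimates over the dataset,
clamped to [1e−6, 1−1e−6] so all logarithms stay finite — degenerate
all-zero tracks do occur in real peak data.

## Likelihood computation

`P(A,B) = P(A)·P(B|A)`.  `P(A)` is the TKF length equilibrium
(1−λ/μ)(λ/μ)^{s_A} times the base factors (and, for models I/B, the
ancestral mark equilibrium factors; for N/M those factors live inside the
recursion — match columns carry π^h_a·g and delete columns carry Φ_B).
The inclusion of the length-equilibrium factor is constant across the four
models, so classification and the r metrics are unaffected by it.

`P(B|A)` sums monotone lattice paths (diagonal / delete / insert steps;
Delannoy-many) with a single-matrix recursion.  A diagonal step aggregates
two latent link fates: survival, with weight p₁·f·(mark kernel terms), and
death-plus-unrelated-insertion, with the composite weight
(p₁′−λβp₀′)·π_b·(mark equilibrium terms).  The composite coefficient can be
negative; grouped over emission-equivalent path classes the aggregate
weight is p₀′λβ + p₁′ ≥ 0, so every matrix cell is non-negative.  The
recursion is evaluated in linear space with per-row rescaling and an
accumulated log register (a numba kernel), keeping 500-bp regions well
inside double precision; products this long underflow naive evaluation.

An exhaustive oracle (`oracle_pair_log_likelihood`) enumerates every path
and every per-diagonal fate on tiny pairs, in linear space, and is the
ground truth for the DP in the test suite (tolerance 1e−9 in log space).
The boundary terms of the N/M recursion carry Φ factors as products over
the deleted (resp. inserted) prefix positions, the convention consistent
with the interior delete and insert terms.

## Estimation

* λ is tied per pair: λ_i = μ(s_{A,i}+s_{B,i})/(s_{A,i}+s_{B,i}+2) — the
  tie is written in terms of a single pair's lengths, so it is applied per
  pair rather than pooled.  Note λ/μ is then length-determined, so the
  ancestor factor carries no information about μ; μ is identified from the
  indel pattern through β, p₁, p₀′, p₁′.
* θ = (μ, s, κ_1..κ_H) is estimated by Nelder–Mead on the negative
  log-likelihood, in log-parameter space (positivity by construction).
  Default stopping: simplex size 1e−6 and NLL change 1e−8 (absolute, in the
  scipy sense), max 2000 iterations; two documented default starts,
  (μ,s,κ) = (0.02, 0.05, 0.5) and (0.08, 0.1, 1.0).  The accepted
  best-vertex NLL is recorded per iteration; the trace is non-increasing by
  the simplex acceptance rule and is asserted as such in the tests.
* The EM mixture over {N, M, I, B} updates responsibilities
  γ_iK ∝ α_K P_K(pair_i|θ) and priors α_K = mean_i γ_iK in the E-step; the
  M-step improves θ against the *full mixture* log-likelihood at fixed α
  (a generalized-EM step with a short inner simplex run), accepted only if
  it does not decrease the objective, so the observed-data log-likelihood
  is monotone.  Priors are floored at 1e−12 and renormalized.

## Region analysis

Each pair is scored under all four models (at per-model MLEs, or at the EM
θ̂) and classified by the largest likelihood; exact ties break toward the
simpler hypothesis in the order N > M > I > B.  Classification frequencies
give a = P(ind=0) = freq(N)+freq(M) and b = P(mut=0) = freq(N)+freq(I)
(optionally the EM priors instead), from which conditional likelihoods are
built as two-component mixtures (log-sum-exp), e.g.
P(A,B|mut=0) = a·P_N + (1−a)·P_I.  The dependence contrasts are

    r_ind = [l(ind=1) − l(ind=0)] / |l(ind=1) + l(ind=0)|   (sum_abs)
    r_ind = [l(ind=1) − l(ind=0)] / (s_A + s_B)             (length)

and likewise r_mut; both normalizations share the numerator and positive
denominators, so they always agree in sign.  The sign convention is fixed
so that positive values mean the dependent side fits better.  In quadrant
summaries, values exactly 0 count toward the negative (independence) side.

## Simulator

The generator draws an ancestor at equilibrium (iid bases from π, marks
Bernoulli(π1) — or Bernoulli(φ1) for N/M, with φ1 ~ Beta(1.5, 1.5(1−π1)/π1)
per region, whose mean is π1), samples the alignment from the exact TKF91
link fates (survive with probability e^{−μt} plus Geometric(λβ) extra
births; on death, no descendant with probability μβ/(1−e^{−μt}), else
1+Geometric(λβ); the immortal link contributes Geometric(λβ) leading
inserts), and emits descendant bases from f and marks per the generating
hypothesis's column rules.  In the rare event that no descendant position
survives, the pair is redrawn.  The truth φ is drawn once per region; at
fitting time φ is re-estimated from the realized tracks, so recovery tests
exercise the same estimate-vs-truth mismatch a real pipeline has.

Simulation defaults are the study conditions: uniform base frequencies,
π1 = 0.1, one mark, 100 pairs of 500-bp ancestors, t = 1.  The simulator
needs a concrete λ; we set λ = μ·L/(L+1) for ancestor length L, the value
the per-pair length tie takes at s_A = s_B = L, so generation and fitting
are mutually consistent.

The declared parameter grid (`SIMULATION_GRID`) holds eight (μ, s, κ)
combinations spanning {0.01, 0.1, 1}.  What the generator does *not*
emulate: spatially correlated peak structure (marks are iid at equilibrium
within a region), context-dependent substitution, rate variation across
sites, and alignment uncertainty from real liftOver pipelines — so passing
recovery tests show correctness of the estimator under the model, not
robustness to real-data model violations.

## Problem sizes and numerical choices

The acceptance script keeps the study's 100 pairs per dataset and scales
the ancestors to 200 bp, for both the model-identification count and
parameter recovery (10 replicates per condition, conditions
g2 = (0.1, 0.1, 1) and g6 = (0.01, 0.01, 0.1) from the declared grid); the
test suite uses smaller versions of the same checks.  Pair count matters
more than region length for model identification: the discriminating
signal between a local-equilibrium model (N, M) and its global-equilibrium
twin (I, B) accrues per region, because per-indel-column differences shrink
as the per-region mark-frequency estimates concentrate, so identification
of indel-dependent data remains the hardest case at reduced scale.  Batch fits loosen the simplex stopping rule
to 1e−4 in log-parameter space, far below the statistical error at these
sample sizes.  DP–oracle agreement is asserted at 1e−9 in log space;
probability identities at 1e−12.

## Real-data workflow (optional, not self-contained)

Reproducing the published two-species H3K4me3 analyses requires external
inputs: round-spermatid H3K4me3 ChIP-seq (GEO GSE68507) for human, rhesus
and mouse, ENCODE DNase clusters, genome builds and liftOver chains.  The
preprocessing (mapping, peak calling, homolog construction) is out of scope
here; once regions are exported as paired FASTA plus region-relative BED
peaks, `jemge estimate` / `em` / `classify` / `metrics` run the full
analysis.  Reference estimates for this system are s ≈ 0.07, μ ≈ 0.04,
κ ≈ 0.75, with roughly 73% of human–rhesus pairs classified to the
sequence-dependent models; agreement at the "approximately" level is the
realistic expectation given preprocessing differences.

## Known limitations

* Single pairwise branch; no outgroup, so gains and losses are not
  polarized.
* One κ per mark; no rate heterogeneity across sites or regions.
* TKF91 treats indels base-by-base (no long-indel/fragment model), which
  undercounts long transposon insertions as single events.
* The F81 substitution form cannot represent transition/transversion bias.
* Classification uses raw likelihood argmax without complexity penalty;
  the four models share θ dimensionality, so this mainly matters for
  near-ties (broken deterministically toward independence).
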