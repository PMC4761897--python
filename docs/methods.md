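# Methods

`hybridase` analyses allele-resolved RNA-seq from F1 hybrid crosses of
inbred (here: budding-yeast) parental strains. Because the two parental
alleles of every gene share one nucleus, they see an identical pool of
trans-acting factors; a reproducible expression difference between the
alleles of a hybrid is therefore a cis-regulatory signal, while a change
in one allele's expression *between* hybrid contexts is a trans signal
from the partner genome. The package implements the full chain from
allele-resolved counts (or simulated reads) to cis- and trans-level
calls, together with a generator that produces studies with known ground
truth.

## 1. Synthetic study generator (`sim`)

The generator emulates the statistical structure of a four-parent
hybrid panel:

* **Sequences.** Each gene has an ancestral promoter (default 200 bp)
  and ORF (default 500 bp) with uniform base composition. Every strain
  independently substitutes each base at rate `m` chosen so that the
  *pairwise* density of differences equals `snp_rate` (default 0.005 ≈
  one variant per 200 bp, the density typical of divergent yeast
  lineages); solving 2m(1−m) + (2/3)m² = `snp_rate` gives m ≈
  `snp_rate`/2. Alleles differ by substitutions only, keeping
  coordinates aligned and read placement exact.
* **Motif plants.** A consensus site for a position-probability matrix
  is embedded at a random recorded promoter offset, identical across
  strains; optionally one strain's copy receives a single substitution
  at the motif's highest-information position (consensus base replaced
  by the least-preferred base). The disruption can be coupled to a cis
  effect, modelling a binding-site polymorphism that lowers expression
  of the broken allele.
* **Counts.** Counts are negative binomial with variance μ + φμ²
  (default φ = 0.05 — the dispersion of the emulated data type is not
  externally fixed, so this is a modelling choice representative of
  well-replicated RNA-seq; φ = 0 falls back to Poisson). The mean for
  an allele with parent strain *p* in hybrid (s1, s2) is

      column_scale × baseline_g × 2^{cis(p)} × Π_TF [act(TF,s1)·act(TF,s2)]^{target(g,TF)}

  Per-gene baselines are lognormal around `baseline_mean` (default 200
  counts per allele, spread σ = 0.5); column totals are drawn uniformly
  from `library_size_range` (default 0.9–1.1 × the nominal total) and
  the means rescaled to hit them, emulating library-size variation.

  Two modelling points deserve emphasis. The cis offset multiplies only
  the allele that carries it, so the true allelic log2 ratio in any
  hybrid is cis(p1) − cis(p2) and an allele's absolute level is the
  same in all three of its hybrid contexts unless a trans activity
  differs. The trans factor is the hybrid's *shared* environment (both
  parents' activities, acting on both alleles equally): trans
  differences consequently never create allelic imbalance — the premise
  that makes ASE a pure cis readout — but they do shift a target
  allele's level between contexts, which is exactly what CSE measures.
  An earlier per-allele formulation (each allele scaled only by its
  partner's activity) was rejected because it let trans variation
  masquerade as ASE.
* **Reads.** Optionally, labelled reads are drawn uniformly along the
  ORF of the labelled allele on a random strand, with independent
  substitution errors at `error_rate`, to exercise the classifier.

All randomness flows from one integer seed through fixed per-operation
substreams, so a configuration reproduces byte-identical outputs.

**What the generator does not emulate:** indels and structural variants,
non-uniform base composition, positional coverage bias, paired-end
reads, UTRs, mapping ambiguity between genes, and correlated gene
networks. Passing tests therefore demonstrate correctness of the
statistics under the substitution-only, independent-gene model, not
robustness to real-library artefacts.

## 2. Read classification (`seqmap`)

Alleles are pre-paired, equal-length orthologs. Genes with a missing
allele, unequal ORF lengths, or undefined bases are carried with
exclusion flags and skipped downstream. A read is placed at its best
exact-coordinate offset over both alleles and strands — the placement
score is min(mismatches vs allele 1, vs allele 2), with ties broken
toward the forward strand and then the smaller offset — and is assigned
to the allele with strictly fewer mismatches there, provided the
placement covers at least one discriminating position and the winner is
within `max_mismatch` (default 2). Everything else is "uninformative"
and counted separately so the informative fraction is reportable.
Full alignment is deliberately out of scope: under substitution-only
divergence exact placement is optimal and auditable.

## 3. ASE testing (`ase_quant`)

* **Normalization.** TMM: the reference column is the one whose upper
  quartile of count fractions is closest to the mean upper quartile;
  each column's factor is 2^(weighted trimmed mean of per-gene log2
  ratios against the reference), excluding genes zero in either column,
  trimming 30% per tail of M and 5% per tail of the average abundance
  A, weighting by inverse asymptotic variances, and rescaling factors
  to geometric mean 1.
* **Filters.** `detectable_<hybrid>`: ≥ `min_reads` (default 10) for
  both alleles in at least one replicate of that hybrid. `uda`
  ("universally detectable"): ≥ `min_reads` per allele in *every*
  replicate of *every* hybrid. Both readings of the detectability rule
  are carried as separate flags rather than collapsed.
* **Dispersion.** One common φ per hybrid by conditional maximum
  likelihood: counts are quantile-adjusted to the hybrid's common
  effective library size (normal/gamma quantile-mix mapping, one
  refinement pass), and the NB conditional log-likelihood given each
  allele-group total is maximized over φ ∈ [1e-6, 10] on a log grid
  (Brent). Tagwise/trended shrinkage is out of scope.
* **Exact test.** Per gene, the two allele groups are compared as two
  conditions with replicates: quantile-adjust to the common effective
  size, round the two group sums, condition on their total, and sum the
  probabilities of all outcomes no more probable than the observed one
  (two-sided). Under φ = 0 the conditional law is binomial; otherwise
  it is the exact conditional of two NB sums, enumerated over 0..total.
  M is the log2 ratio of pseudocounted (+0.5) per-replicate group
  means. Group sums are rounded to integers so the enumeration is
  exact; the tie comparison uses a 1e-10 relative tolerance.
* **FDR.** Storey q-values: π0 estimated from #{p>λ}/(m(1−λ)) on the
  grid λ = 0.05..0.95 (step 0.05) with a least-squares cubic in λ
  evaluated at λ = 0.95, clipped to (0, 1]; q = π0 × BH. `method="bh"`
  forces π0 = 1. Significant ASE defaults to q < 0.05; q-values are
  computed within hybrid, since each hybrid has its own detectable set.

The ASE stage was validated in development against an independent
implementation of the same TMM/common-dispersion/exact-test pipeline on
identical simulated matrices (log-p correlation > 0.9999; dispersion
estimates agreeing to seven significant digits). The shipped test suite
relies only on self-contained enumeration oracles.

Measured power at the generator's default conditions (φ = 0.05, mean
200 counts per allele, |cis log2| = 1, three replicates, q < 0.05):
about 0.75–0.81, with empirical FDR ≤ 0.10 and |bias of M̂| < 0.03.
This is the information-theoretic limit of the design, not an
implementation ceiling — an independent reference pipeline reaches the
same value on the same data.

## 4. Binding model (`motif_bind`)

Matrices are MEME-minimal format, pseudocounted (α = 0.01 per entry)
and renormalized at load. The per-window score in the default `prob`
mode is the PWM probability of emitting the window, Π_j θ[j, base_j] —
a relative affinity with unit concentration, which is a probability and
so needs no capping. The occupancy of a promoter is the probability
that at least one window on either strand is bound, P_bound =
1 − Π_i (1 − p_i), computed in log space. An alternative `affinity`
mode p = K/(1+K) with K = Π θ/background (uniform background 0.25,
configurable) is available behind a flag; which saturation the original
occupancy formulation intended is not recoverable, so the default is
pinned in configuration and tests rather than inferred. Windows
overlapping N are skipped (contribute no binding); promoters shorter
than the motif score 0. ASB for a promoter pair is
P_bound(allele 1) − P_bound(allele 2) ∈ [−1, 1]. The per-SNP report
attributes binding change to individual variants by the best
overlapping-window score on each allele, ranked by absolute score
change (relative change is reported but not used for ranking, because
it diverges when both windows score near zero).

## 5. ASB~ASE association (`cis_map`)

Per hybrid, genes in the hybrid-specific ASE set with complete ASB are
correlated TF-by-TF (Pearson feeding the permutation/K-S machinery,
Spearman feeding per-motif reporting). The null permutes the ASE
vector's gene labels — one permutation shared by all TFs, preserving
the cross-TF dependence of ASB — with empirical two-sided
p = (1 + #{|R_null| ≥ |R_obs|})/(n_perm + 1). The global test is a
two-sample K-S of the pooled observed R against the pooled permuted R
(per hybrid and pooled across hybrids; both poolings are exposed
because either aggregation is defensible). Per-motif significance uses
the analytic Spearman p with Bonferroni correction over tested motifs,
permutation p retained alongside. Genes with near-zero ASB are
retained: most ASB values are legitimately near zero and filtering
them would bias the null. Per-gene causal attribution is explicitly
not attempted.

## 6. Context-specific expression (`trans_map`)

With alleles indexed by query strain *a* and partner context,
CSE(a, b) = 2·Expr(a,b) / (Expr(a,c) + Expr(a,d)), where Expr is
TMM-normalized, replicate-averaged expression and a pseudocount
ε = 0.5 normalized counts is added to every term (genes whose
background is zero before pseudocounting are flagged invalid and
excluded from tests). CSE is invariant to rescaling an allele's
expression, so cis differences cancel and only context effects remain.

A TF's targets are genes scoring at least half the maximum motif score
(mean GOMER P_bound across strains), clamped to at least the top 50 and
at most the top 10% of scored genes, ties broken by gene id. Per
(TF, foreground) pair, targets vs non-targets are compared by Welch's
t-test on log2 CSE — log because CSE is a right-skewed ratio, Welch
because the groups are very unequal in size — once per query parent
(for the sign-consistency requirement) and once pooled across the
three query parents (one p per pair, giving one BH family at α = 0.1
matching a one-row-per-TF-per-strain results table). A pair is
significant iff q ≤ 0.1 *and* all three query-parent differences share
a sign.

Two behaviours of this statistic are worth knowing. First, a genuine
activity increase of a TF in strain *b* also produces relative "down"
calls for the same TF in the other foregrounds, because those contexts
are now being compared against a raised background — both directions
are real findings about relative activity, not artefacts. Second,
every other TF's non-target group contains the active TF's targets, so
strongly shifted target sets can induce small spillover differences for
unrelated TFs; with a single dominant activity this appears as
secondary calls roughly an order of magnitude weaker.

## 7. Directional selection and enrichment (`selection`)

For each parent, genes whose parent-oriented M is significant
(q < 0.05) with a consistent sign in all three hybrids carrying that
parent — and universally detectable — form the maximally- or
minimally-expressed allele sets. This is deliberately a significance-
and-sign rule, not a rank statistic. Enrichment of a set against a GMT
collection is a one-sided hypergeometric upper tail within a
configurable universe (default: the UDA genes), fold =
(overlap/|set|)/(|category∩universe|/|universe|), BH-corrected at
FDR < 0.10.

## 8. Pipeline (`cli`)

`hybridase run-all` wires the stages in dependency order over
TSV/FASTA/JSON interfaces only, with a JSON manifest (config hash,
package version, seed, per-stage row counts, K-S summary). Runs are
deterministic: identical configs give identical manifests and outputs.
Failures write a `failed` marker naming the stage. Per-stage
subcommands (`simulate`, `ase`, `bind`, `asb`, `cis`, `cse`, `das`,
`enrich`) operate on the same files.

## Problem sizes

The shipped demo and the test/acceptance workloads use 250–2,000 genes,
4 strains / 6 hybrids / 3 replicates, 1–50 motifs and 1,000
permutations — sizes chosen so a complete run takes about a minute on
one CPU while keeping every statistical check inside its sampling
error. All fixtures are generated programmatically at run time.

## Known limitations

* Common dispersion only; genes with atypical variability are not
  shrunk individually.
* The GOMER per-site saturation mode of the original formulation is
  not uniquely determined; both provided modes are monotone transforms
  of the same window scores, and ASB signs agree between them.
* CSE requires every query allele to appear in all three contexts;
  missing hybrids make pairs incomplete rather than partially scored.
* The classifier ignores multi-gene mapping ambiguity; it assumes the
  upstream gene assignment is correct.
* Enrichment treats categories as fixed sets (no annotation-clustering
  or term-similarity correction).
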