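# Methods

## The problem and the design

Pooled CRISPR dropout screens in non-proliferative cultures (e.g. ovarian
cancer spheroids in suspension) are dominated by stochastic, Cas9-independent
changes in guide representation: when a library of ~10^5 guides passes
through a population bottleneck, low-abundance guides drop in and out of the
pool regardless of any editing. A guide-only (GO) design runs a parallel
screen in Cas9-negative cells carrying the same library through the same
culture protocol. Those cells experience the same drift mechanism but no
gene knockout, so the ratio of Cas9-positive over Cas9-negative guide
abundance isolates the Cas9-dependent (biological) signal.

The screen has three sampled stages: the plasmid library (L0), the initially
infected adherent population (T0), and the population after transfer to
suspension/spheroid culture (Tf), with replicate cultures per arm at T0 and
Tf. Genes whose guides drop out more strongly between T0 and Tf in the
Cas9-positive arm, relative to the guide-only arm, are candidate survival
genes in the suspension (dormancy-like) condition.

## Scoring model

With read counts `c[i,s]` for guide `i` in sample `s`:

1. **Normalization.** `a[i,s] = 1e6 * (c[i,s] + 1) / Σ_j (c[j,s] + 1)` —
   a +1 pseudocount (so every abundance is positive and every log-ratio
   finite) followed by reads-per-million scaling. Columns sum to 1e6
   exactly.
2. **Guide ratios.** For stage `t ∈ {T0, Tf}` and replicate `r`,
   `λ[i,t,r] = log2(a_pos[i,t,r] / a_neg[i,t,r])`, pairing arms by
   replicate index. When Cas9-negative replicates are missing, an explicit
   `cas9neg="pooled"` option substitutes the mean Cas9-negative abundance
   at that stage; the default is an error.
3. **Percentiles.** Within each `(t, r)`, guides receive average-rank
   percentiles `ρ ∈ (0, 1]` of `λ` (ties share the mean rank; the maximum
   gets exactly 1). Ranking makes the gene score bounded, monotone in the
   ratio, and insensitive to sequencing depth and to the scale of λ.
4. **Gene Enrichment Scores.** A gene's Initial ES per replicate is the
   mean ρ of its guides at T0 ("adherent score"); the Final ES the same at
   Tf ("spheroid score"). The Library ES is the mean average-rank
   percentile of raw L0 abundance; it is reported for QC only and never
   filters genes. The companion software that introduced these score
   names does not publish their arithmetic; the mean-percentile definition
   used here is this package's own, chosen to reproduce the depletion
   semantics of the enrichment-ratio rule below.
5. **Enrichment Ratio.** `ER = mean_r(Final ES) / mean_r(Initial ES)`.
   ER < 1 means the gene's guides sank in the suspension ranking relative
   to the adherent ranking — stronger, suspension-specific dropout.
6. **Testing.** A two-sided paired t-test across replicates on
   `d_r = Final ES_r − Initial ES_r` (df = R − 1), Benjamini–Hochberg
   across all scored units (control pseudo-genes included, flagged).
   A gene is called `depleted_in_suspension` iff ER < 1 and p_adj < 0.05,
   both strict; thresholds are configurable (`CallConfig`).

Degenerate cases: all `d_r = 0` gives p = 1; a nonzero constant `d_r`
(zero variance) gives p = 0 and a logged `degenerate_variance` flag;
fewer than two replicates is an error.

**Naive baseline.** For benchmarking the value of the guide-only control,
the `naive` variant scores the Cas9-positive arm alone:
`λ[i,Tf,r] = log2(a_pos[i,Tf,r] / a_pos[i,T0,r])` and `λ[i,T0,r] ≡ 0`
(so every guide's T0 percentile is the midpoint `(N+1)/(2N)` and the
Initial ES is a constant baseline). Everything downstream is identical.
This variant retains the variance-induced log bias that the two-arm ratio
cancels, which is exactly the artifact the guide-only design removes.

**Control pseudo-genes.** Non-targeting controls carry no gene unit, so
`group_controls` partitions them deterministically (library order) into
pseudo-genes `CTRL_0001…` of a chosen size (default: the library's
guides-per-gene). They flow through scoring like genes, flagged
`is_control`, and drive the QC statistics.

## Counting

Spacers are located by a fixed 5' offset or a 5' anchor sequence (the
vector-specific constant sequence is a required user input) and counted by
exact match only; a mismatch-tolerant mode is deliberately out of scope.
Reads with no anchor, a truncated spacer, or no library match are tallied
as unassigned, so `assigned + unassigned = reads` per sample. Spacers
shared by several guides are unresolvable; by default their reads go to
unassigned (`ambiguous="drop"`), or to every matching guide under
`ambiguous="duplicate"`. Counting is order-independent and additive over
file concatenation. Reverse-complement matching is off by default
(single-end sense-strand reads assumed).

## QC

- **Control ROC.** With controls as known negatives and a per-gene
  essentiality score (default −ER; −log10 p_adj available), the ROC AUC is
  computed tie-corrected (Mann–Whitney; ties count ½), which equals the
  trapezoidal area under the tie-grouped curve.
- **Control non-essential rate.** Fraction of control pseudo-genes with no
  depletion call; near 1 in a well-behaved screen.
- **External correlation.** Per-gene ER joined on gene symbol against an
  external viability table (e.g. siRNA knockdown survival), Pearson or
  Spearman with two-sided p; at least 3 matched genes required.

## Set integration

Hit lists are intersected with full inclusion–exclusion region counts
(summing to the union size). Over-representation uses the upper-tail
hypergeometric test `P(X ≥ k)` for overlap `k` of a query of size `n`
against a set of size `K` in a universe of size `N`, with a minimum-overlap
filter (default 45) applied *before* testing, BH across the tested sets
only, and a q-value cutoff (default 0.01). The default universe is the set
of genes the screen actually scored — the background must reflect testable
genes — and is overridable for other conventions. Gene symbols are
case-folded and whitespace-stripped on input.

## Simulator

The generator reproduces the screen's sampling hierarchy with a single
seeded RNG:

1. true library frequencies `f ∝ exp(Normal(0, σ))`, σ = 0.5 by default
   (a realistic lognormal skew for a pooled lentiviral library);
2. L0 reads ~ Multinomial(D, f), D = 1e6 reads/sample;
3. per arm and replicate, T0 cell frequencies ~ Multinomial(B, f)/B with
   bottleneck B = 1e5 cells by default (the drift-severity knob); in the
   Cas9-positive arm only, frequencies are reweighted by each gene's
   adherent fitness multiplier and renormalized; T0 reads ~
   Multinomial(D, ·);
4. Tf applies an independent second bottleneck to each replicate's T0 arm
   frequencies, then (Cas9-positive only) the suspension multiplier, then
   sequencing.

Genes are assigned to classes {neutral, adherent_essential,
suspension_essential, both} by configured fractions; affected guides get a
per-passage survival multiplier w (default 0.25, i.e. 4-fold dropout).
Controls are simulated exactly like neutral genes. Multinomial sampling at
both layers was chosen over an explicit negative-binomial read model:
overdispersion emerges from the two-stage hierarchy with no extra free
parameters, mirroring the bottleneck mechanism itself. One passage per
stage transition; the multi-day suspension protocol is collapsed into the
single Tf multiplier.

What the simulator does *not* emulate: PCR amplification bias, sequencing
error (counting is exact-match on error-free reads), copy-number or
cutting-toxicity artifacts, guide-efficiency heterogeneity within a gene,
and spatial spheroid structure. Passing tests therefore demonstrate the
statistical behavior of the pipeline under the stated sampling model, not
performance on any particular real dataset.

## Numerical and design choices

- Percentiles use average ranks (`scipy.stats.rankdata`), so the mean
  percentile within a sample is exactly `(N+1)/(2N)`.
- BH is `statsmodels`' step-up, validated in tests against a brute-force
  oracle; hypergeometric tails are `scipy.stats.hypergeom.sf(k−1, …)`,
  validated against pmf enumeration; the paired t-test is validated against
  the closed-form df = 2 expression `p = 1 − |t|/√(t²+2)`.
- All scoring is permutation-invariant in guide and gene order; identical
  arms give ER ≡ 1 and p ≡ 1 exactly.
- Simulation sizes used in the test suite and acceptance summary: 2000
  genes × 4 guides + 1000 controls, triplicates, B = 1e5 (2e4 for the
  severe-drift comparison), D = 1e6 — a desk-scale rendering of a
  genome-wide screen that keeps every run to seconds.

## Known limitations

- With triplicates the paired t-test has 2 degrees of freedom, so
  attainable p-values are bounded well away from 0 and BH across thousands
  of genes is conservative: on simulated data the ER *ranking* recovers
  planted genes essentially perfectly (AUC ≈ 1) while few genes survive
  the p_adj < 0.05 call at genome scale. Real screens with stronger,
  multi-passage selection produce larger paired-t statistics; users can
  also relax `CallConfig` or rank by ER directly.
- Exact-match counting undercounts libraries with high sequencing error.
- The pooled Cas9-negative fallback changes the error structure of λ and
  is therefore opt-in.
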