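# Methods

This note documents the models, defaults and numerical choices behind the
`nucleocyclic` package: what the synthetic world states, what each
estimator assumes, and where the design was genuinely open.

## The synthetic world

`synthetic_data.SimConfig` states one world; every default below was fixed
from the phenomena the analysis targets, not tuned to test outcomes.

**Genome and promoters.** Promoters are planted on a jittered grid
(> 1000 bp apart; a sizing error is raised otherwise), each with a random
strand. The 500-bp window upstream of a TSS is drawn at
`upstream_AT_fraction` = 0.6 A+T; the downstream window at
`downstream_CG_fraction` = 0.6 C+G — the nucleosome-destabilizing /
nucleosome-accommodating boundary the analysis is meant to detect, at a
magnitude typical of vertebrate promoters. The background is uniform
(25% per base).

**Nucleosomes.** Phased promoters carry a downstream array: first dyad at
+100 (the empirical mode of first-dyad positions), then every
`nucleosome_spacing` = 180 bp (`n_array` = 3 nucleosomes). 180 bp is a
typical vertebrate repeat length and sits mid-range of the plausible
165–200 bp; the genome-wide *mean* neighbor distance (165 bp) is not used
as the spacing because the stable-dyad isolation filter uses exactly that
radius — planting arrays at the filter boundary would make every array
dyad uncallable by construction. Unphased promoters get the same number of
dyads at uniform random downstream positions (per tissue), and every
promoter gets random unphased upstream nucleosomes outside a ~150-bp
depleted region. Intergenic space carries regularly spaced background
arrays shared by all tissues: these are the "stable, genome-wide"
nucleosomes.

**Core composition envelope.** Positioned cores (arrays and background)
overlay an A/T modulation across ±73 bp of the dyad: a dip of
`core_at_dip` = 0.15 (cosine-tapered, i.e. a C/G-rich core) plus a
~10.2-bp periodic component of amplitude 0.08 — the canonical rotational
positioning signal. This envelope is load-bearing: the fragment-length
discrepancy compares interior A/T profiles after trimming 30 bp from each
fragment end, so a world whose cores are compositionally flat inside
offers that estimator no signal at all; end-placement cleavage bias alone
marks only the trimmed-off termini.

**Reads.** Each planted dyad receives Poisson(`coverage` = 50) fragments:
midpoint ~ Normal(dyad, `dyad_jitter_sd` = 2), length ~ Normal(
`core_length_true` = 147, `fragment_length_sd` = 5), and each fragment end
independently shifted by at most 1 bp toward A/T bases with weight
`mnase_at_weight` = 3 (MNase cleavage bias as end-placement reweighting —
only the end-composition artifact matters to the estimators under test,
so no digestion kinetics are simulated). One end per fragment is
sequenced, chosen with probability 0.5 — forward reads anchor the
fragment start, reverse reads the end.

**Expression.** Per tissue, promoter expression is log-normal
(`expression_log_sd` = 1 in natural-log units, a broad but realistic
dynamic range); promoters phased in a tissue get
`expression_phasing_boost` = 1.0 added in log space, coupling phasing to
expression (the phenotype the end-to-end tests must recover). A
`silent_fraction` = 0.15 of promoters per tissue is unexpressed there and
never phased there (phasing is transcription-coupled), which populates the
activity Venn regions and the breadth-zero path. `library_size` = 10⁶
tags per tissue fall on promoters multinomially and spread over ±10 bp of
the TSS with geometric decay (ratio 0.5) — a stand-in, since the true
within-cluster positional law of 5′ tags is not known.

**Evolution.** Two descendant branches at 1.7% per-site substitution
probability and an outgroup branch at 2.5% (matching a ~3.4% SNP
divergence between the descendants), transition/transversion ratio 2,
sites independent, substitution-only (the strain coordinate map is the
identity; no indels, recombination or linked selection). Per-category
per-site rate multipliers can be injected to plant spatially modulated
mutation processes. The substitution record exactly reconstructs each
descendant.

**What a green test does not establish.** The generator has no read-level
sequencing error, mappability structure, repeats (beyond what uniform
sequence produces), copy-number variation, nucleosome eviction dynamics,
or tag noise away from promoters. Estimator recovery here demonstrates
correctness of the computation on data satisfying the model's assumptions,
not robustness to real-library artifacts.

## Estimators: numerical choices

**Dyad scores.** Midpoint-count scoring with offset ⌊(L−1)/2⌋ = 73 and a
21-bp running average (edge-aware: the window average divides by the
in-range width, so a constant track is a fixed point and mass is conserved
away from track ends). The exact scoring kernel of the antecedent method
is not public; midpoint counts + smoothing is a declared stand-in.

**Fragment length.** Forward vectors sample A/T at x+30 … x+L−31; for
reverse reads the fragment start is *imputed* from the candidate L as
y−L+1 and sampled ascending, which is what makes the discrepancy L-
dependent: a wrong L misaligns the reverse profile against the forward one
by exactly the length error. Sampling inward from the reverse anchor
without the L-imputation would make both expected vectors identical for
every candidate (both measure the same profile from their own cleavage
end) and the estimator uninformative. Exact ties resolve to the smaller L.
Reads too close to a contig end are skipped and counted.

**Peaks and stable dyads.** x is a peak when s(x) strictly exceeds s
within ±146 bp; a flat-topped maximum (a run of exactly equal values,
which clean synthetic counts + 21-bp averaging produce routinely) reports
its central position — the unbiased choice for a symmetric read cloud;
reporting the left edge would shift every called dyad about half a
plateau (~6 bp) leftward. Distinct tied peaks still resolve leftmost.
Filters apply in order (isolation 165 bp inclusive; uniqueness via an
exact catalog of canonical 25-mers over the genome, standing in for "maps
elsewhere" without running an aligner; cross-tissue proximity 10 bp
against filter-surviving candidates of both other tissues) and each one
only removes; eliminations are recorded per candidate. Only forward-strand
scores feed stable-dyad calling — an upstream convention followed
literally.

**Autocorrelation.** Mean-centered with the full-window variance
denominator (the conventional sample ACF; |R| ≤ 1; invariant under
positive affine maps of the scores); zero-variance windows are missing.
Lag ties resolve to the smaller lag. Grouping is rank tertiles by default
(sizes differ by ≤ 1; ties and all-equal inputs fall back to position
order, so labels are deterministic); 1-d k-means is available as an
alternative since the original stratification method is unstated.

**Composition and profiles.** Offset 0 is the anchor base; windows are
[−500, −1] and [+1, +500] on the transcribed strand, so the anchor is
never double-counted. The incidence z-test's default denominator is
1/n₁ + 1/n₂ over the focal-base counts (the form this analysis
historically used); because a conventional two-proportion test divides by
the window totals instead, the corrected 1/m₁ + 1/m₂ variant is provided
behind a flag and both are reported by the pipeline. With n₁ = 0 or n₂ = 0 the verbatim
form is undefined and reported missing. Around dyads, offsets 70–74 bp
upstream (both signs in mirrored both-strand mode, keeping the complement
identity exact) are excluded before the 41-bp running average — they carry
the cleavage-bias artifact — and are rendered only by the smoothed curve;
smoothing is NaN-aware.

**Ancestral inference.** Strict parsimony: ancestor = outgroup base when
the outgroup matches focal or sister; three-way disagreements *and* sites
where the outgroup matches neither descendant are undetermined (excluded
from numerator and denominator); any gap/ambiguity excludes the site.
This is deliberately conservative — when both descendants agree against
the outgroup, a parallel substitution cannot be ruled out. Rates are
normalized by all determined sites at the offset so opposite base changes
share a denominator; only focal-branch changes are counted. Flux pools
counts over a region before dividing, which makes
flow-in − flow-out = net incidence change per base an exact identity
(the four net changes sum to zero to machine precision).

**Rank-sum machinery.** One-tailed directions are always a caller-supplied
argument. Exact null distribution when both sides have ≤ 20 tie-free
values; otherwise the normal approximation with tie correction. A fully
degenerate contrast (all values equal) reports the 0.5 boundary with a
flag. Dyad-vs-linker contrasts compare per-offset differences in [−30, 30]
against [70, 130] (the linker 100 bp downstream), dropping offsets missing
in either profile (the MNase exclusion removes a few from the linker
window).

**Correlation screen.** The 48-column roster (2 strains × 3 tissues ×
{expression, breadth} + 2 strains × 3 tissues × 2 sides × {periodicity,
consistency} + 4 bases × {up, down, asymmetry} for the focal strain) is a
reconstruction — the parameter family is documented but its exact
enumeration is not; the roster is configurable. Expression enters as
log₁₀(x + 0.01). Rows with any missing value are dropped (and counted)
before Spearman; the Bonferroni level is α/1128. Focal and sister
representatives are paired by nearest same-strand position within 500 bp
(standing in for reciprocal-best alignment, which the identity coordinate
map makes trivial).

## Scale of the shipped runs

The acceptance script and the end-to-end tests run 600 promoters on a
1.2-Mb genome (~15 s): large enough that the planted coupling drives the
consistency-expression correlation far past the Bonferroni level
(p ~ 10⁻¹⁹ at r ≈ 0.35) while the whole suite stays inside a desktop time
budget. The statistics scale as designed up to thousands of promoters.

## Known limitations

- Real-data mode expects single-chromosome FASTA and BED inputs and an
  identity coordinate map; alignment-based strain mapping is out of scope.
- The dyad-scoring kernel and the ancestral-inference rule are declared
  stand-ins for methods whose originals are not fully public; both are
  documented above and isolated behind module functions.
- The printed z statistic is not variance-calibrated (its denominator uses
  focal-base counts); calibration claims in the tests apply to the
  corrected variant only.
- C→T vs G→A asymmetry (transcription-coupled repair) is testable but the
  default generator is strand-symmetric, so that contrast is null on
  synthetic data unless a strand-asymmetric modulation is injected.
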