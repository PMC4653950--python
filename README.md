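# nucleocyclic

Analysis of promoters with strongly phased downstream nucleosome arrays
("nucleocyclic" transcription start sites) in pairs of diverged inbred
strains, built for regulatory and evolutionary epigenomics: TSS calling
from 5′-end mRNA tags, nucleosome dyad-score tracks from MNase core reads,
phasing metrics by autocorrelation, promoter sequence-composition
asymmetry, and ancestral-base mutational flux inferred with an outgroup
strain. A first-class synthetic-world generator provides ground truth for
every estimator, so the whole pipeline is testable end to end without any
sequencing data.

## The model in brief

- **TSS calling.** Per-position 5′-tag counts are normalized so each
  library totals 300,000 (≈ one cell's mRNA complement, so a score of 1.0
  is roughly one copy per cell). The three tissue tracks are averaged;
  positions with merged expression > 0.1 within 20 bp of each other form a
  TSS cluster; the representative TSS is the cluster's maximal position,
  retained greedily so that representatives are pairwise > 500 bp apart.
  Cluster *breadth* is the distance between the 5th- and 95th-percentile
  positions of the cumulative tag sum.
- **Dyad scores.** A single-end core read anchored at *x* (forward) marks
  a dyad at *x* + 73; a reverse read at *y* marks *y* − 73 (147-bp wrap).
  Raw per-strand counts are smoothed with a 21-bp running average, giving
  the local dyad positioning score *s(x)*.
- **Core fragment length.** For candidate lengths *L* ∈ [137, 157], A/T
  incidence vectors over the fragment interior (30 bp trimmed from both
  ends to dodge the MNase cleavage skew) are averaged over forward- and
  reverse-anchored reads; the mean squared difference between the two
  vectors is minimal when *L* matches the real end-to-end distance.
- **Stable dyads.** Peaks of *s(x)* (strict maxima within 147 bp) are kept
  if isolated (no other peak within 165 bp, the mean neighbor-dyad
  distance), unique (no 25-mer in the ±165 bp flank occurring twice in the
  genome), and reproducible (a dyad within 10 bp in both other tissues).
  The *first* downstream dyad of a TSS is the score argmax in [+50, +150].
- **Phasing.** In the 500-bp windows upstream and downstream of each
  representative TSS, the normalized autocorrelation *R(L)* of *s* over
  lags 150–220 bp yields the periodicity *L\** (argmax) and consistency
  *R(L\*)*. TSSs are stratified into tertiles of downstream consistency;
  Group 1 — the top stratum — is the nucleocyclic class.
- **Sequence asymmetry.** Base counts in the 500-bp windows up/downstream
  are compared with the two-sample incidence z statistic
  Z = (n₁/m₁ − n₂/m₂) / √(μ(1−μ)(1/n₁ + 1/n₂)), μ = (n₁+n₂)/(m₁+m₂)
  (a variance-corrected variant with 1/m₁ + 1/m₂ is available).
- **Mutational flux.** With strains ((focal, sister), outgroup), a site's
  ancestral base is the outgroup base when it matches either descendant;
  the rate of X→Y at an offset is count(X→Y)/all determined sites, so a
  change and its reverse are directly comparable. Flow-in/flow-out per
  base balance exactly with the net incidence change. Directional
  contrasts (dyad vs linker windows, C→T vs G→A up/downstream) use
  one-tailed Wilcoxon rank-sum tests.
- **Correlation screen.** 48 parameters per TSS (expression, breadth,
  periodicity and consistency per strain × tissue × side, base counts and
  asymmetries) enter a Spearman matrix; significance is Bonferroni-held at
  0.05/1128 ≈ 4.4 × 10⁻⁵.

## Worked example

```sh
echo '{"genome_length": 300000, "n_promoters": 100}' > small.json
nucleocyclic all --seed 5 --config small.json --out run1
```

prints `{"1": 34, "2": 33, "3": 33}` (the three consistency groups) and
writes `run1/report.json`, which for this seed contains:

- 100 representative TSSs called (55 active in all three tissues);
- estimated core fragment length **147 bp** (the simulated truth);
- 704 stable dyads per tissue;
- upstream A excess: z = **+11.9** (p ≈ 7 × 10⁻³³), C deficit z = **−13.1**
  — the A/T-rich upstream / C/G-rich downstream promoter boundary;
- Group-1 expression above the rest (one-tailed rank-sum p ≈ 8 × 10⁻⁵,
  median log₁₀ expression 3.46 vs 3.00);
- downstream-consistency × expression Spearman r ≈ **0.35** (p ≈ 4 × 10⁻⁴;
  at this small scale above the Bonferroni level — the full-scale run
  below clears it, p ≈ 10⁻¹⁹).

`run1/` also holds representative-TSS and phasing tables (TSV), stable
dyads (BED), the Spearman matrix, and a manifest with checksums; the same
seed reproduces every file byte for byte.

Library use mirrors the CLI: `synthetic_data` simulates worlds,
`tss_model` / `nucleosome_map` / `phasing` / `seqcomp` / `evolution` /
`correlate` / `group_comparisons` expose each stage, and
`pipeline.run_pipeline` orchestrates them.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch on the coupled synthetic world
(600 promoters on a 1.2-Mb genome): it generates the genome and strain
histories, calls TSSs and dyads, estimates the fragment length, groups
TSSs by downstream consistency, and runs the asymmetry, flux, correlation
and group tests, printing the complete run report to stdout and writing
the results file to `--out`. See `docs/methods.md` for model assumptions,
parameter defaults, and known limitations.
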