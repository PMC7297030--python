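# Methods

## Segregation-type expectations

A marker SNV in an F1 cross of two outbred parents is described by the
ordered allele pair of each parent, the first allele being the one on the
haplotype that carries the recessive allele of the trait locus the marker is
linked to.  Twelve such phase-resolved derivatives segregate (at least one
parent heterozygous).  Expectations assume complete marker–locus linkage and
Mendelian transmission; the trait is expressed only in offspring homozygous
recessive at every modelled locus — one locus, or two unlinked loci with all
parents heterozygous at each (probability (1/4)ⁿ).

The recessive-pool allele frequency follows directly from the phase: the
recessive class is fixed for each parent's first marker allele.  The
dominant-pool frequency is the Mendelian total minus the recessive class:

    AF_dom = (E[dose] − dose_rec · (1/4)ⁿ) / (2 · (1 − (1/4)ⁿ))

All arithmetic is carried in exact rationals (`fractions.Fraction`) and
converted to the percent scale at the boundary, so equality tests against
the published one-decimal values (33.3/46.7, 66.7/73.3, 16.7/23.3; AFDD
66.7/53.3 and 33.3/26.7 percentage points) are exact.  An independent
enumeration route over all gamete combinations (`pool_af_from_enumeration`)
cross-checks the closed form in the test suite for all 12 × 2 cases.
Exactly five derivatives have positive AFDD (types A–E); the other seven are
uninformative (equal pool AFs or negative difference).

Filter windows are stored as the published decimal constants (A:
AF(rec) ≥ 85, AFDD ≥ 43.3; B/C: AF(rec) ≥ 85, 16.7 ≤ AFDD < 43.3; D/E:
35 ≤ AF(rec) ≤ 65, 16.7 ≤ AFDD ≤ 43.3), not recomputed from fractions.  The
B/C upper AFDD bound is half-open so the A and B/C windows partition their
shared source group.

## The synthetic experiment

The generator reproduces the statistical structure the scan assumes, at a
size a laptop handles in about two seconds per replicate:

- **Genome**: 5 chromosomes × 30 Mb, SNV density 1/10 kb (≈15,000 sites).
  Each site draws a segregation-type derivative from a mixture: weight 0.075
  for each of the 12 segregating derivatives, 0.10 for non-segregating
  homozygous-variant sites (reference-homozygous sites carry no variant and
  are never emitted).  The uniform mixture is a neutral choice; empirical
  proportions in any real genome depend on its heterozygosity structure.
- **Trait loci**: a dominant Co-like locus (chr1:28 Mb, both parents
  heterozygous; in coupling with the suppressor in the seed parent and in
  repulsion in the pollen parent) and two recessive suppressors:
  locus 1 at chr1:26.5 Mb heterozygous in both parents, locus 2 at
  chr2:14.5 Mb homozygous recessive in the seed parent and heterozygous in
  the pollen parent — the configuration inferred for the real cross.  Both
  positions sit mid-window so a causal locus is not split across a tiling
  boundary by construction of the coordinate grid.
- **Recombination**: Haldane model (no interference); crossovers realised as
  a Markov chain along each chromosome with switch probability
  (1 − e^(−2d))/2 per interval.  Default 5 cM/Mb: appropriate for a 150-Mb
  genome (Arabidopsis-like) and consistent with the locally observed
  recombination between the dominant locus and its nearest marker in the
  source cross (≈0.08–0.11 over 1.65 Mb).
- **Phenotypes**: offspring without the dominant allele are always standard.
  Carriers homozygous recessive at all suppressor loci express the
  suppressed phenotype in evaluation round *t* with penetrance
  (0.867, 0.667, 0.448) — the observed double-recessive frequencies across
  the three evaluation years; other carriers leak into the suppressed class
  at 0.03 per round (the order of the observed non-recessive class rates,
  0.018–0.107).  A single latent uniform per individual makes expression
  persistent, so individuals revert from standard to columnar as penetrance
  falls with age, never the reverse — matching the observed monotone decline
  of the suppressed class.  The split of each binary class into the two
  cosmetic sub-scores (1/2 and 3/4) is Bernoulli(0.5).
- **Pools**: 16 suppressed-phenotype and 18 dominant-phenotype carriers,
  sampled uniformly without replacement from the first evaluation round
  (highest penetrance, hence the deepest pool of available suppressed
  carriers; the latent-uniform model makes later-round suppressed sets
  subsets of this one).  Non-carriers are never pooled.
- **Reads**: per site, depth ~ Poisson(22.5) in the recessive pool and
  Poisson(34.6) in the dominant pool; variant reads ~ Binomial(depth,
  f(1−ε) + (1−f)ε/3) with true pool frequency f and substitution error
  ε = 0.002.  Reads are emitted at every segregating site in both pools;
  read-level artefacts (mapping bias, indel noise, duplicated reads) are not
  modelled, so QC removal rates on synthetic data reflect depth alone.
- **Randomness**: one integer seed feeds named `numpy.random.SeedSequence`
  children per stage; identical (config, seed) gives byte-identical tables.

One cross direction is simulated (the reciprocal contribution in the real
population was small and ignored there too).

## Scan methodology

Window counts use a non-overlapping 1-Mb tiling by default (counts are then
conserved per chromosome); an overlapping step is available.  Input
positions are 1-based, window and peak coordinates 0-based half-open (BED).
Trailing partial windows are scored but excluded from background estimation.

The z score compares each window's informative-SNV count with a genome-wide
background mean and SD.  The pipeline default estimates that background by
sigma-clipping to convergence, seeded with median/IQR so that extreme peaks
cannot inflate the initial spread and mask themselves: on a 150-window
genome the handful of windows carrying the causal signal would otherwise
contribute a large share of the empirical variance and bias the test against
its own target.  Plain empirical moments and a Poisson-SD variant remain
available (`dispersion="empirical" | "poisson"`).  Poisson dispersion is
deliberately not the default: linked sites within a window share
pool-composition noise, which overdisperses background counts relative to
Poisson and would inflate the false-positive rate.

Peak declaration uses the combined informative track *and* the pooled
A + B/C track.  The homozygous-class types carry most of the mapping power
at a far lower background density, and the real loci in the source study
were determined by types A–C; single-type tracks are not tested separately
because their desk-scale window counts (mean < 1) put the normal
approximation out of its depth.  LODz is computed on the log scale
(`-log10(2·Φ(−|z|))`), so very strong peaks do not underflow.  A peak region
is a run of windows with z > 0 and LODz > 2.5; the pipeline tolerates one
sub-threshold window inside a region (`merge_gap=1`) because a region linked
to one causal locus is genetically contiguous, while the `call_peaks`
function itself defaults to `merge_gap=0`.

## Confirmation statistics

`gof_chi_square` is the Pearson statistic without continuity correction
(required to reproduce the published worked examples 1.029, 47.04, 16.49,
82.46 from their counts).  Allele-distortion tests compare the transmitted
parental alleles in a phenotype group against 1:1 and report a marker-
homozygous parent as "uninformative" rather than testing it.  The
genotype-class phenotype-frequency table excludes non-carriers and, by
default, recombinants between the dominant locus and suppressor locus 1.
Score-on-genotype regression codes each locus as categorical class
indicators (ordinary least squares via statsmodels); the overall-F p value
is reported, and a joint two-locus fit never undercuts the nested
single-locus fits.

## What the synthetic validation does and does not show

Parameter-recovery runs at the default scale recover the both-parent-
heterozygous suppressor essentially always (20/20 seeds, region overlapping
the locus within 1 Mb), with the A/B–C types driving the causal windows.
The second suppressor — homozygous in one parent, so informative only
through the C- and E-pattern sites, about 2/12 of segregating markers — is
recovered in well under half of replicates at this marker density
(~100 sites/Mb): its expected informative excess is ~4–6 SNVs per window
against a background SD of ~2.5–3.5, an expected z below the |z| ≈ 2.95
implied by the LODz 2.5 cutoff.  This is a density limit, not an estimator
choice: scaling the source study's corresponding peak (LODz ≈ 12 at ~30×
this marker density) by the square root of the density ratio lands below
the cutoff as well.  Detecting such a locus reliably requires the full
marker density of a real pooled-sequencing experiment; the desk-scale runs
validate the machinery and the strong-locus case, not the power of the
method at full scale.  About one to two additional sub-threshold-adjacent
regions per genome are called on average, most of them detached linkage
shoulders of the true loci — comparable to the unconfirmed candidate
regions the method produced on real data.

## Degenerate inputs and numerical notes

- QC raises on malformed records (variant reads exceeding depth) instead of
  dropping them; duplicate (chrom, pos, ref, alt) keys within a pool are an
  error; a tri-allelic position yields two pool-specific records.
- Common SNVs below the 15% heterozygote floor in either pool are left
  "ungrouped" and take no further part in the scan.
- A single full window cannot be scored (no dispersion); uniformly equal
  counts give z = 0 everywhere.
- AF is undefined (NaN) at zero depth; such records never survive QC.
- Chromosome names present in a pool table but absent from the genome table
  abort the scan with the offending contig named.
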