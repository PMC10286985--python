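# Methods

## Problem and overall model

Laboratory strains of the marine midge *Clunio marinus* synchronize adult
emergence to the lunar phase via a circalunar clock entrained by moonlight
(30-day regime) or tidal mechanical agitation (15-day semilunar regime).
Some strains have lost sensitivity to the mechanical cue: their emergence
under turbulence entrainment is arrhythmic.  The package maps the genetic
basis of that loss in experimental crosses between a sensitive and an
insensitive strain.  The analysis chain is:

1. **Rhythm phenotyping** (`circstats`).  Emergence days folded onto the
   zeitgeber cycle are treated as circular data.  The mean resultant vector
   length R measures rhythm strength (R = 1 perfectly synchronized, R = 0
   uniform/arrhythmic); the derived dispersions are circular SD
   `sqrt(-2 ln R)`, angular variance `2(1-R)`, and angular deviation
   `sqrt(2(1-R))`.  Angles use the convention theta = 2*pi*day/period, so
   day = period wraps to 0; mean directions just past the cycle anchor
   therefore appear as small values (e.g. 0.04).  The circular median is the
   observed day minimizing mean circular arc distance, ties broken toward
   the mean direction then toward the smaller day (the convention is ours;
   the statistics are identical on per-individual or count-weighted input).

2. **Probability phenotyping** (`phenotyping`).  F2/BC progeny emerging in
   the sensitive-parent peak may still be genetically insensitive.  Each
   individual therefore receives P(insensitive | emergence day) from a
   two-component mixture: per-day reference densities f_S (sensitive parent
   KDE) and f_I (insensitive parent KDE), mixing proportion pi fitted by EM
   on the progeny days (init 0.5, tolerance 1e-8 on pi, cap 10,000
   iterations), posterior p_I(d) = pi f_I / (pi f_I + (1-pi) f_S).  Before
   phenotyping, progeny distributions are phase-corrected onto the sensitive
   reference by an integer-day circular shift of the mean directions
   (integer because lunar days are integers; skipped with a warning when the
   reference R < 0.2, where phase is undefined).  Phase correction cannot
   change R, so only rhythmicity is scored.  The reduced dataset binarizes
   with strict thresholds: p > 0.7 insensitive, p < 0.3 sensitive, the rest
   excluded.  The population phenotype ratio is 100 x mean posterior,
   rounded — under a converged EM this equals the fitted mixing proportion.

   *Kernel choice.*  The KDE is circular with a von Mises kernel whose
   concentration equals the `bandwidth` parameter (default 10), the
   convention of circular density estimators such as R's
   `density.circular`.  Under the alternative reading — a wrapped Gaussian
   with SD of 10 days — both reference densities on a 15-day cycle are
   numerically uniform (max/min < 1.02), the mixing proportion is
   unidentifiable, and no phenotype information survives; concentration 10
   (kernel SD about 0.8 days) instead reproduces the peaked smoothed
   emergence distributions this design presumes.  Both kernels are
   available (`kernel='vonmises' | 'wrapped_gaussian'`).

3. **Genotype matrices** (`crossmap`).  VCF genotypes are filtered at
   minGQ 20 (failing genotypes set missing), minor allele frequency 0.10,
   and maximum missing fraction 0.60; multiallelic sites are dropped.
   Informative markers: F2 keeps AB x AB parents; BC keeps AB x AB and
   AB x homozygous-recurrent, each tagged with its expected offspring
   classes (1:2:1 or 1:1).  Where parental genotypes leave the A/B polarity
   ambiguous, each marker is relabeled (identity or A<->B swap), left to
   right along the chromosome, to minimize genotype switches against the
   nearest previously resolved marker across all individuals; ties keep
   identity, and a chromosome with no unambiguous anchor fixes its first
   marker to identity.  Recombination events are genotype changes between
   consecutive non-missing calls of one individual; missing calls are
   bridged, the event being assigned to the flanking-marker interval; an F2
   AA<->BB jump involves two recombinant gametes and by default counts as
   two events (configurable, since published event totals may count either
   way).  Genetic maps use the Kosambi function d = 0.25 ln((1+2r)/(1-2r)):
   adjacent r is the switch fraction in a BC and the maximum-likelihood
   estimate from the 3x3 joint genotype table in an F2 (bounded search on
   (1e-6, 0.49)); estimates at or above 0.5 are capped at 0.49.

4. **QTL scans** (`qtlscan`).  Conditional genotype-class probabilities are
   computed by a forward-backward hidden Markov pass per chromosome with
   transition probabilities from the inverse Kosambi function of each cM
   gap, a symmetric genotyping-error emission (epsilon = 1e-4), and grid
   step 1 cM (markers only for the simulation studies; the scans are
   insensitive to the step at the marker densities used).  Quantitative
   traits (the probability phenotype) use Haley-Knott regression on
   expected dosages, LOD = (n/2) log10(RSS0/RSS1); binary traits use a
   logistic likelihood ratio, LOD = (LL1 - LL0)/ln 10.  This replaces the
   EM-normal-mixture interval mapping of classical packages; at these
   marker densities the numeric difference is small and the model flag
   isolates the choice.  Significance is the 95th percentile of the
   genome-wide maximum LOD over 1000 phenotype permutations (seeded).
   Credible intervals normalize 10^LOD over a chromosome and grow the
   interval from the peak toward the higher-mass neighbor until 95% mass.
   Composite interval mapping backward-eliminates marker cofactors
   (smallest-|t| first) from the 30 strongest single-marker candidates down
   to 5, and drops cofactors within 10 cM of the test position.  The
   two-locus scan compares null, additive, and full (interaction) models on
   a 2.5 cM coarse grid: LODf = full vs null, LODi = full vs additive.
   `fit_multiple_qtl` jointly regresses on all term dosages (products for
   interactions), reporting 100(1 - RSS_full/RSS_null) and drop-one
   variance shares with F statistics; dropping a locus also drops its
   interactions.

5. **Panel optimization** (`empanel`).  Each of n_runs (default 1000)
   restarts draws a binary panel b_i ~ Bernoulli(p_i) and greedily
   coordinate-ascends on the genome-wide maximum LOD: individuals are swept
   in random order, any flip that raises the maximum is accepted, and the
   run stops after an improvement-free sweep.  Identical final panels are
   grouped; convergence % = runs reaching the panel / n_runs; error
   fraction = share of individuals with |b_i - p_i| > 0.1 (strict
   inequality); only panels with convergence >= 5% are reported, each with
   the peak and 95% interval of a binary logistic scan.  A run fails when
   its final maximum LOD falls below the maximum LOD of the quantitative
   scan of the starting probabilities — the natural reading of "no panel
   better than the starting one", and the only reading under which an
   already-binary input trivially converges to itself.  Inside the ascent,
   panels are scored by the Haley-Knott regression LOD of the 0/1 vector
   (the standard regression scan of a binary trait): the per-position
   designs are QR-factorized once and a flip is a rank-one update, making a
   full evaluation O(positions), about three orders of magnitude faster
   than refitting logistic models; reported panels still get genuine
   logistic scans.  The known-locus validation blurs a known binary
   phenotype (sex) under lettered scenarios — A/B/C keep 75/50/25% of
   phenotypes exact and blur the rest to U(0.5, 0.99)/U(0.01, 0.5); D-G
   blur everyone with ranges narrowing toward 0.5 (G's true-1 range, not
   stated in the source protocol, mirrors its true-0 range); the logistic
   family maps u ~ U(0,1) through 1/(1+exp(-k(u-0.5))) reflected to the
   true side of 0.5 — then re-optimizes panels and checks interval coverage
   of the true locus.  Note the direction of difficulty: D's draws extend
   toward certainty (0.99) while F's stop at 0.75, so F and G are the more
   uncertain scenarios despite their narrower ranges.

6. **Simulation** (`synthdata`).  The generator emulates the mapping
   design: two fully homozygous parental strains (sensitive: von Mises
   emergence, default peak day 12 and concentration kappa = 2.6, chosen to
   give vector length ~0.77 like a strongly entrained sensitive strain;
   insensitive: kappa = 0, uniform), F1s heterozygous everywhere, F2/BC
   progeny from Poisson-count, uniform-position crossovers (Haldane, no
   interference — mapping then uses Kosambi; the deliberate mismatch is
   bounded by the 15 cM recovery tolerance).  Marker maps default to 3
   chromosomes x 45 markers at 2.5 cM (~110 cM each, echoing ~130-marker
   maps on three chromosomes).  Inversion blocks suppress crossovers
   exactly (positions are drawn from the non-block cM measure), giving the
   non-recombining marker blocks seen over polymorphic inversions.
   Insensitivity is drawn by penetrance given the genotype at the
   architecture loci (default: one locus, chr2 at 55 cM, recessive with
   penetrance 1 for the insensitive homozygote — hence 25% insensitive in
   F2 and 50% in a backcross to the insensitive parent); multiple loci
   combine by noisy-OR, and epistatic pairs override their members with an
   explicit two-locus penetrance table.  BC genotypes are coded relative to
   the recurrent parent (recurrent homozygote AA, het AB), so no BB call
   can occur.  Von Mises draws are rounded to the nearest integer day with
   the period boundary wrapping to day `period`.  A sex locus is modeled as
   heterozygosity at the nearest marker (het = male), giving a 1:1 binary
   phenotype in perfect linkage for validation.  What the generator does
   *not* emulate: genotyping error profiles of RAD data, segregation
   distortion, crossover interference, family structure in the reference
   panels, and day-to-day census noise — so passing tests demonstrate
   correctness of the machinery under the assumed model, not robustness to
   every artifact of real cross data.

## Numerical choices

- EM for the mixing proportion: init 0.5, stop when |pi_t+1 - pi_t| < 1e-8,
  cap 10,000 iterations; identical densities raise an error
  (unidentifiable); a day where both densities vanish is an error.
- R = 0 exactly reports circular SD = +inf rather than erroring.
- LOD computations clip RSS at 1e-12 and floor LOD at 0; logistic Newton
  uses a 1e-8 ridge guard and clips eta at +-30.
- Permutation thresholds are chunked (default 200 phenotypes per block) to
  bound memory; seeds recorded.
- Panel-scorer flip comparisons use an absolute 1e-9 improvement margin;
  run failure uses a relative 1e-6 margin against the reference LOD so that
  float noise at numerically extreme LODs (perfectly separating panels)
  cannot misclassify a run.
- Bounded scalar ML for F2 adjacent r; r capped at 0.49 before the Kosambi
  transform (d diverges at 0.5).

## Problem sizes in the validation studies

Simulation studies run at the design sizes of the mapping families they
emulate: BC n = 100-200 and F2 n = 150-400 progeny, 135 markers; type-I
error calibration uses 500 null replicates with 1000-permutation
thresholds; QTL recovery uses 50 replicates of a 25%-variance locus; the
sex-locus validation uses 20 seeds x 200 optimizer runs per blur scenario.

## Known limitations

- The per-day probability equations behind the mixture posterior and the
  exact step rules of the panel optimizer are reconstructions; both are
  isolated behind single functions (`mixture_posterior`, the ascent loop in
  `optimize_panels`) so alternatives (fixed Mendelian priors, batch flips,
  annealing acceptance) can be swapped.  Published convergence percentages
  of specific panels depend on the unpublished step rules and are not a
  validation target; the sex-locus protocol is.
- Haley-Knott on probability phenotypes treats a bounded [0,1] trait as
  Gaussian; this mirrors standard practice and the affine invariance of the
  LOD, but extreme mixing proportions compress the trait scale.
- Kernel smoothing widens the sensitive reference density relative to the
  true emergence distribution, so the sensitive mixture component absorbs
  some uniformly emerging (insensitive) progeny near the peak: the
  estimated insensitive percentage runs 2-4 points below the Mendelian
  truth at the default strain concentration (kappa = 2.6), inside the +-5
  point band the ratio-recovery checks use.  Sharper parental rhythms
  shrink the bias.
- De novo linkage grouping/ordering is out of scope: marker order comes
  from the reference genome (inversions are logged, not reordered).
- The allele-polarity resolver cannot recover the polarity of a
  chromosome's first marker when it has no unambiguous anchor; it is fixed
  to identity and flagged.
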