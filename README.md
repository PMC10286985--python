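# lunaqtl

QTL mapping of circalunar zeitgeber-entrainment phenotypes in experimental
crosses, from raw emergence records to localized loci.

## The scientific problem

Marine midges (*Clunio marinus*) time adult emergence to the lunar phase
with a circalunar clock entrained by moonlight or by the semilunar cycle of
tidal mechanical agitation.  Some strains have lost sensitivity to the
mechanical cue: under turbulence entrainment they emerge arrhythmically.
Mapping the loci behind that loss in F2/backcross families faces a specific
obstacle — a progeny individual emerging inside the sensitive-parent peak
may be either genotype, so phenotypes are inherently probabilistic.

`lunaqtl` implements the full analysis chain for this setting, for
geneticists running experimental crosses with rhythm phenotypes:

- **Circular statistics** of emergence-day distributions on a periodic
  axis.  Rhythm strength is the mean resultant vector length
  R = |sum_j e^(i theta_j)| / n with theta = 2*pi*day/period; dispersion
  follows as circular SD sqrt(-2 ln R), angular variance 2(1-R), angular
  deviation sqrt(2(1-R)).
- **Mixture phenotyping**: per-day posterior probability of being
  insensitive, p_I(d) = pi f_I(d) / (pi f_I(d) + (1-pi) f_S(d)), from
  circular kernel density estimates of the parental distributions and an
  EM-fitted mixing proportion pi; binarized "reduced" datasets at the
  0.3/0.7 thresholds; phenotype-ratio estimates.
- **Cross genotype matrices**: VCF filtering (minGQ 20, MAF 0.10,
  missingness 0.60), informative-marker selection, allele-polarity
  resolution by along-chromosome consistency, recombination-event
  accounting, Kosambi genetic maps.
- **QTL scanning**: HMM conditional genotype probabilities, Haley-Knott
  (quantitative) and logistic-LRT (binary) single-QTL scans with
  LOD = (n/2) log10(RSS0/RSS1), 1000-permutation 5% thresholds, 95%
  Bayesian credible intervals, composite interval mapping (5 cofactors,
  10 cM window), two-locus LODf/LODi scans, and multiple-QTL fits with
  percent-variance decomposition.
- **Binary phenotype-panel optimization**: stochastic restarts of a greedy
  coordinate ascent that flips individual phenotypes to maximize the
  genome-wide LOD, with convergence-percentage and error-fraction
  diagnostics and a known-locus (sex) validation protocol.
- **Forward simulation** of strains, crosses, and emergence data with
  planted architectures, inversion blocks, and a sex locus, so the whole
  chain is testable without any external data.

## Worked example

Simulate a backcross of 200 progeny segregating a recessive insensitivity
locus on chromosome 2 at 55 cM, phenotype it from emergence days, and scan:

```python
from lunaqtl import synthdata, phenotyping, qtlscan

sim = synthdata.simulate_cross(synthdata.ArchitectureConfig(), "BC", 200, seed=1)
sens = synthdata.simulate_strain_emergence(synthdata.SENSITIVE_DEFAULT, 300, 2)
insens = synthdata.simulate_strain_emergence(synthdata.INSENSITIVE_DEFAULT, 300, 3)

pheno, profile, shift = phenotyping.probability_phenotypes(
    sim.emergence, sens, insens, phenotyping.TURBULENCE)
print("mixing proportion:", round(profile.mixing_proportion, 3))
print("sensitive:insensitive =", phenotyping.estimate_ratio(pheno["p_insensitive"]))

grid = qtlscan.genotype_probabilities(sim.matrix, step_cM=None)
y = pheno["p_insensitive"].to_numpy()
scan = qtlscan.scan_single(grid, y)
thr = qtlscan.permutation_threshold(grid, y, n_perm=1000, seed=1)
lo, hi = qtlscan.bayes_interval(scan, scan.peak_chromosome)
print(f"peak {scan.peak_chromosome} @ {scan.peak_cM} cM, LOD {scan.max_lod:.2f} "
      f"(threshold {thr:.2f}), 95% interval [{lo}, {hi}] cM")
```

Output:

```
mixing proportion: 0.452
sensitive:insensitive = (55, 45)
peak chr2 @ 55.0 cM, LOD 22.53 (threshold 2.29), 95% interval [55.0, 55.0] cM
```

Read: the mixture fit estimates ~45% insensitive progeny — the Mendelian
expectation for a backcross to the insensitive parent is 50% — and the
scan localizes a highly significant QTL (LOD 22.5 against a genome-wide
5% threshold of 2.3) whose 95% credible interval sits exactly on the
planted locus at 55 cM.

The same pipeline runs from the shell:

```
lunaqtl simulate --cross-type BC -n 200 --seed 1 --out sim/
lunaqtl summarize sim/emergence.csv --out summary.csv
lunaqtl run --config examples/demo.yaml   # phenotype -> reduce -> scan -> cim
                                          # -> fitqtl -> panel optimization
```

The demo config completes in under a minute and writes phenotype,
profile, scan, composite-interval-mapping, multiple-QTL-fit, and panel
reports (each with a JSON provenance sidecar) to `demo_out/`.

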