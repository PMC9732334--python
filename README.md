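# parapop

Population-genomic inference for a case of parapatric speciation with a
shift to self-fertilization: a selfing species (*Arabidopsis
arenicola*-like) budding from an outcrossing parent (*A. lyrata*-like) at
an expanding post-glacial range edge. The package provides the full
inference chain such a study needs, together with synthetic-data
generators with known ground truth so that every estimator can be tested
for parameter recovery:

* **structured-coalescent simulation** of population splits, migration and
  partial selfing (the equilibrium identity-by-descent shortcut
  F = s/(2−s)), producing polarized diploid genotypes at independent
  non-recombining loci;
* **joint unfolded site-frequency spectra** over pooled super-populations,
  with the study's variant filters (biallelic, minor allele count > 3,
  20 kb thinning) as explicit, separate operations;
* **composite-likelihood demographic fitting**: the expected SFS is
  approximated by Monte-Carlo coalescent (branch-length accumulation),
  lnCL = Σ m·ln p over polymorphic cells, free parameters are optimised
  ECM-style with multi-start and common random numbers, concurrent models
  compared by AIC = 2k − 2 lnCL, winners propagated through sequential
  hierarchical selection steps, and uncertainty quantified by parametric
  bootstrap;
* **introgression tests**: Patterson's D = (ABBA − BABA)/(ABBA + BABA) in
  allele-frequency form with delete-one block-jackknife Z scores;
* **mating-system estimation**: multilocus F_IS = 1 − ΣH_obs/ΣH_exp with
  sample-size-corrected H_exp, equilibrium conversions F = s/(2−s),
  t = 1 − s, and the detection-corrected progeny-array outcrossing-rate
  estimator t̂_m = (detected fraction)/mean(P_det);
* **individual-level LD** by the correlation of zygosity Δ(d) — the
  within-genome correlation of heterozygosity status between sites at
  distance d — and its extent, the distance at which the first-bin-scaled
  Δ decays to 0.1;
* **mutational load**: per-sample counts of homozygous MODERATE- and
  HIGH-impact variants (SnpEff-style ANN annotations), geodesic
  expansion-route distances, and OLS regression of load on log10 distance.

Interchange formats are VCF 4.x (GT, optional ANN), tab-separated sample
metadata, YAML demographic-model configs, and a documented text layout for
multidimensional SFS.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data (intermediate datasets are written to `scratch/`, tables to
`results/`):

```
python analysis/01_simulate_data.py  --seed 1
python analysis/02_build_sfs.py      --seed 1
python analysis/03_fit_demography.py --seed 1
python analysis/04_introgression.py  --seed 1
python analysis/05_mating_system.py  --seed 1
python analysis/06_ld_zygosity.py    --seed 1
python analysis/07_load_geography.py --seed 1
```

At seed 1 the drivers print:

```
split time: 5820 generations (95% CI 5284-6341); 5820-11641 years at 1-2 yr/generation
step backbone_topology: selected sister_P1P2 (AIC 11923.0)
step derived_placement: selected are_from_P2 (AIC 16345.2)
D null calibration over 40 replicates: mean D = -0.0058, |Z| < 3 in 100%
 selfing_rate  equilibrium_F  mean_FIS  ...
        0.649           0.48     0.494  ...
        0.734           0.58     0.590  ...
progeny arrays under complete selfing: t_m = 0.0 (SD 0.0)
parent_selfer_like (rho=0.999): theta=0.207, LD extent 2137 bp (closed form 2301 bp)
expansion-load regression: slope +2.0 load units per log10(km), r = 0.54, p = 0.032 (n = 16)
```

Reading the output: data simulated under a split 6007 generations ago are
refit to 5820 generations with a bootstrap interval covering the truth;
AIC model selection recovers both the generating backbone topology and
the placement of the derived selfer; Patterson's D stays null when there
is no gene flow; genotypes at inbreeding equilibrium under selfing rates
0.6486 and 0.7342 yield multilocus F_IS near 0.48 and 0.58; fully selfed
progeny arrays give an outcrossing rate of exactly 0.0 (SD 0.0);
heterozygosity tracts with persistence ρ = 0.999 decay to a 10% scaled Δ
at ≈ 2.3 kb; and serial founder events along an expansion route produce
the expected positive load-distance slope.

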