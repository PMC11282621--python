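# capricline

Tools for testing whether genome-wide diversity of livestock populations
declines with distance from their domestication centre — built around the
goat (*Capra hircus*) SNP-array data sets sampled across Europe, Africa and
Asia, with Ganj Dareh (Zagros Mountains, western Iran; early evidence of
goat management ~10,000 years before present) as the dispersal origin.

A range expansion that proceeds by serial founder events erodes
heterozygosity at every foundation: after *s* bottlenecks of *N_b* diploid
founders, expected heterozygosity shrinks as

    E[He_s] = He_0 · (1 − 1/(2·N_b))^s

so breeds sampled farther along a dispersal route should be less diverse
and more differentiated from populations near the origin.  The package
measures this with:

- **Ho** — observed heterozygosity: per-locus fraction of heterozygous
  genotypes, averaged over loci;
- **He** — Nei's unbiased gene diversity: 2n/(2n−1) · 2p(1−p) per locus;
- **Fis = 1 − Ho/He** — positive under homozygote excess (inbreeding),
  negative under a deficit (e.g. admixture);
- **Fst** — Weir–Cockerham θ against a reference breed raised near the
  origin (the Iranian Markhoz), combined across loci as Σa / Σ(a+b+c);
- **Vincenty ellipsoidal distance** (WGS84) from each breed's sampling
  site to the origin;
- **Pearson correlation** r of each statistic against distance, with the
  exact two-sided t-transform p-value, over configurable breed subsets
  (continents, with/without insular breeds, without commercial breeds);
- **IDW interpolation surfaces** of Ho/He/Fis with ten equal classes, and
  **genotype PCA** with per-breed centroids, for structure summaries.

Genotypes come in as PLINK text PED/MAP; QC covers MAF, SNP/individual
missingness, a Hardy–Weinberg conditional exact test, unmapped SNPs, and
covariance-preserving per-breed subsampling.  A serial-founder simulator
generates breeds along a synthetic dispersal route with the closed-form
decay law above, so the entire pipeline is testable end to end without any
external download.  The published per-breed tables (40 European, 43
African and 22 Asian breeds) ship with the package.

## Worked example

Diversity-vs-distance regression for the African breeds, excluding the
three commercial South African breeds and the insular populations
(Madagascar, Canary Islands):

```sh
$ capricline cline --preset africa_no_islands
statistic_name      subset_label  n_breeds         r  p_two_sided     slope  intercept  n_dropped
            ho africa_no_islands        37 -0.457551     0.004409 -0.000006   0.422158          0
            he africa_no_islands        37 -0.489531     0.002105 -0.000006   0.422744          0
    fst_vs_ref africa_no_islands        37  0.615413     0.000050  0.000007   0.023077          0
```

Observed and expected heterozygosity fall significantly with distance to
Ganj Dareh (r ≈ −0.46 and −0.49; a loss of about 0.006 heterozygosity per
1000 km from a near-origin baseline of ~0.42), and differentiation from
the Markhoz reference rises (r = 0.62) — the classic footprint of an
overland serial-founder expansion.  Running the same command with
`--preset europe_all` gives r = −0.47 (Ho), but the European gradient is
carried almost entirely by the depauperate British and Irish breeds: with
`--preset europe_no_british_irish` it weakens to r = −0.28 and loses
significance.

The same machinery runs on simulated data:

```sh
$ capricline simulate --seed 3 --n-populations 4 --n-loci 200 --sample-n 10 --out-prefix demo
$ capricline stats demo.ped demo.map --reference POP01 --out div.csv
breed_id       ho       he       fis  fst_vs_ref
   POP01 0.387962 0.380211 -0.020386         NaN
   POP02 0.381306 0.378884 -0.006390    0.017625
   POP03 0.362556 0.361262 -0.003579    0.021495
   POP04 0.370333 0.364085 -0.017162    0.033578
```

Each population along the route is one founder event farther from the
origin: heterozygosity drifts downward and θ against the origin
population grows monotonically.

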