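# cnamcr

Copy-number analysis of two-channel array-CGH tumor/normal profiles:
interval-score segmentation, cross-sample common-aberration statistics,
recurrent-region (CNAR/MCR) extraction across array platforms of different
probe density, MLPA validation calling, and the association statistics that
link copy-number alterations (CNAs) to gene expression and
clinicopathological variables.

The package targets the analysis style of multi-platform gastric-cancer
aCGH cohorts — probe-level log2(Cy5/Cy3) ratios per tumor/normal pair,
measured on dense (400K/244K) and custom (60K) oligonucleotide arrays —
but every stage is generic over any probe design. A synthetic cohort
generator with planted ground truth makes the whole pipeline testable
without any data download.

## The model in brief

For a normalized log2-ratio profile r with per-array noise sigma (estimated
by the derivative log-ratio spread, DLRS), a probe interval [i, j] scores

    S(i, j) = | Σ_{k=i..j} r_k / σ | / √(j − i + 1)

Segments are extracted greedily per chromosome: take the maximum-score
interval, keep it if S ≥ 6.0, recurse on the flanks. Calls are filtered to
≥3 probes and |mean log2| ≥ 0.25; |mean log2| ≥ 0.8 marks amplification /
deletion. A fuzzy-zero correction re-tests each segment with an inflated
variance term ν (|mean| / √(σ²/n + ν²)) to suppress long, faint calls.

Across samples, probe j's carrier count K_j is tested against the exact
Poisson-binomial null built from each sample's genome-wide aberrant
fraction ("context"); runs of probes with p < 0.05 whose supporting calls
reciprocally overlap the run by ≥ 0.9 are common aberrations. A **CNAR** is
the union hull of same-direction calls linked by reciprocal overlap > 0.9;
an **MCR** is the intersection of all member segments of CNARs observed on
every platform. Recurrence filters are >20% of the cohort (all calls) and
≥10% (amplification/deletion classes).

MLPA peak ratios (control-probe scaled, population-normalized) call
deletion below 0.75 and amplification above 1.25. Expression uses the
ΔΔCt method (FC = 2^−ΔΔCt against an RPLP0-style reference gene) with a
two-sided one-sample t-test on log2 FC; clinical analyses use chi-square /
Fisher 2×2 tests, Pearson correlation with Bonferroni correction,
average-linkage hierarchical clustering, and Kaplan–Meier / log-rank
survival comparison.

## Worked example

```bash
cna-mcr run --seed 11 --outdir run11
```

simulates the default cohort (88 tumors: 30 + 10 + 48 samples on three
platform densities over a 3 × 10 Mb mini-genome), normalizes (lowess →
quantile → centralization), segments, and extracts common aberrations and
recurrent regions. `run11/recurrent_mcrs.tsv` then contains, e.g.:

```
kind  chrom  start    end      direction  n_support  frequency  percent  platforms
MCR   chr1   7027004  7243402  loss       33         0.3750     37.5     acgh-244k,acgh-400k,acgh-60k
MCR   chr2   5015640  5474513  gain       22         0.2500     25.0     acgh-244k,acgh-400k,acgh-60k
MCR   chr3   8015256  8149178  loss       24         0.2727     27.3     acgh-244k,acgh-400k,acgh-60k
```

Each row is a minimal common region supported on all three platforms: the
interval shared by every member call, the number of distinct supporting
samples, and the cohort frequency. `calls.seg` holds the per-sample
segment calls (SEG format), `common_aberrations.tsv` the context-corrected
per-platform common regions with their Poisson-binomial p-values, and
`truth.json` the planted ground truth for comparison.

The same stages are available as library functions (`cnamcr.segmentation`,
`cnamcr.regions`, …) and as per-stage subcommands (`cna-mcr simulate |
normalize | segment | common | regions | mlpa | expression | clinstats`).

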