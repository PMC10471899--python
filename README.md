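# pathreg

Coherent gene-set enrichment analysis by penalized beta regression of
differential-expression *P*-values on gene-set membership.

## The problem

Differential-expression experiments yield one *P*-value per gene; enrichment
analysis asks which pathways (gene sets) are over-represented among the
dysregulated genes.  Classical single-term tests (Fisher's exact test, GSEA)
score each pathway in isolation, which breaks down as pathway databases grow
large and redundant: overlapping pathways produce correlated, noisy
enrichment calls.  `pathreg` instead estimates all pathway enrichments
*jointly*, letting pathway-pathway similarity structure the computation.

## The model

With *N* genes and *K* pathways, let **Y** = (p₁, …, p_N)ᵀ be the gene
*P*-values and **X** ∈ {0,1}^(N×K) the binary membership matrix
(x_ij = 1 iff gene *i* is in pathway *j*).  Each p_i is modeled as
beta-distributed with mean μ_i and shared precision φ (shape parameters
p = μφ, q = (1−μ)φ), and the mean is linked to membership through a logit
link, g(μ) = **Xβ**.  The coefficients and precision minimize

```
−log L(β, φ | Y, X)  +  λ‖β‖₁  +  ψ Σᵢ Σⱼ (βᵢ − βⱼ)² gᵢⱼ
```

where g_ij ∈ [0,1] is a pathway similarity (Jaccard or overlap coefficient
by default, or any user-supplied matrix).  The L1 term keeps the set of
enriched pathways sparse; the network-fusion term pulls similar pathways
toward a common enrichment score, so redundant pathways jointly drive the
signal instead of competing.  β_j is pathway *j*'s signed enrichment score
(negative = member genes have small *P*-values); pathways are ranked by
|β_j|.  λ and ψ are chosen by cross-validation on held-out log-likelihood.

The package also ships the synthetic benchmark that validates the method: a
clustered term-database generator, a similarity-biased sampler of activated
pathways (factor ρ), membership noise (fraction η), beta-distributed
*P*-value simulation, Fisher's exact test and random-null baselines, and
precision-recall evaluation.

## Worked example

`examples/01_fit_enrichment.py` simulates an experiment with five activated
pathways out of sixty and fits the model:

```
truly activated: ['T0009', 'T0011', 'T0012', 'T0027', 'T0042']
phi = 1.008, converged = True

 rank term_id   beta  abs_beta  term_size  frac_significant
    1   T0042 -1.091     1.091     33.000             0.455
    2   T0011 -0.960     0.960     42.000             0.500
    3   T0037 -0.633     0.633     21.000             0.476
    4   T0009 -0.616     0.616     44.000             0.500
    5   T0027 -0.509     0.509     27.000             0.407
```

Four of the five activated pathways top the ranking with negative
coefficients: membership in them pulls *P*-values toward 0 (their member
genes are ~46–50% individually significant at *P* < 0.05, against a ~14%
background rate).  `examples/02_cross_validation.py` shows held-out
likelihood selecting a positive λ on sparse truth, `03_benchmark.py` a small
method comparison, and `04_network_view.py` the similarity-network view of
the top terms.

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
pathreg fit --pvalues pvalues.tsv --gmt pathways.gmt --out-dir out/
pathreg simulate --n-terms 200 --n-active 20 --eta 0.25 --out-dir sim/
pathreg benchmark --n-replicates 10 --out-dir bench/
pathreg fisher --pvalues pvalues.tsv --gmt pathways.gmt --out-dir fet/
pathreg network --fit-tsv out/enrichment.tsv --gmt pathways.gmt --out-dir net/
```

Inputs are plain text: a two-column TSV (gene, pvalue) and a standard GMT
gene-set file.  Every run writes a `run_manifest.json` recording parameters
and seeds.

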