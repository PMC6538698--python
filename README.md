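# endbias

Quantify, model, and correct 5′/3′-end sequence biases in small-RNA
sequencing of equimolar reference pools.

Library-preparation chemistry — single-stranded adapter ligation and
template-switching reverse transcription — samples RNAs unevenly depending
on their terminal bases. Sequencing an equimolar pool of n known species
(e.g. a 962-member miRNA reference set) makes this bias measurable: with
unbiased sampling every species should receive CPM = 10⁶/n counts per
million, so the per-species measurement error is

    Δlog₁₀CPM_m = log₁₀(CPM_m + pc) − log₁₀(10⁶/n)

with a half-count pseudo-count pc. `endbias` models this error as a
function of each species' terminal bases only,

    Δlog₁₀CPM_m = f(x_{m,+1}, x_{m,+2}, x_{m,+3}, x_{m,−3}, x_{m,−2}, x_{m,−1}),

where x_{m,i} is the base at signed position i (one-hot encoded, 24
indicators) and f is a random-forest regressor. Corrected pseudo-counts
subtract the predicted error on the log scale:

    corrected_m = 10^(log₁₀CPM_m − Δ̂log₁₀CPM_m).

Around this core the package provides:

- **seqio** — FASTA reference pools; TSV count tables; counts from SAM/BAM
  alignments (uniquely mapped reads, 15–40 nt insert filter).
- **normcore** — CPM and median-of-ratios normalization, measurement
  errors, log₂ RMSE, ECDF.
- **endprofile** — abundance-adjusted base frequencies at positions +1..+6
  and −6..−1, 3′-end composition, k·SD over/under-representation labels,
  PCA of end features.
- **biascorrect** — the error model, 8-fold cross-validation, positional
  importance (5′ vs 3′ share), correction, and a trinucleotide-frequency
  reweighting alternative.
- **overhangdesign** — compensating 3′-overhang A:C:G:T primer ratios
  (preset `NTTR` = 6.6:0.4:1:1) and the ligase −3-position adapter-dimer
  screen.
- **simulate** — a seeded generator of equimolar pools and multinomial
  count tables under configurable terminal biases, so the whole pipeline
  is testable without external data.
- **evaluate** — saturation curves, abundance summaries, replicate
  correlations, and sequence-factor (length/GC/fold) outlier tests with a
  built-in base-pair-maximization folding proxy.

## Worked example

```python
import endbias as eb

pool = eb.simulate_pool(n=962, seed=1)                   # equimolar pool
spec = eb.BiasSpec.tgirt_like(seed=1, depth=1_000_000)   # terminal biases
table, truth = eb.simulate_counts(pool, spec, replicates=3)

ab = eb.cpm(table)
errors = eb.measurement_errors(ab, expected_cpm=1e6 / 962)
features = eb.encode_end_features(pool)
model = eb.fit_bias_model(features, errors)

corrected = eb.correct_counts(ab, model, pool, renormalize=True)
print("RMSE(log2) before:", round(eb.rmse_log2(ab, 1e6 / 962), 3))
print("RMSE(log2) after: ", round(eb.rmse_log2(corrected, 1e6 / 962), 3))
imp = eb.positional_importance(model)
print("5'/3' importance split:",
      round(100 * imp.five_prime_share), "/",
      round(100 * imp.three_prime_share))
```

Output:

```
RMSE(log2) before: 1.64
RMSE(log2) after:  0.098
5'/3' importance split: 44 / 56
```

The uncorrected table misstates species abundances by 1.64 log₂ units RMS
around the expected 1,039.5 CPM; subtracting the model's predicted errors
removes ~94% of that, and the importance split attributes slightly more of
the bias to the 3′ end (dominated by the terminal base, which the
template-switching step reads) than to the 5′ end (the ligase's substrate).

The same flow is available from the shell:

```sh
endbias simulate --n 962 --depth 1000000 --tgirt-like --seed 1 -o sim/
endbias correct --counts sim/counts.tsv --ref sim/pool.fa -o corrected.tsv
endbias design --counts sim/counts.tsv --ref sim/pool.fa
```

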