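# tfkey

Key transcription-factor (TF) discovery from transcriptome data, in two
steps:

1. **Build the inputs.** A genes × samples expression matrix is transformed
   into one *ranked gene list* per sample with a specificity index — ED
   (expression differential), PEM (preferential expression measure), SPM
   (specificity measure) or START (star-coordinate projection). In parallel,
   promoter sequences are scanned with position weight matrices (PWMs) to
   build *ranked gene sets*: each TF's candidate targets, scored by the
   **Jindex** — the maximum over promoter windows (both strands) of the
   width-averaged log-likelihood ratio of the PWM against the promoter's own
   base composition. Jindex ≥ 1.0 flags a candidate binding site.

2. **Test the association.** For every (TF set, sample) pair, the shared
   genes' two rank orders are compared with Kendall's tau-a,

       τ  = 2/(n(n−1)) · Σ_{i>j} sgn(i−j)·sgn(R_i−R_j),

   or its weighted form with per-gene weights v_i (options `-w 0/1/2/7/8`:
   unweighted, MIX-LINEAR, LINEAR, MIXED-DENSITY-CURVE, DENSITY-CURVE),

       τ_w = 2/((Σv)² − Σv²) · Σ_{i>j} v_i v_j sgn(i−j)·sgn(R_i−R_j).

   The linear schemes up-weight top-ranked genes; the density schemes weight
   genes by 1 − d/max d with d a Gaussian kernel density of the continuous
   scores, emphasizing both tails of the score distribution. P-values come
   from a normal approximation with an exact permutation-null variance (see
   `docs/methods.md`); q-values are Benjamini–Hochberg within each sample,
   and each pair receives the signed activity score sign(τ)·(−log10 p).

Why weighted and why these indexes: omics inputs are routinely
threshold-filtered (binding sites kept above a score cutoff, gene lists kept
to upregulated genes). When **both** sides are half-spectrum, negative
associations become nearly invisible to rank correlation — the
"unable to detect negative correlation" fallacy. A full-spectrum, signed
gene list (ED is the canonical choice) restores detectability, and the
weighting schemes trade sensitivity for focus on the informative top/tails.
The `simgen` module reproduces all four data regimes used to characterize
this behavior, and `tfkey sweep` generates the p-vs-covariance response
curves (U-shaped for full-spectrum data, J-shaped under double filtering).

## Worked example

All inputs are plain text. The bundled fixture generator writes a coherent
synthetic bundle — expression TSV, promoter FASTA, JASPAR PWMs, a ranked
gene-set TSV and a manifest — with a planted association between TF01's
target scores and sample S1's ED scores (ρ = 0.8):

```sh
tfkey fixture --seed 42 --n-genes 200 --planted "0,0,0.8" --out demo/inputs
tfkey pipeline --matrix demo/inputs/expression.tsv \
               --sets demo/inputs/gene_sets.tsv \
               --method ed -w 7 --out demo/run
```

```
INFO tfkey: 2/15 pairs significant at FDR < 0.05
```

`demo/run/results.tsv` (first rows):

```
set_id  sample_id  n_overlap  tau           z            p               q               direction  signed_score
TF01    S1         120        0.7632570039  9.779930033  1.373054293e-22 4.119162878e-22 1          21.86231229
TF02    S1         120        0.05526164974 0.508892981  0.6108272402    0.7051512263    1          0.2140816036
TF03    S1         120        0.04195961348 0.3783760918 0.7051512263    0.7051512263    1          0.1517177345
```

The planted pair (TF01, S1) is recovered with τ_w = 0.76 and q ≈ 4·10⁻²²;
its signed score 21.86 dominates the TF × sample score matrix
(`score_matrix.tsv`), while unplanted pairs stay near 0. Scanning the
bundle's promoters with its PWMs recovers the implanted consensus sites:

```sh
tfkey scan --pwms demo/inputs/pwms.jaspar \
           --fasta demo/inputs/promoters.fasta --threshold 1.0 --out demo/scan
```

```
INFO tfkey: 193 sites (Jindex >= 1) across 3 TF set(s)
```

with `demo/scan/sites.tsv` listing, per (TF, gene), the best site's 1-based
offset, strand, Jindex and the legacy RS score, and
`demo/scan/gene_sets.tsv` ready to feed back into `tfkey pipeline`.

Other entry points: `tfkey index` (gene lists only), `tfkey test` (one gene
list against a set collection), `tfkey simulate` / `tfkey sweep` (the four
simulation regimes and their response curves). Every subcommand accepts
defaults from a YAML file via `tfkey --config file.yaml ...`.

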