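# maldimtu

Dereplication of microbial isolate libraries from MALDI-TOF mass spectra.

The package turns raw linear-mode profile spectra (1,880–20,000 Da) into
**MALDI-TOF taxonomic units (MTUs)** and downstream diversity/classification
summaries:

1. **preprocess** — Savitzky-Golay smoothing, TopHat (morphological opening)
   baseline removal, TIC normalization, MAD noise estimation, window-maximum
   peak detection, replicate averaging.
2. **align** — consensus-reference linear mass warping and strict
   largest-gap peak binning into a spectra × bins feature matrix.
3. **optimize** — two seeded random-search loops over the seven
   preprocessing/alignment parameters: loop 1 maximizes the mean pairwise
   Jaccard coefficient between per-target average reference-standard (BTS)
   peak sets; between the loops, spectra failing the quality rule (median
   SNR of the 10 largest peaks ≥ 15 and ≥ 13 peaks) are pruned; loop 2
   minimizes the overlap of similarity values between ≥ 99 %-identity
   isolate pairs and all other pairs.
4. **similarity** — Jaccard and cosine matrices and the Jaccard-weighted
   cosine: observed cosines are multiplied by the clamped hyperbolic
   prediction `y(x) = y0 + x / (x + 0.2)` with `y0` the mean cosine of
   near-disjoint pairs.
5. **cluster** — average-linkage clustering of `1 − W` cut at a similarity
   threshold (default 0.65, optionally derived from a 4-parameter logistic
   fit of 16S percent identity vs weighted cosine as `midpoint − 0.01`),
   with column-resampling bootstrap support (BP, optional multiscale AU)
   and newick export.
6. **diversity** — exact hypergeometric rarefaction, Chao1-based
   extrapolation and Good-Turing sample coverage with seeded bootstrap CIs.
7. **classify** — nearest-centroid (or decision-tree) MTU classifier with
   resubstitution / leave-one-out confusion matrices, accuracy and Cohen's
   kappa.
8. **synth** — synthetic libraries with known ground truth (species peak
   templates, strain variation, per-target mass drift, baseline + noise,
   BTS replicates, matching 16S-style identity matrix) so the whole
   pipeline runs without instrument data.

## CLI

Simulate a complete input set and run the full pipeline:

```sh
maldimtu simulate --out data/ --species 20 --strains 3 --seed 1

cat > config.yaml <<EOF
spectra_dir: data
metadata: data/metadata.csv
identity_matrix: data/identity.csv
output_dir: run
loop1_iters: 25
loop2_iters: 50
seed: 1
EOF

maldimtu run-all --config config.yaml
```

`run/` then contains the optimization traces, QC report, feature matrix,
similarity matrices, MTU table, dendrogram (newick with support values),
diversity curve, classifier report and a `manifest.json` recording seeds,
package version and config hash — a rerun with the same config is
bit-identical. Individual stages (`preprocess`, `optimize`, `qc`,
`similarity`, `cluster`, `diversity`, `classify`) are also exposed as
subcommands operating on the documented CSV artifacts.

Input spectra are two-column CSV/TSV (m/z, intensity) or mzML, one spectrum
per file, linked by a metadata table
(`file,spectrum_id,isolate_id,group,target_id`). 16S identities come in as
a square percent-identity CSV.

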