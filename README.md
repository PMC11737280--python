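# maldicci

Open-source MALDI-TOF MS fingerprint matching for mosquito species
identification using a cross-correlation index (CCI).

The package implements the full analysis chain:

- **spectra_io** — mzXML and plain-text spectrum I/O, metadata and result
  tables (TSV; `-Inf` encodes log10(CCI) = −∞).
- **preprocess** — resampling to a uniform 1 Da mass grid, sqrt intensity
  transform, Savitzky–Golay smoothing, SNIP baseline removal, TIC
  normalization, optional rigid spectrum alignment.
- **cci** — the cross-correlation index: per 500 Da mass interval
  (3000–12,000 Da by default), the strict local maximum of the normalized
  cross-correlation function over a symmetric lag window; the CCI is the
  product of the per-interval maxima (0 if any interval lacks a local
  maximum), reported as log10(CCI) ∈ [−∞, 0].
- **refdb** — labelled reference databases: build, exhaustive
  all-pairs/cross-panel CCI tables, repeatability/reproducibility/specificity
  summaries, specimen-level median matrices, bank-to-bank best-match
  concordance, QC filtering, merging, persistence.
- **identify** — highest-CCI specimen identification with an identification
  threshold (default log10(CCI) ≥ −14) and TP/TN/FP/FN classification.
- **evaluate** — seeded simulation experiment (random spot subsets per
  specimen, default 1000 repeats) estimating sensitivity, specificity, PPV,
  NPV and accuracy with medians and equal-tailed 95% credible intervals,
  including the unreferenced-query specificity mode (same-species matches
  disabled) and ROC threshold sweeps.
- **synthetic** — a deterministic generator of labelled synthetic panels
  (species peak templates, specimen-level jitter, spot-level drift/noise/
  baseline) so the entire pipeline is testable offline.

## CLI

```bash
# generate a synthetic reference/test panel
maldicci simulate-panel --seed 1 --out runs/panel

# build a reference database from raw spectra + metadata
maldicci build-db --spectra-dir runs/panel/reference \
    --metadata runs/panel/reference_metadata.tsv --out runs/db

# all-pairs CCI table, summaries and bank-to-bank concordance
maldicci compare --db runs/db --bank-to-bank --out runs/cmp

# identify specimens (one mzXML file per specimen)
maldicci identify --db runs/db --threshold -14 --out runs/id \
    runs/panel/test/*.mzXML

# simulation experiment over thresholds and spot counts
maldicci evaluate --db runs/db --test-dir runs/panel/test \
    --test-metadata runs/panel/test_metadata.tsv \
    --thresholds -14,-13,-12 --spots 1,2,4 --repeats 1000 --seed 1 \
    --out runs/eval
```

Every subcommand writes a `config.yaml` snapshot of the effective
configuration into its output directory. Preprocessing and CCI parameters can
be overridden with `--config config.yaml` (sections `preprocess`, `cci`,
`generator`).

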