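# Reference result tables

Per-chip result tables and validation summaries transcribed from the published
chip-dPCR miRNA validation experiments that this package models (a serial
dilution of the cel-miR-39 spike-in mimic, and duplex miRNA assays on plasma,
lung-cancer cell-line, and PDX tissue specimens; each target assay is paired
with cel-miR-39 on the VIC channel, e.g. "16-39" = miR-16-5p/FAM duplexed with
cel-miR-39/VIC).

Transcription notes:

- Decimal commas in the source were converted to decimal points, and thousands
  separators in partition counts were removed.
- Sample labels were normalized for whitespace, one `1.10` typo was corrected
  to `1:10`, and en dashes in assay names became ASCII hyphens. Labels such as
  `(1:5)` and `1:10` encode pre-analytic and on-chip dilution steps; the
  reader multiplies them into a single dilution factor.
- One line of the plasma table is typeset ambiguously in the source (the
  undiluted values run into the 1:10 values). It was resolved as spike 567.6
  (553.93–581.54), target 8.56 (7.2–10.2) — the only split in which each
  confidence interval brackets its point estimate and the ten-fold dilution of
  the undiluted value (40.32) is respected.
- `detection_efficiency.csv` carries the source's printed integer efficiency
  percentages alongside the expected/observed pairs; two rows (D1, D3) round
  differently from `100 × expected / observed` by one point and are treated as
  source rounding noise.
- `replicate_cv.csv` holds per-sample coefficients of variation for miR-16-5p
  measured in duplicate within one PCR run (intra) and across two runs (inter).

These files use the same results-CSV schema that `chipdpcr.io` writes, minus
the optional `qc_pass`, `dilution_factor`, and `chip_id` columns (recomputed
or parsed from the sample label on load).
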