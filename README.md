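# bloodpmf

Peptide-mass-fingerprint identification of blood, blood provenance and semen
from MALDI-MS centroided peak lists.

The package implements the full desk-side pipeline:

- **`peptide_mass`** — monoisotopic mass calculus: peptide neutral mass with
  variable methionine oxidation, m/z at arbitrary charge, signed ppm error,
  a/b/c/y fragment series, nominal (integer) m/z labels.
- **`insilico_digest`** — tryptic digestion (Keil rule: cleavage C-terminal
  to K/R, suppressed before proline) with missed cleavages and oxidation
  variants; cross-species specificity annotation (proteotypic vs shared
  peptides); FASTA input and TSV theoretical tables.
- **`spectrum_io`** — plain-text peak-list I/O (mMass-style `.txt` exports)
  and the preprocessing filters: S/N ≥ 10 threshold, exclusion-list removal
  (matrix clusters, trypsin autolysis), 600–2000 Th window. Filters are
  idempotent, commute, and log themselves into the list's history.
- **`marker_matching`** — the diagnostic marker panel (sequence-backed,
  literal-m/z and nominal-support markers) and two-stage matching:
  candidate at ≤ 30 ppm, confirmed at ≤ 15 ppm; plus binary-search
  annotation of whole peak lists against theoretical tables.
- **`classifier`** — the refined decision tree mapping confirmed markers to
  claims over identification levels I–V (blood? human/animal? species?
  semen?), and the earlier haemoglobin-only strategy for comparison.
- **`synthetic_data`** — synthetic peak-list simulation (ppm jitter,
  background peaks, S/N sampling, marker dropout, trace samples) and the
  packaged blind-cohort fixtures (`table1`, `table5`, `table6`).
- **`evaluation`** — claim scoring against ground truth (full/partial/
  incorrect) and cohort statistics (correct-identification rate, blood
  false-negative/false-positive rates).

## CLI

```sh
bloodpmf digest --fasta proteins.fasta --missed 2 --mz-min 600 --mz-max 2000 --out table.tsv
bloodpmf simulate --fixture table6 --seed 7 --jitter-ppm 3 --outdir peaks/
bloodpmf preprocess --in peaks/128_F.txt --snr 10 --range 600 2000 --out clean.txt
bloodpmf match --peaks clean.txt --candidate-ppm 30 --confirm-ppm 15
bloodpmf classify --peaks clean.txt --strategy refined --report claim.json
bloodpmf evaluate --fixture table6 --seed 1 --out summary.tsv
```

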