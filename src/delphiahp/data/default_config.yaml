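# Default pipeline configuration. Every block is optional; omitted blocks
# keep these values. Paths left null fall back to the bundled reference data.
paths:
  hierarchy: null
  round1_scores: null
  round2_scores: null
  means: null
  output_dir: delphiahp_out

screening:
  retain_mean: 4.0       # retain when mean >= retain_mean and cv < retain_cv
  retain_cv: 0.25
  delete_mean: 3.5       # delete when mean < delete_mean
  delete_cv: 0.30        # delete when cv > delete_cv
  max_not_necessary: 0.30  # delete when not-necessary vote share exceeds this

# |mean difference| -> 1..9 comparison scale (inclusive upper bounds;
# null = unbounded last bin)
saaty_mapping:
  - {upper: 0.0, scale: 1}
  - {upper: 0.15, scale: 2}
  - {upper: 0.35, scale: 3}
  - {upper: 0.50, scale: 4}
  - {upper: 0.75, scale: 5}
  - {upper: 0.85, scale: 6}
  - {upper: null, scale: 7}

random_index:
  1: 0.0
  2: 0.0
  3: 0.52
  4: 0.89
  5: 1.12
  6: 1.26
  7: 1.36
  8: 1.41
  9: 1.46

authority:
  ca_tables:
    theory: {large: 0.3, medium: 0.2, small: 0.1}
    practice: {large: 0.5, medium: 0.4, small: 0.3}
    reference: {large: 0.1, medium: 0.1, small: 0.1}
    intuition: {large: 0.1, medium: 0.1, small: 0.1}
  familiarity_levels:
    very unfamiliar: 0.2
    unfamiliar: 0.4
    moderate: 0.6
    familiar: 0.8
    very familiar: 1.0

report:
  stats_decimals: 2
  weight_decimals: 4

seed: 0
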