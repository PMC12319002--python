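# delphiahp

Delphi expert-consensus statistics and analytic-hierarchy-process (AHP)
weighting for three-level indicator systems, packaged around a digital health
competency assessment framework (3 primary, 9 secondary, 19 tertiary
indicators) that ships with the library as a fully reproducible reference
dataset.

The pipeline turns multi-round expert score panels (integer 1–5 Likert
ratings, optional "not necessary" votes, judgment-basis grades and
familiarity ratings) into:

* **Delphi round statistics** — per-indicator mean / population SD /
  coefficient of variation, effective questionnaire recovery rate, expert
  authority coefficients `Cr = (Ca + Cs)/2`, and the tie-corrected Kendall
  coefficient of concordance `W` with its chi-square test;
* **indicator screening** — configurable retain / review / delete rules
  (retain when mean ≥ 4 and CV < 0.25; delete when the not-necessary vote
  share exceeds 30%, mean < 3.5 or CV > 0.3);
* **hierarchy revisions** — add / delete / rename actions per round with a
  full audit log;
* **AHP weights** — one positive reciprocal judgment matrix per parent node,
  built by mapping absolute sibling mean-score differences onto the 1–9
  comparison scale through a calibrated binned lookup; weights from the
  principal eigenvector (power iteration), consistency ratios `CR = CI/RI`
  gated at 0.1, and combination (global) weights with leaf ranks;
* **synthetic panels** — a seeded generative model
  (`clamp(round(mu + noise), 1, 5)`) with tunable consensus and a two-round
  convergence mechanism, so every stage is testable without external data.

Two λmax conventions are exposed for the consistency test: the exact
principal eigenvalue and the normalized-column-mean approximation. The
column-mean estimator is the reporting default because it is the convention
of the reference implementation whose four-decimal consistency ratios this
package reproduces; see `delphiahp.ahp` for details.

## CLI

```sh
# full pipeline on the bundled reference data -> weights.tsv/.json + audit.jsonl
delphiahp run --out out/

# weights and consistency ratios only
delphiahp ahp-weights --format json

# simulate a two-round 15-expert study and analyse it
delphiahp simulate --seed 7 --sigma 0.3 --out panels/
delphiahp delphi-stats --scores panels/round1_scores.csv \
    --authority panels/round1_authority.csv
delphiahp screen --scores panels/round1_scores.csv

# fit a difference->scale mapping to observed (means, weights) pairs
delphiahp calibrate-mapping --observations obs.json
```

Exit codes: 0 ok, 2 validation error, 3 consistency-gate failure. All
thresholds, the difference→scale mapping, the random-index table and the
authority grade tables are overridable through a YAML config
(`--config`; see `src/delphiahp/data/default_config.yaml` for the schema
and defaults).

## Layout

```
src/delphiahp/
  hierarchy.py   indicator tree, validation, revision log
  delphi.py      round statistics, authority, Kendall's W, screening
  ahp.py         judgment matrices, eigenvector weights, consistency, calibration
  simulate.py    seeded synthetic panel generator
  config.py      YAML pipeline configuration
  reporting.py   report tables, audit log, pipeline orchestration
  cli.py         click command group
  data/          reference framework, means, score multisets, default config
tests/           unit + property tests and tests/test_acceptance.py
scripts/acceptance.py
```
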