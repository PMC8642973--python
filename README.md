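# fusemble

Ensemble consensus calling, knowledge-based filtering and prioritization of
RNA-Seq gene fusion predictions.

Fusion callers disagree wildly: sensitive tools report thousands of
candidates per sample, precise tools miss real events. `fusemble` starts
downstream of the callers. It parses the native tab-delimited outputs of up
to seven callers (Arriba, CICERO, FusionCatcher, FusionMap, JAFFA,
MapSplice, STAR-Fusion), harmonizes gene symbols to approved HGNC names via
alias matching (with cytogenetic-band disambiguation), overlaps predictions
on **unordered gene pairs** (so differing breakpoints and reciprocal
orientations still match), reconciles discordant breakpoints by read
support, and prioritizes by caller consensus and evidence.

Consensus records then pass through three knowledge-based filters:

* **read-through removal** — same chromosome, same strand, breakpoints
  fewer than 200,000 bases apart;
* **cohort-frequency removal** — gene pairs called in more than 10% of an
  internal cohort (a persistent per-pair frequency store);
* **minimum-evidence removal** — no caller supplies at least 4 reads;

with a **known-fusion-list rescue** that retains listed pairs supported by
at least 2 callers even when a filter fires, a supplementary **singleton
channel** for listed pairs seen by a single caller, and a gene-partner
pathogenicity frequency score (1–10) for recurrent known partners.

The package also ships a benchmark module (sensitivity/precision against a
truth set, consensus-threshold ablation sweeps) and a deterministic
synthetic fixture generator that emits per-caller files in each native
dialect with planted true fusions, read-through artifacts, recurrent cohort
artifacts, low-evidence fusions and per-caller false positives — the test
bed for everything else.

## CLI

```sh
# generate a synthetic fixture with 14 planted known-list fusions
fusemble simulate --seed 7 --out-dir fixture/

# run the full pipeline on a set of caller outputs
fusemble run \
    --caller-file arriba=fixture/arriba.tsv \
    --caller-file jaffa=fixture/jaffa.tsv \
    --caller-file starfusion=fixture/starfusion.tsv \
    --known-list fixture/known_fusions.tsv \
    --freq-db fixture/freqdb.json \
    --out-dir out/
```

`run` writes four TSVs to `--out-dir`: `filtered.tsv` (prioritized kept
records with all annotations), `unfiltered.tsv` (every consensus record),
`singletons.tsv` (known-list single-caller channel) and `audit.tsv` (the
per-record filter decisions and reasons). Runs are incremental: parsed
caller outputs are cached under `out/unified/`, and re-running with just a
newly finished caller's file updates the consensus as if all files had been
given at once. Thresholds are flags: `--min-callers` (3),
`--known-list-min-callers` (2), `--min-reads` (4),
`--readthrough-distance` (200000), `--max-frequency` (0.10).

Other subcommands:

```sh
# add a sample's >=2-caller consensus to the cohort frequency store
fusemble register-sample --freq-db db.json --sample-id s1 --from-run out/

# score caller outputs against a truth set across consensus thresholds
fusemble benchmark --truth fixture/truth.tsv \
    --caller-file arriba=fixture/arriba.tsv \
    --caller-file jaffa=fixture/jaffa.tsv \
    --thresholds 2,3 --out sweep.tsv
```

## Layout

```
src/fusemble/
  models.py         unified call / consensus record dataclasses
  caller_io.py      declarative per-caller dialects (data/dialects.yaml)
  harmonize.py      HGNC alias matching with cytoband disambiguation
  ensemble.py       unordered-pair overlap, breakpoint reconciliation
  filters.py        read-through / frequency / evidence filters + rescue
  freqdb.py         cohort detection-frequency store (JSON-backed)
  knowledgebase.py  known-fusion list, scoring, singleton channel
  benchmark.py      sensitivity/precision scoring and ablation sweeps
  synth.py          deterministic synthetic fixture generator
  pipeline.py       end-to-end orchestration and report writing
  cli.py            click entry points
  data/             dialect config, alias table, seed known list,
                    mock gene annotation, gene type descriptors
```
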