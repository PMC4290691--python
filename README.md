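# qualmc

Symbolic CTL model checking for multi-valued logical signaling networks,
with synchronous and fairness-constrained asynchronous update semantics,
an explicit-state oracle, and a bundled 30-node ER-Golgi stress-response
case study with its published verification-verdict table.

## What it does

- **Models** (`qualmc.logic_model`): networks of discrete-level nodes
  (inputs / internals / Boolean fate outputs) with signed edges. A node's
  next level is `clamp(basal + sum(activators) - sum(inhibitors))`;
  `joint_min` nodes require all of their activators. Models are plain
  YAML files (see `src/qualmc/data/er_golgi.model.yaml` for the schema).
- **Dynamics** (`qualmc.dynamics`): Kripke structures under synchronous
  (simultaneous, deterministic) or asynchronous (one process per step,
  nondeterministic) updates. Inputs are chosen at time 0 and frozen.
  Asynchronous systems carry one fairness constraint per update process.
- **Checking** (`qualmc.ctl`): full CTL (`EX/AX/EF/AF/EG/AG/EU/AU`,
  Boolean connectives, level-comparison atoms) decided by BDD fixpoint
  computation — preimages via functional substitution, fair `EG` via the
  Emerson-Lei iteration — plus witness/counterexample lassos that replay
  against the successor functions. A self-contained ROBDD manager lives
  in `qualmc.bdd`.
- **Oracle** (`qualmc.explicit`): brute-force explicit-state CTL with
  fairness (fair SCC construction) for small systems, plus seeded random
  network/formula generators. The symbolic engine is cross-validated
  against it on thousands of instances.
- **Case study** (`qualmc.casestudy`): the reconstructed ER-Golgi
  network (UPR sensor arms, NFkB negative-feedback oscillator, three
  cell-fate outputs) and 32 CTL properties with expected verdicts under
  both semantics; `reproduce()` re-checks the whole table.

## CLI

```sh
# verdict table of the bundled case study (sync + fair async)
qualmc casestudy --report table.tsv

# check your own model / properties
qualmc check --model m.yaml --props p.yaml --semantics async --fair \
    --report out.tsv --trace-dir traces/

# brute-force oracle (small models only) and DOT export
qualmc oracle --model m.yaml --props p.yaml --semantics sync
qualmc render --model m.yaml --out m.dot
```

Property files are YAML lists of
`{id, formula, scenario: {fix: {input: level}}, expect_sync, expect_async}`;
report TSVs have columns
`id, semantics, fair, expected, observed, match, runtime_s`.

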