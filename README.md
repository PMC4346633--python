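# cyclekin

Division-tree kinship statistics and branching-process simulation for
Fucci time-lapse tracking of clonally expanding CD8⁺ T cells.

The package covers the full single-cell cell-cycle-tracking analysis chain:

- **`cyclekin.lineage`** — division trees built from per-cell track records
  (CSV), per-well QC exclusion rules, kinship labelling (C1 → M1/M2 →
  D1–D4), sibling / cousin / mother–daughter / non-relative pair
  extraction, and division-speed classification (fast < 600 min,
  medium 600–800, slow > 1000, no division > 30 h, with the unlabelled
  800–1000 min band reported explicitly as INTERMEDIATE).
- **`cyclekin.fucci`** — mKO2/mAG trace classification into Fucci states
  (KO_HIGH, KO_POS, DOUBLE_POS, AG_POS, DN) with minimum-dwell smoothing,
  and per-cycle phase durations.
- **`cyclekin.simulate`** — a branching-process generator: lognormal cycle
  times with family, per-tree generational-drift, division-shared and
  individual variance components; a heritable slow/no-division state
  switching on at generation ≥ 8; piecewise-linear reporter traces with a
  ground-truth log; population snapshots, CTV dye dilution with a
  9-division detection floor, BrdU pulse labelling, and single-cell
  expansion counts.
- **`cyclekin.stats`** — cycle-time summaries, Spearman correlation (exact
  enumeration p for n ≤ 8), a seeded permutation null, division-speed
  category fractions, the mother→daughter inheritance contingency table
  with a χ² test, and two-colour synchrony metrics.
- **`cyclekin.io` / `cyclekin.cli`** — CSV/TOML/JSON formats, run
  manifests, and the `cyclekin` command.

## Command line

```sh
cyclekin simulate --seed 7 --out runs/sim           # tracks + traces + truth
cyclekin phases   --traces runs/sim/traces.csv --out runs/ph
cyclekin analyze  --tracks runs/sim/tracks.csv --out runs/an --n-perm 1000
cyclekin report   --results runs/an/results.json
```

Every run writes a `manifest.json` (config hash, seed, inputs, outputs,
version) sufficient to reproduce it. A fully commented default simulation
configuration ships at `src/cyclekin/data/default.toml`; pass a modified
copy with `--config`.

## Data formats

Track CSV: `tree_id, well_id, cell_id, parent_id, birth_time_min,
end_time_min, fate{DIVIDED|DIED|CENSORED}, generation_offset,
size_class, cd62l_class` — one row per tracked cell, times in minutes from
imaging start. Trace CSV (long): `cell_id, time_min, ko2_au, ag_au`.
Segmentation CSV: `cell_id, start_min, end_min, state`.
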