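# edqc

Automatic classification of crystallographic ligands and their binding
sites as **Good / Dubious / Bad**, based on how well each residue fits the
electron density (RSR, RSCC, average occupancy, and optional OWAB / R-free /
resolution criteria), with configurable threshold profiles, exclusion-list
ligand filtering, distance-based binding-site detection, and CSV reporting.

## How it works

1. **Ligand extraction** — hetero residues that are not waters and not on
   the *blacklist* (solvents, buffers, additives) or *non-propagating* list
   (mainly metal ions) are candidate ligand components. Components closer
   than the covalent-bond cutoff (strictly below 2.1 Å by default) are
   merged into one multi-component ligand. A ligand covalently close to a
   polymer residue or to a blacklisted residue is rejected; metal contacts
   neither reject nor merge.
2. **Binding-site detection** — every polymer residue and every non-water,
   non-blacklisted hetero residue (metals included) with any atom within
   the site cutoff (4.5 Å by default, boundary inclusive) of any ligand
   atom belongs to the site.
3. **Classification** — each component starts at score 0 and gains one
   point per enabled, unmet condition (RSCC ≥ 0.9, average occupancy ≥ 1.0,
   RSR ≤ good-RSR cutoff, plus optional OWAB/R-free/resolution caps).
   Score 0 → Good; score > tolerance (default 1) → Bad; otherwise Dubious.
   An RSR above the hard cap (0.4) forces the component Bad. Ligands and
   sites take the worst label of their components.

Two default profiles ship, differing only in the good-RSR cutoff, which
absorbs the difference between the two statistics dialects:
`Default (PDB)` (good RSR ≤ 0.24) and `Default (PDB_REDO)` (good RSR ≤ 0.165).

Per-residue statistics are read from a local TSV dialect (see
`edqc/stats.py`); structures are plain PDB-format files. A density module
(`edqc/density.py`) can compute RSR/RSCC from a density grid directly
(single-Gaussian-per-atom model density), so the whole engine is testable
offline; it makes no attempt at numeric parity with databank pipelines.

## CLI

```sh
# generate a synthetic, ready-to-classify data directory with known labels
edqc fixtures --out-dir data/ --n 5 --seed 1 --profile "Default (PDB_REDO)"

# classify: writes results.csv, results_components.csv, rejections.tsv
edqc classify --data-dir data/ --id-file ids.txt \
    --profile "Default (PDB_REDO)" --out-dir out/

# list or export the shipped threshold profiles
edqc profiles --export profiles/
```

`edqc classify` accepts `--ids` (repeatable) or `--id-file`, replacement
exclusion lists (`--blacklist`, `--non-propagating`), threshold tweaks
(`--site-cutoff`, `--bond-cutoff`, `--tolerance`), and a label-override
file (`--overrides`, `subject<TAB>label` lines) for non-interactive
re-classification. Profiles are flat `key=value` files; `off` disables an
optional threshold.

The main results CSV has one row per ligand/site pair
(`model_id, source, ligand_id, ligand_label, ligand_worst_score,
site_label, site_worst_score, n_site_residues, failed/missing summaries`);
a companion `*_components.csv` has one row per scored residue. The
rejection report is a TSV of `subject, reason` with reasons
`no_stats_data`, `covalent_to_polymer`, `blacklisted`,
`covalent_to_blacklisted`.

## Layout

```
src/edqc/
  model_io.py           PDB read/write, alt-loc resolution, occupancy
  ligand_extraction.py  exclusion lists, covalent grouping, rejections
  binding_site.py       cell-list neighbor search, site detection
  stats.py              per-residue stats TSV dialect, local data provider
  classify.py           profiles, scoring, Good/Dubious/Bad labels
  density.py            density grids, model density, RSR/RSCC
  ccp4.py               optional CCP4/MRC map adapter (mode 2, orthogonal)
  fixtures.py           deterministic synthetic complexes with known labels
  report.py             run driver, CSV/TSV writers, profile files
  cli.py                click command-line interface
  data/                 editable default exclusion lists
```
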