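# difftree

Differentiation-tree analysis of mosaic embryonic cell lineages.

A mosaic embryo develops by binary cell divisions, so its development is a
rooted, planar, ordered binary tree. `difftree` takes per-cell lineage
tables (name, parent, volume, timing, position) and provides:

- **Tree model & I/O** (`difftree.lineage`): validated binary lineage
  trees from CSV/TSV tables (explicit parent column or Sulston-style
  nomenclature fallback), annotated Newick import/export, cell lifetimes,
  volume-conservation diagnostics.
- **Orderings & binary codes** (`difftree.codes`): reorder every division
  so the smaller daughter branches left (a *differentiation* ordering,
  with tie/unknown flagging and per-division overrides for a *composite*
  ordering); address each cell with its 0/1 root-path code; per-cell
  Hamming distances between orderings; isometric-graph coordinates
  (`x = n`, `y = N_m - 1 - n` per depth line); random re-ordering nulls;
  spatial joins of Hamming distances with nucleus positions.
- **Asymmetry statistics** (`difftree.asymmetry`): the relative volume
  difference `A = |C_i - C_j| / (C_i + C_j)` of a daughter pair, threshold
  classification (`A > h`), threshold count tables, smaller/larger size
  ratios by depth (`A = (1 - r)/(1 + r)` exactly), power-law and linear
  scaling fits with residual-based outlier flagging.
- **CAST codes** (`difftree.cast`): depth-prefixed C/E tokens
  (`3.CEC` for bits 010), token-file parsing, and Needleman–Wunsch global
  alignment over whole tokens (match +1, gap −1, substitutions disallowed
  by default) with score reports.
- **Synthetic embryos** (`difftree.simulate`): seeded complete binary
  trees with mother-volume partitioning, a tunable asymmetric-split
  regime, and power-law lifetimes — every analysis stage is testable
  without external data.

## CLI

```sh
difftree simulate --seed 42 --max-depth 7 -o embryo.csv
difftree codes embryo.csv -o codes.csv          # lineage + differentiation codes, Hamming
difftree asymmetry embryo.csv --thresholds 0.05,0.1,0.25,0.5 -o thresholds.csv
difftree ratios embryo.csv -o ratios.csv        # min/mean/max size ratio per depth
difftree isometric embryo.csv -o iso.csv
difftree fit embryo.csv --model power --pair volume-lifetime
difftree cast-encode embryo.csv -o embryo.cast
difftree cast-align a.cast b.cast [--max-depth 3] [--file-order]
```

Every file-writing run drops a `*.manifest.json` (config, input
checksums, package version) and refuses to overwrite without `--force`.

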