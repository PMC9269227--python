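# ivscreen

Inverse virtual screening (IVS) — *target fishing* — turns conventional
docking around: instead of screening many ligands against one protein, a
few query ligands are docked against a large panel of protein structures
to rank candidate **targets**. `ivscreen` implements the full
decoy-normalized IVS workflow as a Python library, built around the screen
of three *Cannabis sativa* leaf cannabinoids —
2α-hydroxy-Δ³,⁷-cannabitriol (`cbt1`), cannabidiol (`cbd`) and
cannabidiolic acid (`cbda`) — against an acute-inflammatory-response
panel.

It is written for computational chemists and natural-product researchers
who want a testable, engine-agnostic IVS pipeline: every stage runs at
desk scale from recorded or synthetic inputs, and a live
AutoDock-Vina-compatible backend slots in for real docking.

## The statistic

Raw docking scores favour large hydrophobic pockets that bind anything.
Each query best-pose affinity *V₀* (kcal/mol) on a structure is therefore
normalized by *V_R*, the arithmetic mean of the best affinities of ten
property-matched but structurally dissimilar decoys on the same
structure:

```
V = V₀ / V_R
```

*V* is dimensionless; *V* > 1 means the query outperforms its decoys.
Hits are retained only when both filters hold strictly:

```
V₀ < −7.5 kcal/mol   and   V > 0.75
```

and are summarized two ways: the top-scoring target per compound (by
affinity or by *V*) and the **consensus targets** — UniProt accessions
with a retained structure for *every* query compound, ranked by retrieval
count.

## What's in the box

| module | role |
|---|---|
| `ivscreen.compounds` | query/decoy registry, nominal-mass ESI-MS identity checks, ten-decoy selection (MW ± 25 Da, HBD/HBA ± 1, Tanimoto < 0.4) |
| `ivscreen.panel` | PDB cleaning (waters/ions/buffer, altlocs, models), ligand-derived sites, docking boxes (site extent + 2 × 10 Å, 1.0 Å spacing) |
| `ivscreen.pockets` | deterministic grid buriedness scan for apo structures (top 5 pockets) |
| `ivscreen.docking` | engine contract: Vina subprocess adapter (exhaustiveness 64, seeded) + bit-reproducible replay backend for recorded affinity tables |
| `ivscreen.screen` | V-normalization, strict retention filters, top scores, UniProt consensus, full provenance-stamped reports |
| `ivscreen.interactions` | geometric pose audit: H-bonds (≤ 3.5 Å, ≥ 120°), π-π stacks (≤ 5.5 Å, parallel/T-shaped), salt bridges (≤ 4.0 Å), known-site residue scoring |
| `ivscreen.synth` | synthetic panels with planted true targets, toy cavity receptors, decoy candidate libraries |
| `ivscreen.refscreen` | the recorded cannabinoid screen (affinities + PDB→UniProt mapping) for replay |

## Worked example

```sh
python examples/03_replay_screen.py
```

```
Top target per compound (by affinity, kcal/mol):
  cbd   -> Tumor necrosis factor (7KPA)  -9.7
  cbda  -> Tumor necrosis factor (7KPA)  -10.1
  cbt1  -> Tumor necrosis factor (6X83)  -9.2

Shared consensus targets (retained by all three compounds):
  P01375  Tumor necrosis factor  [3 hits]
      cbd: -9.7 (7KPA), cbda: -10.1 (7KPA), cbt1: -9.2 (6X83)
  P37231  Peroxisome proliferator-activated receptor gamma  [3 hits]
      cbd: -9.2 (4PRG), cbda: -9.4 (4PRG), cbt1: -8.6 (2ZK6)
  P00734  Prothrombin/Thrombin  [3 hits]
      cbd: -8.6 (6ZV8), cbda: -8.5 (1RD3), cbt1: -8.4 (6ZUX)
```

All three cannabinoids score best on TNFα (affinities −9.2 to −10.1
kcal/mol, well below the −7.5 retention bound), and thrombin (P00734) and
PPARγ (P37231) are retained for every query — the screen's shared
putative anti-inflammatory targets. The other `examples/*.py` scripts
walk through compound properties, decoy selection, pocket detection, pose
contacts and the synthetic planted-target benchmark, each printing what
it computes and what the numbers mean. A thin `ivscreen` CLI mirrors the
same capabilities (`ivscreen --help`).

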