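# zipprofiler

Sequence-level characterization of **bZIP transcription-factor families**
and their relationship to downstream target genes, aimed at plant
gene-family surveys (the shipped analysis emulates an olive-scale family
of ~100 members and a panel of lipid-synthesis genes).

bZIP proteins carry a basic DNA-binding region followed by a leucine
zipper that mediates dimerization. `zipprofiler` implements the
sequence grammar and coiled-coil bookkeeping such surveys use:

* **Domain scan** — the basic region is the 18-residue word
  `N-X7-R/K-X9`; the zipper anchor is the first leucine after it that
  starts a leucine-periodic helix (canonically `L-X6-L-X6-L`, with
  2-heptad zippers admitted). Per-protein length, average molecular
  weight and isoelectric point (Bjellqvist pKa set, bisection on the
  Henderson–Hasselbalch net charge) are computed alongside.
* **Heptad register** — the zipper is partitioned into heptads
  `L0..L9` with slot order `g a b c d e f`; `L0` covers the four
  residues before the anchor leucine, the leucine (slot *d*) and the
  two residues after it.
* **Dimerization typing** — residue classes at the core positions *a*
  (Asn / hydrophobic I,V,L,M / charged R,K,E,D / other) and *d*
  (Leu / I,V,M / other); the `g↔e′` pair of each heptad is *complete*
  when both residues are charged and is typed attractive (`+/−`, `−/+`)
  or repulsive (`+/+`, `−/−`); proteins are binned as (I) homodimerizing
  (attractive pairs plus a-position Asn, no repulsive pair),
  (II) both, or (III) heterodimerizing (repulsive pairs only).
* **Family tables** — position composition, the heptad placement of
  a-position asparagines, and per-heptad `g↔e′` tallies.
* **Promoter scan** — exact-word search of −1500 bp promoter windows for
  the palindromic ACGT-core boxes bZIP dimers bind: A-box `TACGTA`,
  G-box `CACGTG`, C-box `GACGTC`.
* **Expression analysis** — `2^−ΔΔCt` relative quantification against a
  reference gene and calibrator sample, row scaling (z-scores) for
  heatmaps, and an all-pairs TF × target Pearson correlation screen
  with signed significant edges (Spearman and Benjamini–Hochberg
  available behind flags).

A synthetic-data module generates proteins, promoters and expression
panels with *planted* structure plus the planted truth, so every stage
is testable end to end without external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs (run them in order; outputs land under `results/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_scan_domains.py
python analysis/03_zipper_profiles.py
python analysis/04_family_stats.py
python analysis/05_promoter_boxes.py
python analysis/06_expression_network.py
```

`02` reports perfect separation of designed bZIPs from grammar-free
decoys:

```
designed bZIPs detected: 103/103 (sensitivity 100.0%)
decoys flagged: 0/20 (specificity 100.0%)
anchor mismatches vs planted truth: 0
```

`03` recovers every planted register and bins the family:

```
registers assigned: 103; planted-truth mismatches: 0
dimerization classes: {'III_heterodimer': 5, 'II_both': 70, 'I_homodimer': 26, 'indeterminate': 2}
```

meaning 26 proteins carry only attractive `g↔e′` pairs plus an
a-position Asn (homodimer-prone), 5 carry repulsive pairs only
(heterodimer-prone), and most mix both. `04` prints the family
composition (e.g. `a position over 555 heptads: asn 21.80%,
hydrophobic 34.05%, charged 20.72%, other 23.42%`), `05` confirms each
promoter's box hits equal its planted layout, and `06` screens the
63 TF × target pairs (`3 significant positive, 2 significant negative at
alpha=0.05`).

The same stages are available as a CLI (`zipprofiler scan|profile|
stats|promoter|ddct|correlate|simulate|run`); `zipprofiler run
--config run.yaml` executes everything and writes a deterministic run
manifest.

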