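# Methods

## Domain model

A bZIP domain is modelled as two exact-sequence signals. The basic
(DNA-binding) region is the 18-residue word `N-X7-[RK]-X9`: an invariant
asparagine, any seven residues, an arginine or lysine, any nine
residues. Matching is literal (a regular expression with overlap via
lookahead); there is no position weight matrix, profile HMM or E-value —
the grammar itself is the computation this package implements, and a
profile search would answer a different question (homology rather than
grammar membership).

The leucine zipper is anchored at the first leucine *at or after the end
of the basic-region match* (the basic region may itself contain
leucines, which are never zipper anchors here; the choice is logged per
protein). An anchor is accepted when a second heptad is available:
either another leucine exactly 7 residues downstream, or at least 7
residues following the anchor. This admits the 2-heptad zippers seen in
real family surveys while rejecting isolated terminal leucines. When
several basic-region matches have valid anchors, the leftmost wins
(deterministic tie-break; alternates are logged at debug level).

## Heptad register

Registers use slot order `g a b c d e f` with `L0` spanning
`[anchor−4, anchor+3)`, so the anchor leucine sits at slot *d*.
Subsequent heptads are consecutive 7-residue windows, stopping at the
sequence end or after `L9` (at most 10 heptads). A trailing partial
heptad is kept with absent (None) slots. If fewer than 4 residues
precede the anchor the register is kept with absent leading slots and a
`truncated_l0` flag rather than dropped — discarding would silently lose
real domains. (A truncated L0 can only arise in zipper fragments without
a basic region, since a basic-region match guarantees ≥14 residues
upstream of the anchor; `register_from_anchor` handles that case.)

## Pair typing and dimerization classes

Because the register starts at *g*, the inter-helical `g↔e′` contact
falls at slot *e* of the same register heptad (five residues downstream
of *g*), so pairs are taken within one heptad. A pair is *complete* only
when both residues are in {R, K, E, D}; histidine is deliberately not
counted as charged. Complete pairs are attractive basic–acidic,
attractive acidic–basic, repulsive basic, or repulsive acidic; anything
else is incomplete. Partial heptads contribute their defined slots to
composition statistics; their pair is incomplete if *g* or *e* is
absent.

Dimerization classes, with A = attractive pairs, Rp = repulsive pairs,
N = a-position asparagines in a register:

| class | rule |
|---|---|
| I (homodimer-prone) | A ≥ 1, Rp = 0, N ≥ 1 |
| III (heterodimer-prone) | Rp ≥ 1, A = 0 |
| II (both) | A ≥ 1 and Rp ≥ 1; also A ≥ 1, Rp = 0, N = 0 |
| indeterminate | A = 0, Rp = 0 |

The class-II cell for attractive-only registers without Asn is a design
choice: the homodimer class is defined by *both* the salt bridges and
the a-position polar pocket, so registers with only one line of evidence
fall to the middle class. The four classes partition any input set.

Family tables use heptad-wise denominators: the a/d composition
percentage divides by the number of defined slots at that position over
all proteins (not per-protein averages), and "total `g↔e′` pairs at
`Ln`" counts complete pairs only. Percentages are reported to 2
decimals.

## Physicochemical properties

Molecular weight is the sum of average residue masses plus one water
(via Biopython's ProtParam tables), reported in kDa. The isoelectric
point is the root of the Henderson–Hasselbalch net charge over the free
termini and the D, E, C, Y, H, K, R side chains with the Bjellqvist
(ExPASy) pKa values (N-term 7.5, K 10.0, R 12.0, H 5.98; C-term 3.55,
D 4.05, E 4.45, C 9.0, Y 10.0), found by bisection on [0, 14] to
|charge| < 1e−4. The charge is strictly decreasing in pH and changes
sign on that interval, so the root is unique; the model makes MW
additive up to one water and pI monotone under appending basic/acidic
residues, both of which are tested. Residue-specific terminal pKa
corrections (as in full ProtParam) are intentionally omitted; the tests
cross-check against Biopython's corrected implementation at a few-tenths
tolerance. Sequences containing X get length only; MW/pI are flagged
undefined, never zeroed.

## Promoter scan

Promoters are windows whose 3′ end is the translation start; offsets are
negative 1-based upstream coordinates of a match's 5′-most base (−1 is
the base immediately upstream). Scanning is exact-word over the final
`window` nt (default 1500) on both strands. All three box consensi are
reverse-complement palindromes, so a minus-strand hit always coincides
with a plus-strand hit and is collapsed to `+`; the code still scans the
reverse complement so non-palindromic user-supplied boxes behave
correctly. The bare `ACGT` core is opt-in — alone it matches every ~256
nt of random sequence and adds noise, not signal. A window longer than
the sequence scans the available span with a warning.

## Expression analysis

`2^−ΔΔCt` assumes 100% amplification efficiency (exact doubling per
cycle): ΔCt_s = Ct(target, s) − Ct(ref, s), ΔΔCt = ΔCt_s − ΔCt_cal,
fold = 2^−ΔΔCt. Samples missing the reference Ct are excluded with a
warning; a missing target Ct propagates as missing, never 0 (a Ct of 0
is physically meaningless). The calibrator's fold is identically 1 and
folds are multiplicative across calibrator choices — both are tested
identities of the exponent algebra.

Row scaling is the usual heatmap z-score (mean 0, sample SD with n−1
denominator); constant rows become all-missing with a warning.

The correlation screen emits one edge per (TF, target) pair: Pearson *r*
over complete sample pairs, two-sided p from the t transform with n−2
df, sign, and significance at α (default 0.05, matching the usual
"significant correlation" reporting). Pearson is the default because
the screened quantities are relative-expression values on a common
scale and the reported networks are signed; a Spearman option exists for
rank-robust screening, and Benjamini–Hochberg adjustment is available
but off by default since raw per-edge significance is what such surveys
report. Pairs with fewer than 3 complete observations or zero variance
get missing r/p rather than an arbitrary value.

## Synthetic data

The generators emulate exactly the structure the analysis assumes:

* **Proteins** — non-signal pad + basic region + zipper realizing a
  per-heptad design. Non-signal positions are drawn from {A, S, T, Q, G},
  an alphabet disjoint from every classification set (no N, I/V/L/M,
  R/K/E/D), so planted category counts are exact and recovery is
  deterministic. Pair categories are realized as g,e = (K,E), (E,K),
  (K,R), (D,E), (K,A). The layout provably admits exactly one
  basic-region match and anchors at the designed leucine (no N can sit
  exactly 8 residues before an R/K, and no L precedes the anchor after
  the basic region); designs that would break this — Leu at the a slot
  of L0, Asn at a d slot — are rejected as unrealizable. The C-terminal
  pad defaults to empty so the register length equals the designed
  heptad count, matching the typical bZIP architecture of a C-terminal
  zipper; a `c_pad` option exists to exercise scanners against trailing
  sequence.
* **Decoys** — rejection-sampled random proteins containing no
  basic-region window (bounded at 10,000 attempts, then an error, to
  avoid silent non-termination).
* **Promoters** — planted boxes in a background rejection-resampled
  until no hexamer consensus occurs off-plant (palindromy makes a
  plus-strand check sufficient).
* **Expression** — multivariate normal with identity covariance plus
  planted pairwise correlations; connected components of the planted
  graph are drawn jointly (non-PSD plants are rejected), with a
  vectorized path for the common disjoint-pair case. A constant baseline
  shift keeps values positive-ish without affecting r.

Random family designs draw slot classes at roughly the frequencies plant
bZIP surveys report (≈19% Asn / 35% hydrophobic / 20% charged at *a*;
≈50% Leu / 31% I,V,M at *d*; attractive-leaning pair mixture, zippers of
2–9 heptads). What the generators do **not** emulate: real amino-acid
background composition (decoy-free flanks are deliberately
signal-sparse), homology structure within a family, qPCR measurement
error models, or promoter base composition — so passing tests establish
the correctness of the bookkeeping on in-grammar inputs, not detection
performance against proteome-scale background.

## Problem sizes and determinism

The shipped analysis uses a 103-protein family with 20 decoys, 9
promoters, and a 7 × 9 expression panel over 10 samples (two varieties ×
5 monthly time points pooled, the design under which one combined
correlation matrix is reported). The verification runs use 1,000
designed zippers for register/recovery checks, 500 + 500
proteins/decoys for scan sensitivity/specificity, 100 promoter designs,
10,000 null pairs at n = 10 for false-positive calibration, and 500
pairs at ρ = 0.9 for recovery; at these sizes every check is stable
across seeds. Every random draw flows through a single
`numpy.random.Generator` seeded explicitly; all pipeline stages are
pure functions of (inputs, config), and the run manifest records a
config hash so reruns can be verified bit-identical.

## Known limitations

* The grammar scanner is not a homology search: family members whose
  basic region deviates from `N-X7-[RK]-X9` (as real divergent members
  can) are missed by construction.
* Dimerization classes are sequence heuristics over one helix; they do
  not model partner availability, free energy, or inter-protein
  pairing.
* Exact-word promoter matching finds the named boxes only; degenerate
  or half-site elements are out of scope.
* ΔΔCt assumes perfect efficiency; no efficiency-calibration input is
  accepted.
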