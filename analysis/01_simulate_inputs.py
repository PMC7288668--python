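"""Generate the synthetic study inputs: a designed bZIP family with
decoys, promoters with planted boxes, and expression panels with planted
correlation structure.  Truth files are written beside the data so later
steps can be scored against the plant."""

import json
from pathlib import Path

from zipprofiler.io import write_expression_table, write_fasta
from zipprofiler.simulate import (
    ExpressionDesign,
    PromoterDesign,
    make_decoy_protein,
    make_expression,
    make_family,
    make_promoter,
)

SEED = 20_260_929
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# 103 designed proteins — the size of a typical olive-scale bZIP family —
# plus 20 grammar-free decoys.
family = make_family(n_proteins=103, seed=SEED)
decoys = [make_decoy_protein(200, seed=SEED + 10_000 + i, protein_id=f"decoy{i + 1}")
          for i in range(20)]
write_fasta(list(family.records) + decoys, OUT / "proteins.fasta")
with open(OUT / "family_truth.json", "w") as fh:
    json.dump(family.truths, fh, indent=1)
print(f"{len(family.records)} designed bZIPs + {len(decoys)} decoys -> {OUT/'proteins.fasta'}")

# 9 promoters (the number of target-gene promoters a box figure typically
# shows), each with 1-3 planted boxes inside the -1500 nt window.
promoter_designs = [
    PromoterDesign("prom1", [("G-box", -700), ("A-box", -120)]),
    PromoterDesign("prom2", [("A-box", -1450)]),
    PromoterDesign("prom3", [("C-box", -333), ("G-box", -900)]),
    PromoterDesign("prom4", [("A-box", -60), ("A-box", -1200), ("G-box", -450)]),
    PromoterDesign("prom5", []),
    PromoterDesign("prom6", [("G-box", -6)]),
    PromoterDesign("prom7", [("C-box", -1000)]),
    PromoterDesign("prom8", [("A-box", -777), ("C-box", -88)]),
    PromoterDesign("prom9", [("G-box", -250), ("G-box", -1100)]),
]
records, truth = [], {}
for k, d in enumerate(promoter_designs):
    rec, t = make_promoter(d, seed=SEED + k)
    records.append(rec)
    truth[rec.id] = t
write_fasta(records, OUT / "promoters.fasta")
with open(OUT / "promoter_truth.json", "w") as fh:
    json.dump(truth, fh, indent=1)
print(f"{len(records)} promoters -> {OUT/'promoters.fasta'}")

# expression: 7 TFs x 9 lipid-pathway targets over 10 samples (two
# varieties x 5 monthly points), with planted positive and negative edges.
design = ExpressionDesign(
    tf_genes=[f"TF{i}" for i in range(1, 8)],
    lpg_genes=[f"LPG{i}" for i in range(1, 10)],
    n_samples=10,
    planted={
        ("TF1", "LPG1"): 0.8,
        ("TF1", "LPG2"): 0.5,
        ("TF2", "LPG3"): 0.9,
        ("TF3", "LPG4"): -0.9,
        ("TF4", "LPG5"): -0.85,
        ("TF5", "LPG6"): 0.95,
    },
)
tf, lpg, expr_truth = make_expression(design, seed=SEED)
write_expression_table(tf, OUT / "tf.tsv")
write_expression_table(lpg, OUT / "lpg.tsv")
with open(OUT / "expression_truth.json", "w") as fh:
    json.dump([[a, b, r] for (a, b), r in expr_truth.items()], fh, indent=1)
print(f"expression panels ({len(design.tf_genes)} TF x {len(design.lpg_genes)} LPG, "
      f"n={design.n_samples}) -> {OUT}")
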