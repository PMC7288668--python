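"""Scan the -1500 nt promoter set for A-box/G-box/C-box occurrences and
check the hits against the planted layout."""

import json
from pathlib import Path

from zipprofiler.io import read_fasta
from zipprofiler.pipeline import promoter_stage
from zipprofiler.promoter import scan_promoter

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "promoters"
OUT.mkdir(parents=True, exist_ok=True)

records = read_fasta(BASE / "inputs" / "promoters.fasta", alphabet="dna")
result = promoter_stage(records, OUT, window=1500, include_acgt_core=False)

truth = json.loads((BASE / "inputs" / "promoter_truth.json").read_text())
mismatches = 0
for rec in records:
    hits = [(h.box, h.offset) for h in scan_promoter(rec)]
    expected = [tuple(t) for t in sorted(truth[rec.id], key=lambda t: t[1])]
    if hits != expected:
        mismatches += 1
print(f"{result['outputs']['boxes.tsv']} box hits over {len(records)} promoters; "
      f"promoters disagreeing with the plant: {mismatches}")
print(f"table -> {OUT}/boxes.tsv")
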