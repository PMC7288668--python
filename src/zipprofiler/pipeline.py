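"""End-to-end orchestration: scan -> profile -> stats -> promoter ->
expression, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, expression, family_stats, io, promoter
from .domains import compute_props, scan_protein
from .zipper import SLOT_ORDER, assign_heptads, call_ge_pair, classify_dimerization

logger = logging.getLogger(__name__)

_ABSENT = "-"


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.  Defaults reproduce the
    standard settings: a 1500-nt promoter window and alpha = 0.05."""

    out_dir: str
    proteins: str | None = None
    promoters: str | None = None
    ct_table: str | None = None
    tf_table: str | None = None
    lpg_table: str | None = None
    reference_gene: str | None = None
    calibrator_sample: str | None = None
    window: int = 1500
    alpha: float = 0.05
    correlation_method: str = "pearson"
    include_acgt_core: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("proteins", "promoters", "ct_table", "tf_table", "lpg_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")
        if self.ct_table is not None and (
            self.reference_gene is None or self.calibrator_sample is None
        ):
            raise ValueError("ct_table requires reference_gene and calibrator_sample")
        if (self.tf_table is None) != (self.lpg_table is None):
            raise ValueError("tf_table and lpg_table must be given together")


def scan_stage(records, out_dir: Path) -> dict:
    """Locate domains and compute protein properties; writes domains.tsv
    (1-based inclusive coordinates) and props.tsv."""
    domain_rows, prop_rows, domains = [], [], {}
    for rec in records:
        dom = scan_protein(rec)
        props = compute_props(rec)
        prop_rows.append(
            {
                "protein_id": rec.id,
                "length": props.length,
                "mw_kda": None if props.mw is None else round(props.mw, 2),
                "pi": None if props.pi is None else round(props.pi, 2),
            }
        )
        if dom is None:
            continue
        domains[rec.id] = dom
        domain_rows.append(
            {
                "protein_id": rec.id,
                "basic_start": dom.basic_start + 1,
                "basic_end": dom.basic_end,
                "anchor_leu": dom.anchor_leu + 1,
                "zipper_end": dom.zipper_end,
                "truncated_l0": dom.truncated_l0,
            }
        )
    io.write_table(domain_rows, out_dir / "domains.tsv")
    io.write_table(prop_rows, out_dir / "props.tsv")
    return {
        "domains": domains,
        "outputs": {"domains.tsv": len(domain_rows), "props.tsv": len(prop_rows)},
    }


def profile_stage(records, domains, out_dir: Path) -> dict:
    """Assign heptad registers, type g<->e' pairs, classify dimerization;
    writes register.tsv, pairs.tsv, dimer.tsv."""
    seq_by_id = {rec.id: rec.sequence for rec in records}
    registers, reg_rows, pair_rows, dimer_rows = [], [], [], []
    for pid, dom in domains.items():
        reg = assign_heptads(dom, seq_by_id[pid])
        registers.append(reg)
        for h in reg.heptads:
            reg_rows.append(
                {
                    "protein_id": pid,
                    "heptad": h.index,
                    **{s: (h.slots[s] or _ABSENT) for s in SLOT_ORDER},
                }
            )
            call = call_ge_pair(h)
            pair_rows.append(
                {
                    "protein_id": pid,
                    "heptad": h.index,
                    "g": call.g_res or _ABSENT,
                    "e": call.e_res or _ABSENT,
                    "category": call.category,
                }
            )
        dim = classify_dimerization(reg)
        dimer_rows.append(
            {
                "protein_id": pid,
                "category": dim.category,
                "n_attractive": dim.n_attractive,
                "n_repulsive": dim.n_repulsive,
                "n_asn_a": dim.n_asn_a,
            }
        )
    io.write_table(reg_rows, out_dir / "register.tsv")
    io.write_table(pair_rows, out_dir / "pairs.tsv")
    io.write_table(dimer_rows, out_dir / "dimer.tsv")
    return {
        "registers": registers,
        "outputs": {
            "register.tsv": len(reg_rows),
            "pairs.tsv": len(pair_rows),
            "dimer.tsv": len(dimer_rows),
        },
    }


def stats_stage(registers, out_dir: Path) -> dict:
    """Family-level composition tables; writes position_composition.tsv,
    asn_histogram.tsv, ge_histogram.tsv (and .json mirrors)."""
    import pandas as pd

    comp = pd.concat(
        [
            family_stats.position_composition(registers, "a").to_frame(),
            family_stats.position_composition(registers, "d").to_frame(),
        ],
        ignore_index=True,
    )
    comp["percentage"] = comp["percentage"].round(2)
    asn = family_stats.asn_histogram(registers).to_frame()
    asn["percentage"] = asn["percentage"].round(2)
    ge = family_stats.ge_histogram(registers).to_frame()
    outputs = {}
    for name, frame in (
        ("position_composition", comp),
        ("asn_histogram", asn),
        ("ge_histogram", ge),
    ):
        io.write_table(frame, out_dir / f"{name}.tsv")
        io.write_table(frame, out_dir / f"{name}.json", format="json")
        outputs[f"{name}.tsv"] = len(frame)
    return {"outputs": outputs}


def promoter_stage(records, out_dir: Path, window: int, include_acgt_core: bool) -> dict:
    boxes = list(promoter.DEFAULT_BOXES)
    if include_acgt_core:
        boxes.append(promoter.ACGT_CORE)
    rows = []
    for rec in records:
        for hit in promoter.scan_promoter(rec, boxes, window=window):
            rows.append(
                {
                    "promoter_id": hit.promoter_id,
                    "box": hit.box,
                    "offset": hit.offset,
                    "strand": hit.strand,
                }
            )
    io.write_table(rows, out_dir / "boxes.tsv")
    return {"outputs": {"boxes.tsv": len(rows)}}


def expression_stage(cfg: RunConfig, out_dir: Path) -> dict:
    outputs = {}
    if cfg.ct_table is not None:
        ct = io.read_expression_table(cfg.ct_table, kind="ct")
        folds = expression.delta_delta_ct(ct, cfg.reference_gene, cfg.calibrator_sample)
        io.write_table(folds, out_dir / "folds.tsv")
        outputs["folds.tsv"] = len(folds)
    if cfg.tf_table is not None:
        tf = io.read_expression_table(cfg.tf_table, kind="relative")
        lpg = io.read_expression_table(cfg.lpg_table, kind="relative")
        edges = expression.correlate(
            tf, lpg, alpha=cfg.alpha, method=cfg.correlation_method
        )
        io.write_table(expression.edges_to_frame(edges), out_dir / "edges.tsv")
        outputs["edges.tsv"] = len(edges)
    return {"outputs": outputs}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage in order and write manifest.json.

    Stages with no configured input are skipped.  A rerun with the same
    config and inputs produces identical outputs and manifest content
    (timing is reported separately from the manifest hash fields).
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": [],
    }

    def record_stage(name: str, outputs: dict) -> None:
        manifest["stages"].append({"stage": name, "outputs": outputs})
        logger.info("stage %s: %s", name, outputs)

    t0 = time.time()
    try:
        registers = None
        if cfg.proteins is not None:
            records = io.read_fasta(cfg.proteins, alphabet="protein")
            scan = scan_stage(records, out_dir)
            record_stage("scan", scan["outputs"])
            profile = profile_stage(records, scan["domains"], out_dir)
            record_stage("profile", profile["outputs"])
            registers = profile["registers"]
            if registers:
                stats = stats_stage(registers, out_dir)
                record_stage("stats", stats["outputs"])
        if cfg.promoters is not None:
            promoters = io.read_fasta(cfg.promoters, alphabet="dna")
            prom = promoter_stage(promoters, out_dir, cfg.window, cfg.include_acgt_core)
            record_stage("promoter", prom["outputs"])
        if cfg.ct_table is not None or cfg.tf_table is not None:
            expr = expression_stage(cfg, out_dir)
            record_stage("expression", expr["outputs"])
    except Exception as exc:
        manifest["failed_at"] = len(manifest["stages"])
        manifest["error"] = str(exc)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
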