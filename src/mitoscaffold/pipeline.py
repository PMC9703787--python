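"""Stage orchestration: one config, deterministic seeds, manifest output.

The pipeline runs select -> scaffold -> polish -> repeats -> MTPT ->
assembly stats over the inputs named in a single (YAML-able) config
mapping, writing each stage's tables and sequences into ``outdir`` plus
a manifest of (file, stage, sha256). Identical config and seed give
identical checksums. A ``simulate`` block generates the full synthetic
input set first, which makes the bundled demo self-contained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as mio
from .comparative import CopyNumberInputs, estimate_copy_number
from .mtpt import find_mtpts
from .polish import MapParams, polish_scaffolds
from .repeats import RepeatParams, find_repeats, repeat_proportion, repeat_summary
from .scaffold import (
    ScaffoldParams,
    build_scaffolds,
    placements_table,
    scaffold_records,
)
from .select import (
    ClassBands,
    Contig,
    SelectParams,
    assign_copy_class,
    coverage_from_table,
    gene_hits_from_table,
    select_mito_contigs,
    selection_table,
)
from .simulate import (
    ConfigError,
    LongReadSpec,
    MoleculeSpec,
    MtptSpec,
    RepeatLenMixture,
    ShortReadSpec,
    SimConfig,
    fragment_to_contigs,
    plant_mtpts,
    simulate_long_reads,
    simulate_mitogenome,
    simulate_plastome,
    simulate_short_reads,
)

log = logging.getLogger("mitoscaffold")


class PipelineError(RuntimeError):
    pass


def sim_config_from_dict(d: dict[str, Any], seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a plain mapping (nested spec blocks allowed)."""
    d = dict(d)
    if seed is not None:
        d.setdefault("seed", seed)
    if "molecules" in d:
        d["molecules"] = tuple(MoleculeSpec(**m) for m in d["molecules"])
    for key, cls in (
        ("repeat_len_mixture", RepeatLenMixture),
        ("mtpt", MtptSpec),
        ("long_reads", LongReadSpec),
        ("short_reads", ShortReadSpec),
    ):
        if key in d and isinstance(d[key], dict):
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
            }
            d[key] = cls(**sub)
    for key in ("unique_len_range", "structural_repeat_len_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_cmd(config: dict[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic input set (sequences, reads, truth tables)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim = sim_config_from_dict(config.get("simulate", {}), seed=seed)
    plastome = simulate_plastome(seed=sim.seed)
    truth = simulate_mitogenome(sim)
    if sim.mtpt.n_inserts:
        truth = plant_mtpts(truth, plastome, sim.mtpt)
    frag = config.get("fragment", {})
    contigs, cov = fragment_to_contigs(
        truth,
        base_depth=float(frag.get("base_depth", 89.0)),
        noise_sd=float(frag.get("noise_sd", 0.0)),
        junction_trim=int(frag.get("junction_trim", 100)),
    )
    long_reads = simulate_long_reads(truth)
    r1, r2 = simulate_short_reads(truth)

    paths = {
        "molecules": out / "truth_molecules.fasta",
        "contigs": out / "contigs.fasta",
        "coverage": out / "coverage.tsv",
        "gene_hits": out / "gene_hits.tsv",
        "long_reads": out / "long_reads.fasta",
        "short_reads_1": out / "short_1.fastq",
        "short_reads_2": out / "short_2.fastq",
        "plastome": out / "plastome.fasta",
        "truth_junctions": out / "truth_junctions.tsv",
        "truth_repeats": out / "truth_repeats.tsv",
        "truth_mtpt": out / "truth_mtpt.tsv",
    }
    mio.write_fasta(truth.molecule_records(), paths["molecules"])
    mio.write_fasta(
        [mio.SeqRecord(c.id, c.sequence) for c in contigs], paths["contigs"]
    )
    mio.write_tsv(cov[["contig_id", "length", "mean_cov"]], paths["coverage"])
    hits = pd.DataFrame(
        [
            {"contig_id": c.id, "gene": g, "identity": 1.0}
            for c in contigs
            for g in c.gene_hits
        ],
        columns=["contig_id", "gene", "identity"],
    )
    mio.write_tsv(hits, paths["gene_hits"])
    mio.write_fasta(long_reads, paths["long_reads"])
    mio.write_fastq(r1, paths["short_reads_1"])
    mio.write_fastq(r2, paths["short_reads_2"])
    mio.write_fasta([plastome], paths["plastome"])
    mio.write_tsv(
        pd.DataFrame(
            truth.junction_table,
            columns=["from_id", "from_strand", "to_id", "to_strand", "molecule"],
        ),
        paths["truth_junctions"],
    )
    rep_rows = [
        {"family": fam, "molecule": mol, "start": s, "end": e, "strand": st, "tier": "structural"}
        for fam, places in truth.repeat_placements.items()
        for mol, s, e, st in places
    ]
    for i, (unit, places) in enumerate(truth.embedded_repeats):
        rep_rows += [
            {"family": f"emb{i + 1}", "molecule": sid, "start": s, "end": e,
             "strand": st, "tier": "embedded"}
            for sid, s, e, st in places
        ]
    mio.write_tsv(
        pd.DataFrame(rep_rows, columns=["family", "molecule", "start", "end", "strand", "tier"]),
        paths["truth_repeats"],
    )
    mio.write_tsv(
        pd.DataFrame([dataclasses.asdict(t) for t in truth.mtpt_truth]),
        paths["truth_mtpt"],
    )
    return paths


def run_pipeline(config: dict[str, Any], outdir: str | Path | None = None) -> pd.DataFrame:
    """Run all stages; returns the artifact manifest (file, stage, sha256)."""
    out = Path(outdir or config.get("outdir", "mitoscaffold_out"))
    manifest: list[tuple[str, str]] = []  # (file, stage)

    inputs = config.get("inputs", {})
    if "simulate" not in config:
        # fail on missing inputs before anything is written
        for key in ("contigs", "coverage", "long_reads", "short_reads_1", "short_reads_2"):
            if key not in inputs:
                raise ConfigError(f"missing required input {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"input path does not exist: {inputs[key]}")
    out.mkdir(parents=True, exist_ok=True)
    if "simulate" in config:
        t0 = time.time()
        sim_paths = simulate_cmd(config, out / "simulated")
        inputs = {
            k: str(sim_paths[k])
            for k in (
                "contigs", "coverage", "gene_hits", "long_reads",
                "short_reads_1", "short_reads_2", "plastome",
            )
        }
        log.info("stage simulate done in %.1fs", time.time() - t0)
        manifest += [(str(p), "simulate") for p in sim_paths.values()]

    required = ("contigs", "coverage", "long_reads", "short_reads_1", "short_reads_2")
    for key in required:
        if key not in inputs:
            raise ConfigError(f"missing required input {key!r}")
        if not Path(inputs[key]).exists():
            raise ConfigError(f"input path does not exist: {inputs[key]}")

    # ---- selection -------------------------------------------------
    t0 = time.time()
    contig_recs = mio.read_fasta(inputs["contigs"])
    contigs = [Contig(id=r.id, sequence=r.sequence) for r in contig_recs]
    coverage_from_table(contigs, mio.read_tsv(inputs["coverage"]))
    if "gene_hits" in inputs and Path(inputs["gene_hits"]).exists():
        gene_hits_from_table(contigs, mio.read_tsv(inputs["gene_hits"]))
    sel_cfg = config.get("select", {})
    sel_params = SelectParams(
        min_len=int(sel_cfg.get("min_len", 2000)),
        cov_range=tuple(sel_cfg["cov_range"]) if sel_cfg.get("cov_range") else None,
    )
    select_mito_contigs(contigs, sel_params)
    cls_cfg = config.get("classify", {})
    assign_copy_class([c for c in contigs], ClassBands(**cls_cfg))
    sel_path = out / "selection.tsv"
    mio.write_tsv(selection_table(contigs), sel_path)
    manifest.append((str(sel_path), "select"))
    log.info("stage select done in %.1fs", time.time() - t0)

    selected = [c for c in contigs if c.selected]

    # ---- scaffolding -----------------------------------------------
    t0 = time.time()
    long_reads = mio.read_seqs(inputs["long_reads"])
    sc_cfg = {k: v for k, v in config.get("scaffold", {}).items()}
    sc_params = ScaffoldParams(**sc_cfg)
    result = build_scaffolds(selected, long_reads, sc_params)
    scaff_path = out / "scaffolds.fasta"
    mio.write_fasta(scaffold_records(result), scaff_path)
    pl_path = out / "placements.tsv"
    mio.write_tsv(placements_table(result, {c.id: c for c in selected}), pl_path)
    ev_rows = [
        {
            "contig_a": k[0][0], "end_a": k[0][1],
            "contig_b": k[1][0], "end_b": k[1][1],
            "support": ev.support, "best_read": ev.best.read_id,
        }
        for k, ev in sorted(result.evidence.items())
    ]
    ev_path = out / "evidence.tsv"
    mio.write_tsv(
        pd.DataFrame(ev_rows, columns=["contig_a", "end_a", "contig_b", "end_b", "support", "best_read"]),
        ev_path,
    )
    adj_path = out / "adjacency_report.tsv"
    mio.write_tsv(result.adjacency_report, adj_path)
    manifest += [(str(p), "scaffold") for p in (scaff_path, pl_path, ev_path, adj_path)]
    log.info("stage scaffold done in %.1fs", time.time() - t0)

    # ---- polishing -------------------------------------------------
    t0 = time.time()
    r1 = mio.read_seqs(inputs["short_reads_1"])
    r2 = mio.read_seqs(inputs["short_reads_2"])
    plastome = None
    if "plastome" in inputs and Path(inputs["plastome"]).exists():
        plastome = mio.read_fasta(inputs["plastome"])[0]
    po_cfg = config.get("polish", {})
    polished, change_log = polish_scaffolds(
        result.scaffolds,
        r1 + r2,
        plastome,
        low_cov_threshold=int(po_cfg.get("low_cov_threshold", 5)),
        low_cov_mode=po_cfg.get("low_cov_mode", "reference"),
    )
    polished_recs = [
        mio.SeqRecord(
            s.id if not s.circular else f"{s.id}_circ",
            s.sequence,
            f"circular={'yes' if s.circular else 'no'}",
        )
        for s in polished
    ]
    pol_path = out / "polished.fasta"
    mio.write_fasta(polished_recs, pol_path)
    log_path = out / "polish_log.tsv"
    mio.write_tsv(change_log, log_path)
    manifest += [(str(pol_path), "polish"), (str(log_path), "polish")]
    log.info("stage polish done in %.1fs", time.time() - t0)

    # ---- repeats + MTPT + stats ------------------------------------
    t0 = time.time()
    rp_cfg = config.get("repeats", {})
    rp = RepeatParams(
        min_len=int(rp_cfg.get("min_len", 24)),
        accounting_mode=rp_cfg.get("mode", "union"),
    )
    fams = find_repeats(polished_recs, rp)
    prop = repeat_proportion(fams, polished_recs, mode=rp.accounting_mode)
    count, mean_len, mean_cn, hist = repeat_summary(
        fams, min_len=int(rp_cfg.get("summary_min_len", 50))
    )
    fam_rows = [
        {"family": f.family_id, "unit_length": f.unit_length,
         "copy_number": f.copy_number,
         "copies": ";".join(f"{sid}:{s}-{e}:{st}" for sid, s, e, st in f.copies)}
        for f in fams
    ]
    fam_path = out / "repeat_families.tsv"
    mio.write_tsv(pd.DataFrame(fam_rows, columns=["family", "unit_length", "copy_number", "copies"]), fam_path)
    bed_path = out / "repeats.bed"
    mio.write_bed(
        [(sid, s, e, f.family_id) for f in fams for sid, s, e, _ in f.copies],
        bed_path,
    )
    summary = pd.DataFrame(
        [{
            "repeat_proportion": prop,
            "n_families_ge_summary_min": count,
            "mean_unit_length": mean_len,
            "mean_copy_number": mean_cn,
            "hist_50_200": hist[0], "hist_200_1k": hist[1],
            "hist_1k_10k": hist[2], "hist_gt_10k": hist[3],
        }]
    )
    sum_path = out / "repeat_summary.tsv"
    mio.write_tsv(summary, sum_path)
    manifest += [(str(p), "repeats") for p in (fam_path, bed_path, sum_path)]

    if plastome is not None:
        mt_cfg = config.get("mtpt", {})
        regions, mt_prop = find_mtpts(
            polished_recs,
            plastome,
            min_len=int(mt_cfg.get("min_len", 50)),
            min_identity=float(mt_cfg.get("min_identity", 0.90)),
        )
        mt_rows = [dataclasses.asdict(r) for r in regions]
        mt_path = out / "mtpt.tsv"
        mio.write_tsv(
            pd.DataFrame(mt_rows, columns=[
                "mito_id", "mito_start", "mito_end", "plast_start", "plast_end",
                "strand", "identity"]),
            mt_path,
        )
        mtb_path = out / "mtpt.bed"
        mio.write_bed(
            [(r.mito_id, r.mito_start, r.mito_end, f"mtpt_{i + 1}") for i, r in enumerate(regions)],
            mtb_path,
        )
        manifest += [(str(mt_path), "mtpt"), (str(mtb_path), "mtpt")]

    from .stats import assembly_stats

    st = assembly_stats(polished_recs)
    st_path = out / "assembly_stats.tsv"
    mio.write_tsv(pd.DataFrame([dataclasses.asdict(st)]), st_path)
    manifest.append((str(st_path), "stats"))
    log.info("stage repeats/mtpt/stats done in %.1fs", time.time() - t0)

    rows = [
        {"file": f, "stage": stage, "sha256": _sha256(Path(f))}
        for f, stage in manifest
    ]
    mdf = pd.DataFrame(rows, columns=["file", "stage", "sha256"])
    mio.write_tsv(mdf, out / "manifest.tsv")
    return mdf


def demo_config(outdir: str | Path, seed: int = 1) -> dict[str, Any]:
    """Self-contained synthetic demonstration config (runs in minutes)."""
    return {
        "seed": seed,
        "outdir": str(outdir),
        "simulate": {
            "seed": seed,
            "n_unique_segments": 5,
            "unique_len_range": [8000, 16000],
            "n_repeat_families": 1,
            "n_embedded_repeat_pairs": 3,
            "mtpt": {"n_inserts": 3, "insert_len_range": [100, 400], "identity": 0.95},
            "long_reads": {"error_rate": 0.02, "depth": 25},
            "short_reads": {"depth": 30},
        },
        "fragment": {"junction_trim": 100},
        "repeats": {"min_len": 24, "summary_min_len": 50},
    }
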