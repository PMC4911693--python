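"""End-to-end run orchestration: simulate -> clean -> circ-call -> quantify
-> deg -> circ-stats -> novel-filter, with a run manifest.

The run configuration is one declarative YAML mapping; every stage
threshold is surfaced with its default.  All outputs are plain TSV/JSON and
deterministic under the configured seed (the manifest's timestamps are the
only non-reproducible bytes, so determinism checks compare everything but
the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .circcall import (
    annotate_backsplices,
    attach_forward_reads,
    classify_exon_position,
    filter_support,
)
from .circstats import alu_enrichment, flanking_features, sample_control_introns
from .diffexpr import classify_maternal_zygotic, de_series, size_factors
from .ioformats import (
    read_bed,
    read_chimeric,
    read_count_table,
    read_gtf,
    read_linear_junctions,
    read_spikein_table,
    write_circ_table,
)
from .noveltx import filter_novel, read_novel_table, write_novel_table
from .quantcopy import (
    circ_copy_number,
    circ_rpkm,
    compute_rpkm,
    ercc_qc,
    estimate_sample_copies,
)
from .readqc import clean_read_pairs, read_fastq, write_fastq
from .synth import SimulationConfig, simulate_all

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run",
    "simulate": {},  # SimulationConfig overrides
    "clean": {
        "qual_threshold": 5,
        "lowqual_frac": 0.5,
        "n_frac": 0.1,
        "at_frac": 0.8,
        "polyrun": 24,
        "min_len": 30,
    },
    "circ_call": {"min_reads": 2, "tol": 0},
    "quantify": {"min_attomole": 0.001, "anchor": 25},
    "deg": {"four_cell_stage": "4cell", "fc_up": 2.0, "fc_down": 0.5,
            "alpha_fdr": 0.05, "min_rpkm_gate": 1.0},
    "circ_stats": {},
    "novel_filter": {"min_rpkm": 0.5, "min_rep_rpkm": 0.25,
                     "min_dist": 10000, "min_exons": 2, "min_len": 500},
}

_KNOWN_SECTIONS = set(DEFAULT_CONFIG)


def load_config(source: str | Path | dict) -> dict:
    """Merge a user config (YAML path or dict) over the defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    unknown = set(user) - _KNOWN_SECTIONS
    if unknown:
        raise PipelineError(f"unknown config section(s): {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if isinstance(value, dict):
            bad = [
                k for k in value
                if key != "simulate" and k not in DEFAULT_CONFIG[key]
            ]
            if key == "simulate":
                sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
                bad = [k for k in value if k not in sim_fields]
            if bad:
                raise PipelineError(f"unknown config field(s) {key}.{bad}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Any stage failure raises :class:`PipelineError` after writing the
    manifest collected so far (with the error recorded).
    """
    cfg = load_config(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    fixtures = out / "fixtures"
    manifest: dict = {
        "command": "pipeline",
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }
    try:
        _run_stages(cfg, out, fixtures, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        raise PipelineError(str(exc)) from exc
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _run_stages(cfg: dict, out: Path, fixtures: Path, manifest: dict) -> None:
    # --- simulate ------------------------------------------------------
    sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulate"])
    simulate_all(sim_cfg, fixtures)
    manifest["stages"].append("simulate")

    # --- clean ---------------------------------------------------------
    ccfg = cfg["clean"]
    adaptors = [
        line.strip()
        for line in (fixtures / "adaptors.txt").read_text().splitlines()
        if line.strip()
    ]
    r1 = list(read_fastq(fixtures / "reads_R1.fastq"))
    r2 = list(read_fastq(fixtures / "reads_R2.fastq"))
    k1, k2, rep1, rep2 = clean_read_pairs(r1, r2, adaptors, **ccfg)
    write_fastq(k1, out / "clean_R1.fastq")
    write_fastq(k2, out / "clean_R2.fastq")
    pd.DataFrame([rep1.as_dict(), rep2.as_dict()], index=["R1", "R2"]).to_csv(
        out / "qc_report.tsv", sep="\t"
    )
    manifest["stages"].append("clean")

    # --- circ-call -----------------------------------------------------
    genes = read_gtf(fixtures / "genes.gtf")
    chimeric, _ = read_chimeric(fixtures / "chimeric.tsv")
    candidates, diag = annotate_backsplices(
        chimeric, genes, tol=cfg["circ_call"]["tol"]
    )
    records = filter_support(candidates, min_reads=cfg["circ_call"]["min_reads"])
    by_id = {g.gene_id: g for g in genes}
    for rec in records:
        classify_exon_position(rec, by_id[rec.hosting_gene])
    linear = read_linear_junctions(fixtures / "linear_junctions.tsv")
    attach_forward_reads(records, linear)
    write_circ_table(records, out / "circ.bed")
    pd.DataFrame([dataclasses.asdict(diag)]).to_csv(
        out / "circ_call_diagnostics.tsv", sep="\t", index=False
    )
    manifest["stages"].append("circ-call")

    # --- quantify ------------------------------------------------------
    counts = read_count_table(fixtures / "counts.tsv", fixtures / "samples.tsv")
    panel = read_spikein_table(fixtures / "spikeins.tsv")
    gene_lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genes}, dtype=float
    )
    estimates, gene_rpkm = estimate_sample_copies(
        counts, panel, gene_lengths,
        min_attomole=cfg["quantify"]["min_attomole"],
    )
    ercc_ids = [s.species_id for s in panel.ercc()]
    spike_lengths = panel.lengths()
    all_lengths = pd.concat([gene_lengths, spike_lengths])
    rpkm_all = compute_rpkm(counts, all_lengths.reindex(counts.counts.index))
    qc = ercc_qc(rpkm_all.loc[rpkm_all.index.isin(ercc_ids)])
    anchor = cfg["quantify"]["anchor"]
    circ_copies = {}
    for est in estimates:
        sample = est.sample_id
        read_len = int(counts.meta.loc[sample, "read_length"])
        mapped = float(counts.meta.loc[sample, "total_mapped_reads"])
        circ_sum = 0.0
        for rec in records:
            back = rec.back_reads.get(sample, 0)
            if back:
                circ_sum += float(circ_rpkm(back, read_len, mapped, anchor))
        refseq_sum = float(gene_rpkm[sample].sum())
        est.circ_copies = circ_copy_number(circ_sum, refseq_sum, est.final_copies)
        circ_copies[sample] = est.circ_copies
    pd.DataFrame(
        [dataclasses.asdict(e) for e in estimates]
    ).to_csv(out / "copies.tsv", sep="\t", index=False)
    gene_rpkm.rename_axis("gene_id").to_csv(out / "rpkm.tsv", sep="\t")
    with open(out / "ercc_qc.json", "w") as fh:
        json.dump(
            {
                "ok": qc.ok,
                "n_retained": len(qc.retained),
                "mean_pearson": None if qc.pearson is None else qc.mean_offdiag,
            },
            fh, indent=2,
        )
        fh.write("\n")
    manifest["stages"].append("quantify")

    # --- deg -----------------------------------------------------------
    dcfg = cfg["deg"]
    copies = pd.Series({e.sample_id: e.final_copies for e in estimates})
    factors = size_factors(counts, copies)
    stage_of = counts.meta["stage"]
    stages = list(sim_cfg.stages)
    norm_rpkm = gene_rpkm.div(factors, axis=1)
    keep = norm_rpkm.index[(norm_rpkm >= dcfg["min_rpkm_gate"]).any(axis=1)]
    gene_counts = counts.counts.loc[counts.counts.index.isin(gene_lengths.index)]
    from .ioformats import CountTable

    gene_table = CountTable(gene_counts, counts.meta)
    de = de_series(
        gene_table, stage_of, stages, factors, keep_genes=keep,
        fc_up=dcfg["fc_up"], fc_down=dcfg["fc_down"],
        alpha_fdr=dcfg["alpha_fdr"],
    )
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    for (a, b), res in de.items():
        res.rename_axis("gene_id").to_csv(de_dir / f"de_{a}_vs_{b}.tsv", sep="\t")
    stage_rpkm = norm_rpkm.T.groupby(stage_of).mean().T
    classes = classify_maternal_zygotic(
        de, stage_rpkm, stages, four_cell_stage=dcfg["four_cell_stage"]
    )
    classes.rename_axis("gene_id").to_csv(out / "gene_classes.tsv", sep="\t")
    manifest["stages"].append("deg")

    # --- circ-stats ----------------------------------------------------
    features = flanking_features(records, genes)
    features.per_circ.to_csv(out / "circ_features.tsv", sep="\t", index=False)
    features.per_gene.rename_axis("gene_id").to_csv(
        out / "circ_isoforms.tsv", sep="\t"
    )
    repeats = read_bed(fixtures / "repeats.bed")
    flanking = [
        (row.chrom, int(row.upstream_intron_start), int(row.upstream_intron_end))
        for row in features.per_circ.itertuples(index=False)
        if row.upstream_intron_start >= 0
    ] + [
        (row.chrom, int(row.downstream_intron_start), int(row.downstream_intron_end))
        for row in features.per_circ.itertuples(index=False)
        if row.downstream_intron_start >= 0
    ]
    hosting = {rec.hosting_gene for rec in records}
    controls = sample_control_introns(
        genes, hosting, n=len(flanking), seed=cfg["seed"] + 7
    )
    alu = alu_enrichment(flanking, controls, repeats, seed=cfg["seed"] + 8)
    with open(out / "alu_enrichment.json", "w") as fh:
        json.dump(
            {
                "flanking_density_per_kb": alu.flanking_density_per_kb,
                "control_density_per_kb": alu.control_density_per_kb,
                "p_value": alu.p_value,
                "n_flanking": len(alu.flanking_counts),
                "n_control": len(alu.control_counts),
            },
            fh, indent=2,
        )
        fh.write("\n")
    manifest["stages"].append("circ-stats")

    # --- novel-filter --------------------------------------------------
    ncfg = cfg["novel_filter"]
    candidates_nov = read_novel_table(fixtures / "novel_candidates.tsv")
    kept, tally = filter_novel(candidates_nov, genes, **ncfg)
    write_novel_table(kept, out / "novel_kept.tsv")
    tally.as_frame().to_csv(out / "novel_tally.tsv", sep="\t", index=False)
    manifest["stages"].append("novel-filter")
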