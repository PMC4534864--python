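"""End-to-end orchestration of the MSAP and msGBS tracks.

``run_msap_track`` turns peak tables into the qualitative (PhiPT/AMOVA,
diagnostic markers, PCoA) and quantitative (NB exact test) summaries;
``run_gbs_track`` runs demultiplexing, filtering, per-variety differential
tests, phase-conserved consensus calling and gene-window annotation.
Every output file carries a header with the config hash and seed, so two
runs with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amova, annotate, dmr, gbs, msap, nbstats
from .datatypes import TagCountMatrix
from .simulate import (
    CONTROL_SAMPLE,
    SimConfig,
    design_metadata,
    simulate_gbs_reads,
    simulate_msap_profiles,
)


@dataclass
class PipelineConfig:
    """All tunables of both tracks; unknown keys are rejected at load."""

    peak_table: str | None = None
    metadata: str | None = None
    fastq: str | None = None
    barcodes: str | None = None
    genome: str | None = None
    gff: str | None = None
    out_dir: str = "epifidelity_out"
    binning_tolerance_bp: float = 0.5
    qualitative_window: tuple[float, float] = (100.0, 580.0)
    quantitative_window: tuple[float, float] = (50.0, 550.0)
    presence_threshold: float = 0.0
    low_filter_mode: str = "mean"
    low_filter_value: float = 0.0
    n_perm: int = 999
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_n: float = 10.0
    fdr: float = 0.05
    min_varieties: int = 4
    annotation_window: int = 5000
    tag_len: int = 64
    min_samples: int = 3
    control_sample: str = CONTROL_SAMPLE
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides for simulated inputs

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    header = f"# epifidelity config={config.config_hash()} seed={config.seed}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def _tissue_pairs(tissues) -> list[tuple[str, str]]:
    return list(itertools.combinations(tissues, 2))


def run_msap_track(
    config: PipelineConfig,
    records: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Qualitative + quantitative MSAP analysis.

    Produces per-cultivar field-vs-in_vitro PhiPT (per enzyme), tissue-pair
    PhiPT per condition with cross-cultivar averages, condition-diagnostic
    marker tables, per-cultivar PCoA coordinates and quantitative NB
    exact-test summaries. Returns the result objects and writes CSVs under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    rng_seed = config.seed
    if records is None:
        records, meta, _ = simulate_msap_profiles(config.sim_config())
    elif meta is None:
        raise ValueError("metadata required when peak records are supplied")
    bad = set(meta["condition"]) - {"field", "in_vitro"}
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")

    catalog = msap.bin_peaks(records, config.binning_tolerance_bp)
    binary = msap.score_binary(
        records, catalog, config.qualitative_window, config.presence_threshold,
        samples=list(meta.index),
    )
    heights = msap.build_height_matrix(
        records, catalog, config.quantitative_window,
        (config.low_filter_mode, config.low_filter_value), samples=list(meta.index),
    )

    varieties = list(pd.unique(meta["variety"]))
    enzymes = [e for e in ("HpaII", "MspI") if e in {c[0] for c in binary.columns}]

    # --- per-cultivar field vs in_vitro PhiPT ------------------------------
    rows = []
    for v, enzyme in itertools.product(varieties, enzymes):
        sids = meta.index[meta["variety"] == v]
        sub = binary.loc[sids, enzyme]
        d = amova.binary_distance(sub)
        res = amova.amova_phipt(
            d, meta.loc[sids, "condition"], n_perm=config.n_perm, seed=rng_seed
        )
        rows.append(
            {"variety": v, "enzyme": enzyme, "comparison": "field_vs_in_vitro",
             "phipt": res.phipt, "p_value": res.p_value, "n_perm": res.n_perm}
        )
    condition_phipt = pd.DataFrame(rows)

    # --- tissue-pair PhiPT within each condition ---------------------------
    tissues = list(pd.unique(meta["tissue"]))
    rows = []
    for v, enzyme, cond, (t1, t2) in itertools.product(
        varieties, enzymes, ("field", "in_vitro"), _tissue_pairs(tissues)
    ):
        sids = meta.index[
            (meta["variety"] == v)
            & (meta["condition"] == cond)
            & meta["tissue"].isin([t1, t2])
        ]
        present = set(meta.loc[sids, "tissue"])
        if {t1, t2} - present:
            phipt, p = np.nan, np.nan
        else:
            d = amova.binary_distance(binary.loc[sids, enzyme])
            res = amova.amova_phipt(
                d, meta.loc[sids, "tissue"], n_perm=config.n_perm, seed=rng_seed
            )
            phipt, p = res.phipt, res.p_value
        rows.append(
            {"tissue_pair": f"{t1}-{t2}", "enzyme": enzyme, "condition": cond,
             "variety": v, "phipt": phipt, "p_value": p}
        )
    tissue_phipt = pd.DataFrame(rows)
    pivot = tissue_phipt.pivot_table(
        index="variety", columns=["tissue_pair", "enzyme", "condition"],
        values="phipt", dropna=False,
    )
    averages = amova.tissue_divergence_summary(pivot)

    # --- diagnostic markers ------------------------------------------------
    per_cultivar = {}
    for v in varieties:
        sids = meta.index[meta["variety"] == v]
        per_cultivar[v] = amova.diagnostic_markers(
            binary.loc[sids], meta.loc[sids, "condition"]
        )
    shared = amova.all_cultivar_diagnostics(per_cultivar)
    diag = pd.DataFrame(
        {v: df["diagnostic"] for v, df in per_cultivar.items()}
    )
    diag["all_cultivars"] = diag.index.isin(shared)

    # --- PCoA per cultivar --------------------------------------------------
    pcoa_frames = []
    for v in varieties:
        sids = meta.index[meta["variety"] == v]
        res = amova.pcoa(amova.binary_distance(binary.loc[sids]))
        coords = res.coordinates.iloc[:, :2].copy()
        coords.columns = [f"PCo{i+1}" for i in range(coords.shape[1])]
        coords.insert(0, "variety", v)
        pcoa_frames.append(coords)
    pcoa_coords = pd.concat(pcoa_frames)

    # --- quantitative peak-height tests ------------------------------------
    rows = []
    quant_results = {}
    for v, enzyme in itertools.product(varieties, enzymes):
        sids = meta.index[meta["variety"] == v]
        h = heights.loc[sids, enzyme] if enzyme in {c[0] for c in heights.columns} else None
        if h is None or h.shape[1] == 0:
            continue
        counts = h.T.round().astype(int)
        counts.index = [f"{enzyme}_{c:.1f}" for c in counts.index]
        tcm = TagCountMatrix(counts, meta.loc[sids])
        nbstats.normalize_tmm(tcm, config.trim_m, config.trim_a)
        conds = meta.loc[sids, "condition"]
        phi_c = nbstats.common_dispersion(tcm, conds)
        phi_t = nbstats.tagwise_dispersion(tcm, conds, phi_c, config.prior_n)
        res = nbstats.exact_test(
            tcm, conds, pair=("in_vitro", "field"), dispersion=phi_t, equalize_at=phi_c
        )
        quant_results[(v, enzyme)] = res
        rows.append(
            {"variety": v, "enzyme": enzyme,
             "n_significant": int((res["qvalue"] < config.fdr).sum())}
        )
    quant_summary = pd.DataFrame(rows)

    _write(condition_phipt, out / "msap_condition_phipt.csv", config, index=False)
    _write(tissue_phipt, out / "msap_tissue_phipt.csv", config, index=False)
    _write(averages.to_frame("average_phipt"), out / "msap_tissue_phipt_averages.csv", config)
    _write(diag, out / "msap_diagnostic_markers.csv", config)
    _write(pcoa_coords, out / "msap_pcoa_coordinates.csv", config)
    _write(quant_summary, out / "msap_quantitative_summary.csv", config, index=False)
    return {
        "binary": binary,
        "heights": heights,
        "condition_phipt": condition_phipt,
        "tissue_phipt": tissue_phipt,
        "tissue_averages": averages,
        "diagnostics": diag,
        "pcoa": pcoa_coords,
        "quantitative": quant_results,
        "quant_summary": quant_summary,
    }


def run_gbs_track(
    config: PipelineConfig,
    matrix: TagCountMatrix | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """msGBS track: demux -> filter -> per-variety tests -> consensus -> annotation.

    Inputs come from ``config`` paths (FASTQ + barcodes + genome + GFF); if
    absent, a scaled-down read simulation provides them. Passing ``matrix``
    skips demultiplexing and reruns the downstream stages identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    genome_path, gff_path = config.genome, config.gff
    truth = None
    if matrix is None:
        if config.fastq is None:
            sim = config.sim_config()
            meta = design_metadata(sim)
            fastq, barcodes, truth = simulate_gbs_reads(sim, out / "sim_reads", n_tags=sim.n_tags)
            genome_path = genome_path or str(out / "sim_reads" / "genome.fa")
            gff_path = gff_path or str(out / "sim_reads" / "genes.gff3")
        else:
            fastq, barcodes = config.fastq, config.barcodes
        bmap = gbs.BarcodeMap.from_tsv(barcodes)
        demux = gbs.demultiplex(fastq, bmap, tag_len=config.tag_len)
        demux.write_log(out / "gbs_demux_log.json")
        report["reads_in"] = demux.n_reads
        report["reads_retained"] = demux.n_retained
        raw = gbs.build_matrix(demux, meta)
        report["tags_pre_filter"] = int(raw.counts.shape[0])
        matrix = gbs.filter_matrix(
            raw, config.control_sample, min_samples=config.min_samples
        )
        report["tags_post_filter"] = int(matrix.counts.shape[0])
        # drop non-design samples (e.g. control placeholder rows)
        keep = [s for s in matrix.samples if matrix.meta.loc[s, "variety"] != "NA"]
        matrix = matrix.subset_samples(keep)

    results = dmr.per_variety_tests(matrix, prior_n=config.prior_n)
    dmrs = dmr.consensus_dmrs(
        results, fdr=config.fdr, min_varieties=config.min_varieties,
        require_observed=matrix,
    )
    summary = dmr.summarize_differential(
        results, dmrs, fdr=config.fdr, n_unique_tags=matrix.counts.shape[0]
    )

    annotations = None
    if genome_path and gff_path:
        genome = annotate.read_genome(genome_path)
        features = annotate.read_gff3(gff_path)
        cons = dmrs.consensus_tags
        # rows are 64-mer sequences after demux, opaque ids otherwise
        seq_to_id = (
            {s: t for t, s in truth.tag_sequences.items()} if truth is not None else {}
        )
        tag_seqs = {}
        for t in cons:
            s = str(t)
            if not set(s) - set("ACGT"):
                tag_seqs[seq_to_id.get(s, s)] = s
            elif truth is not None and s in truth.tag_sequences:
                tag_seqs[s] = truth.tag_sequences[s]
        hits = annotate.locate_tags(tag_seqs, genome)
        annotations = annotate.annotate_hits(hits, features, window=config.annotation_window)
        _write(annotations, out / "gbs_annotations.csv", config, index=False)
        annotate.write_bed6(hits, out / "gbs_hits.bed")

    _write(dmrs.table, out / "gbs_consensus_dmrs.csv", config)
    _write(summary, out / "gbs_differential_summary.csv", config)
    (out / "gbs_run_report.json").write_text(json.dumps(report, indent=2))
    return {
        "matrix": matrix,
        "per_variety": results,
        "dmrs": dmrs,
        "summary": summary,
        "annotations": annotations,
        "report": report,
        "truth": truth,
    }
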