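"""Synthetic data generator with planted, recorded ground truth.

Emulates the clonal-propagation study design: five cassava varieties
propagated either by field cuttings or by *in vitro* meristem culture,
sampled in three tissues with three replicate plants per cell (one
field-tissue cell of one variety missing by default, giving 87 samples).
Produces (a) MSAP peak tables for the HpaII/MspI isoschizomer pair driven
by planted per-locus methylation states, (b) negative-binomial msGBS tag
count matrices with planted condition-responsive tags (DMRs), (c) raw
msGBS reads carrying exact barcodes plus the 5'-CGG MspI cut-site remnant,
and (d) a toy genome with gene models for annotation. Every planted effect
is recorded in a :class:`GroundTruth` object so downstream stages can be
scored without re-inspecting the simulated data.

All generators are deterministic under a fixed ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS, TISSUES, PHASE_UP_FIELD, PHASE_UP_VITRO, TagCountMatrix, make_metadata
from .msap import (
    STATE_HEMI_EXTERNAL,
    STATE_HYPER_OR_ABSENT,
    STATE_INTERNAL,
    STATE_UNMETHYLATED,
)

DEFAULT_VARIETIES = ("Kiroba", "Kizimbani", "Kibandameno", "Mfaransa", "Mzungu")
CONTROL_SAMPLE = "water_control"

_STATES = (
    STATE_UNMETHYLATED,
    STATE_INTERNAL,
    STATE_HEMI_EXTERNAL,
    STATE_HYPER_OR_ABSENT,
)
# baseline mix of CCGG methylation states at an MSAP locus
_STATE_PROBS = (0.45, 0.25, 0.10, 0.20)

#: presence of a fragment given the site's methylation state
STATE_PRESENCE = {
    STATE_UNMETHYLATED: (1, 1),  # (HpaII, MspI)
    STATE_INTERNAL: (0, 1),
    STATE_HEMI_EXTERNAL: (1, 0),
    STATE_HYPER_OR_ABSENT: (0, 0),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study-design and noise parameters for all simulators.

    Defaults mirror the emulated experiment: 5 varieties x {field,
    in_vitro} x 3 tissues x 3 replicates with one missing field cell,
    160 MSAP loci, 2000 msGBS tags of which 40 are planted
    condition-responsive DMRs at |log2 fold-change| 3 with NB dispersion
    0.2 and 80k-120k reads per library.
    """

    n_varieties: int = 5
    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    conditions: tuple[str, ...] = CONDITIONS
    tissues: tuple[str, ...] = TISSUES
    n_replicates: int = 3
    missing_cells: tuple[tuple[str, str, str], ...] = (
        ("Mfaransa", "field", "mature_leaf"),
    )
    n_loci: int = 160
    frac_condition_loci: float = 0.15
    dropout: float = 0.02
    height_meanlog: float = 6.5
    height_sdlog: float = 0.4
    size_jitter: float = 0.05
    n_tags: int = 2000
    n_true_dmrs: int = 40
    dmr_varieties: int = 5
    prob_phase_field: float = 0.9
    effect_logfc: float = 3.0
    dispersion: float = 0.2
    lib_size_range: tuple[int, int] = (80_000, 120_000)
    barcode_length: int = 5
    tag_length: int = 64
    contaminant_fraction: float = 0.05
    n_control_tags: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_varieties", "n_replicates", "n_loci", "n_tags", "barcode_length", "tag_length"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.n_true_dmrs <= self.n_tags:
            raise ValueError("n_true_dmrs must lie in [0, n_tags]")
        if not 1 <= self.dmr_varieties <= self.n_varieties:
            raise ValueError("dmr_varieties must lie in [1, n_varieties]")
        if not 0 <= self.frac_condition_loci <= 1:
            raise ValueError("frac_condition_loci must lie in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if self.lib_size_range[0] < 1 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be an increasing pair of counts >= 1")
        if self.n_varieties > len(self.varieties):
            raise ValueError("varieties must name at least n_varieties labels")
        if self.effect_logfc < 0:
            raise ValueError("effect_logfc must be >= 0")

    def variety_labels(self) -> tuple[str, ...]:
        return tuple(self.varieties[: self.n_varieties])


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset (closed bookkeeping)."""

    true_dmr_ids: list[str] = field(default_factory=list)
    dmr_phase: dict[str, str] = field(default_factory=dict)
    dmr_varieties: dict[str, list[str]] = field(default_factory=dict)
    locus_states: pd.DataFrame | None = None  # locus x (variety, condition)
    locus_sizes: dict[str, float] = field(default_factory=dict)
    condition_loci: list[str] = field(default_factory=list)
    tag_sequences: dict[str, str] = field(default_factory=dict)
    planted_intervals: dict[str, tuple] = field(default_factory=dict)  # tag -> (chrom, start, end, strand)
    compartments: dict[str, tuple] = field(default_factory=dict)  # tag -> (gene|None, class, distance)
    clean_counts: pd.DataFrame | None = None  # expected retained tag x sample counts
    control_tags: list[str] = field(default_factory=list)
    contaminants: dict[str, int] = field(default_factory=dict)
    n_reads_total: int = 0

    def to_json(self, path) -> None:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, pd.DataFrame) and v is not None
        }
        for key in ("locus_states", "clean_counts"):
            df = getattr(self, key)
            if df is not None:
                payload[key] = {
                    "columns": [list(c) if isinstance(c, tuple) else c for c in df.columns],
                    "index": list(df.index),
                    "data": df.values.tolist(),
                }
        Path(path).write_text(json.dumps(payload, default=list, indent=0))


def design_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample metadata for the full design minus ``missing_cells``."""
    missing = {tuple(c) for c in config.missing_cells}
    rows = []
    for v in config.variety_labels():
        for c in config.conditions:
            for t in config.tissues:
                if (v, c, t) in missing:
                    continue
                for r in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{v}_{c}_{t}_r{r}",
                            "variety": v,
                            "condition": c,
                            "tissue": t,
                            "replicate": r,
                        }
                    )
    return make_metadata(rows)


# ---------------------------------------------------------------------------
# MSAP profiles
# ---------------------------------------------------------------------------


def simulate_msap_profiles(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Peak tables driven by planted per-locus methylation states.

    Returns ``(records, metadata, truth)`` where ``records`` is the tidy
    peak table (sample_id, enzyme, size_bp, height) covering every sample
    and both enzymes. Each locus has a fixed fragment size in [50, 600] bp;
    a per-(variety, condition) methylation state decides fragment presence
    under each enzyme; present peaks get lognormal heights, absent loci no
    peak at all, and a small dropout probability deletes otherwise-present
    peaks.
    """
    rng = np.random.default_rng([config.seed, 1])
    meta = design_metadata(config)
    varieties = config.variety_labels()
    locus_ids = [f"L{i:04d}" for i in range(1, config.n_loci + 1)]
    # sizes on a coarse grid so bins never collide at the default tolerance
    grid = np.arange(50.0, 600.0, 3.0)
    sizes = np.sort(rng.choice(grid, size=config.n_loci, replace=False))
    sizes = sizes + rng.uniform(-0.4, 0.4, size=config.n_loci)

    n_cond = int(round(config.frac_condition_loci * config.n_loci))
    cond_loci = sorted(rng.choice(config.n_loci, size=n_cond, replace=False).tolist())
    cond_set = set(cond_loci)

    cols = pd.MultiIndex.from_product(
        [varieties, config.conditions], names=["variety", "condition"]
    )
    states = pd.DataFrame(index=locus_ids, columns=cols, dtype=object)
    for li, locus in enumerate(locus_ids):
        base = rng.choice(_STATES, p=_STATE_PROBS)
        if li in cond_set:
            alt = rng.choice([s for s in _STATES if s != base])
        else:
            alt = base
        for v in varieties:
            states.loc[locus, (v, "field")] = base
            states.loc[locus, (v, "in_vitro")] = alt

    rows = []
    for sid, srow in meta.iterrows():
        for enzyme_idx, enzyme in enumerate(("HpaII", "MspI")):
            for li, locus in enumerate(locus_ids):
                state = states.loc[locus, (srow["variety"], srow["condition"])]
                present = STATE_PRESENCE[state][enzyme_idx]
                if not present or rng.random() < config.dropout:
                    continue
                rows.append(
                    {
                        "sample_id": sid,
                        "enzyme": enzyme,
                        "size_bp": sizes[li] + rng.normal(0.0, config.size_jitter),
                        "height": float(
                            rng.lognormal(config.height_meanlog, config.height_sdlog)
                        ),
                    }
                )
    records = pd.DataFrame(rows, columns=["sample_id", "enzyme", "size_bp", "height"])
    truth = GroundTruth(
        locus_states=states,
        locus_sizes=dict(zip(locus_ids, sizes.tolist())),
        condition_loci=[locus_ids[i] for i in cond_loci],
    )
    return records, meta, truth


# ---------------------------------------------------------------------------
# msGBS tag counts
# ---------------------------------------------------------------------------


def simulate_tag_counts(
    config: SimConfig,
    meta: pd.DataFrame | None = None,
    tag_ids: list[str] | None = None,
) -> tuple[TagCountMatrix, GroundTruth]:
    """Negative-binomial tag x sample counts with planted DMRs.

    Counts are NB with mean ``lib_size * relative_abundance * effect`` and
    the configured dispersion (Poisson at dispersion 0). Planted DMR tags
    receive a symmetric split of ``effect_logfc`` between conditions (so
    group means separate by ``2**effect_logfc``) with the same phase in
    ``dmr_varieties`` varieties; non-DMR tags have no condition effect.
    """
    rng = np.random.default_rng([config.seed, 2])
    if meta is None:
        meta = design_metadata(config)
    if tag_ids is None:
        tag_ids = [f"tag{i:05d}" for i in range(1, config.n_tags + 1)]
    n_tags = len(tag_ids)
    varieties = config.variety_labels()

    rel = rng.lognormal(0.0, 1.0, size=n_tags)
    rel /= rel.sum()
    lib = rng.uniform(*config.lib_size_range, size=len(meta))

    dmr_idx = rng.choice(n_tags, size=config.n_true_dmrs, replace=False)
    phases = np.where(
        rng.random(config.n_true_dmrs) < config.prob_phase_field,
        PHASE_UP_FIELD,
        PHASE_UP_VITRO,
    )
    affected = {
        int(i): sorted(
            rng.choice(len(varieties), size=config.dmr_varieties, replace=False).tolist()
        )
        for i in dmr_idx
    }

    half = 0.5 * config.effect_logfc
    log_effect = np.zeros((n_tags, len(meta)))
    cond_is_field = (meta["condition"] == "field").to_numpy()
    var_codes = meta["variety"].map({v: k for k, v in enumerate(varieties)}).to_numpy()
    for i, phase in zip(dmr_idx, phases):
        in_aff = np.isin(var_codes, affected[int(i)])
        sign = 1.0 if phase == PHASE_UP_FIELD else -1.0
        log_effect[i, in_aff & cond_is_field] = sign * half
        log_effect[i, in_aff & ~cond_is_field] = -sign * half

    mu = rel[:, None] * lib[None, :] * 2.0 ** log_effect
    if config.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(tag_ids, name="tag"), columns=meta.index)
    truth = GroundTruth(
        true_dmr_ids=[tag_ids[int(i)] for i in dmr_idx],
        dmr_phase={tag_ids[int(i)]: str(p) for i, p in zip(dmr_idx, phases)},
        dmr_varieties={
            tag_ids[int(i)]: [varieties[j] for j in affected[int(i)]] for i in dmr_idx
        },
    )
    return TagCountMatrix(counts_df, meta), truth


# ---------------------------------------------------------------------------
# Toy genome + gene models
# ---------------------------------------------------------------------------

_COMPARTMENT_CYCLE = ("exon", "intron", "upstream_5kb", "downstream_5kb", "intergenic")


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame  # gff-like gene/exon table, 0-based half-open
    fasta_path: Path | None = None
    gff_path: Path | None = None


def simulate_toy_genome(
    config: SimConfig,
    n_tags: int | None = None,
    n_genes: int = 20,
    out_dir: Path | str | None = None,
) -> tuple[ToyGenome, GroundTruth]:
    """Random genome with non-overlapping genes and planted tag sites.

    Genes carry 2-3 exons separated by introns; tags are planted cycling
    through compartments (exon, intron, <=5 kb upstream of the TSS, <=5 kb
    downstream of the TTS, intergenic), alternating strand, each site
    beginning with the CGG MspI remnant. The planted compartment, gene and
    distance are recorded in the returned ground truth.
    """
    rng = np.random.default_rng([config.seed, 3])
    if n_tags is None:
        n_tags = config.n_tags
    tag_len = config.tag_length
    spacing = 14_000  # gene start-to-start; leaves >5 kb flanks + intergenic room
    chrom = "chr1"
    length = spacing * n_genes + 20_000
    seq = rng.choice(list("ACGT"), size=length)

    gene_rows = []
    exon_rows = []
    for gi in range(n_genes):
        gstart = 8_000 + gi * spacing
        strand = "+" if gi % 2 == 0 else "-"
        exon_lens = rng.integers(200, 400, size=3)
        intron_lens = rng.integers(300, 600, size=2)
        pos = gstart
        exons = []
        for k in range(3):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < 2:
                pos += int(intron_lens[k])
        gene_id = f"gene{gi + 1:03d}"
        gene_rows.append(
            {"gene_id": gene_id, "chrom": chrom, "start": gstart, "end": pos, "strand": strand}
        )
        for k, (es, ee) in enumerate(exons, 1):
            exon_rows.append(
                {"gene_id": gene_id, "exon": k, "chrom": chrom, "start": es, "end": ee, "strand": strand}
            )
    genes = pd.DataFrame(gene_rows)
    exons_df = pd.DataFrame(exon_rows)

    truth = GroundTruth()
    used: list[tuple[int, int]] = []

    def free(start: int) -> bool:
        end = start + tag_len
        if start < 0 or end > length:
            return False
        return all(end <= s or start >= e for s, e in used)

    tag_ids = [f"tag{i:05d}" for i in range(1, n_tags + 1)]
    placed = 0
    for ti, tag in enumerate(tag_ids):
        compartment = _COMPARTMENT_CYCLE[ti % len(_COMPARTMENT_CYCLE)]
        gi = ti % n_genes
        g = genes.iloc[gi]
        ex = exons_df[exons_df["gene_id"] == g["gene_id"]]
        start = None
        for _ in range(50):
            if compartment == "exon":
                row = ex.iloc[int(rng.integers(len(ex)))]
                cand = int(rng.integers(row["start"], max(row["start"] + 1, row["end"] - tag_len)))
                dist = 0
            elif compartment == "intron":
                # between exon1 and exon2
                lo = int(ex.iloc[0]["end"]) + 5
                hi = int(ex.iloc[1]["start"]) - tag_len - 5
                if hi <= lo:
                    break
                cand = int(rng.integers(lo, hi))
                dist = 0
            elif compartment == "upstream_5kb":
                gap = int(rng.integers(1, 5001 - tag_len))
                if g["strand"] == "+":
                    cand = int(g["start"]) - gap - tag_len
                else:
                    cand = int(g["end"]) + gap
                dist = gap
            elif compartment == "downstream_5kb":
                gap = int(rng.integers(1, 5001 - tag_len))
                if g["strand"] == "+":
                    cand = int(g["end"]) + gap
                else:
                    cand = int(g["start"]) - gap - tag_len
                dist = gap
            else:  # intergenic: far from every gene (> 5 kb from any flank)
                cand = int(g["start"]) - 7_000 + int(rng.integers(0, 800))
                dist = -1
            if free(cand):
                start = cand
                break
        if start is None:
            continue
        strand = "+" if ti % 2 == 0 else "-"
        tag_seq = "CGG" + "".join(rng.choice(list("ACGT"), size=tag_len - 3))
        sub = tag_seq if strand == "+" else revcomp(tag_seq)
        seq[start : start + tag_len] = list(sub)
        used.append((start, start + tag_len))
        truth.tag_sequences[tag] = tag_seq
        truth.planted_intervals[tag] = (chrom, start, start + tag_len, strand)
        gene_for = None if compartment == "intergenic" else str(g["gene_id"])
        truth.compartments[tag] = (gene_for, compartment, dist if dist >= 0 else None)
        placed += 1
    if placed < n_tags:
        raise RuntimeError(f"could only place {placed} of {n_tags} tags without overlap")

    genome = ToyGenome(sequences={chrom: "".join(seq)}, genes=_gff_table(genes, exons_df))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.fasta_path = out / "genome.fa"
        genome.gff_path = out / "genes.gff3"
        write_fasta(genome.sequences, genome.fasta_path)
        write_gff3(genome.genes, genome.gff_path)
    return genome, truth


def _gff_table(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Feature table (0-based half-open) with gene/mRNA/exon rows."""
    rows = []
    for _, g in genes.iterrows():
        rows.append(
            {"chrom": g["chrom"], "type": "gene", "start": g["start"], "end": g["end"],
             "strand": g["strand"], "id": g["gene_id"], "parent": None}
        )
        rows.append(
            {"chrom": g["chrom"], "type": "mRNA", "start": g["start"], "end": g["end"],
             "strand": g["strand"], "id": g["gene_id"] + ".1", "parent": g["gene_id"]}
        )
    for _, e in exons.iterrows():
        rows.append(
            {"chrom": e["chrom"], "type": "exon", "start": e["start"], "end": e["end"],
             "strand": e["strand"], "id": f'{e["gene_id"]}.exon{e["exon"]}',
             "parent": e["gene_id"] + ".1"}
        )
    return pd.DataFrame(rows)


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write the 0-based half-open feature table as 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, f in features.iterrows():
            attrs = f"ID={f['id']}"
            if f["parent"]:
                attrs += f";Parent={f['parent']}"
            fh.write(
                "\t".join(
                    [
                        str(f["chrom"]), "epifidelity_sim", str(f["type"]),
                        str(int(f["start"]) + 1), str(int(f["end"])),
                        ".", str(f["strand"]), ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# msGBS reads
# ---------------------------------------------------------------------------


def simulate_gbs_reads(
    config: SimConfig,
    out_dir: Path | str,
    n_tags: int | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[Path, Path, GroundTruth]:
    """FASTQ reads + barcode map with planted composition and contaminants.

    Each clean read is ``barcode + CGG + tag body`` where the 64 nt tag
    (CGG included) was planted in the toy genome; per-sample tag counts
    follow the NB model of :func:`simulate_tag_counts` scaled to small
    libraries. A ``contaminant_fraction`` of reads carries either a
    corrupted barcode or a corrupted cut-site; a few control-only tags are
    planted in the negative water control plus some real samples to
    exercise the control filter. Returns (fastq_path, barcode_path, truth).
    """
    rng = np.random.default_rng([config.seed, 4])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if meta is None:
        meta = design_metadata(config)
    if n_tags is None:
        n_tags = config.n_tags

    genome, truth = simulate_toy_genome(config, n_tags=n_tags, out_dir=out)
    tag_ids = sorted(truth.tag_sequences)
    counts_m, count_truth = simulate_tag_counts(config, meta=meta, tag_ids=tag_ids)
    truth.true_dmr_ids = count_truth.true_dmr_ids
    truth.dmr_phase = count_truth.dmr_phase
    truth.dmr_varieties = count_truth.dmr_varieties

    samples = list(meta.index) + [CONTROL_SAMPLE]
    barcodes = _prefix_free_barcodes(rng, len(samples), config.barcode_length)
    bmap = pd.DataFrame({"barcode": barcodes, "sample_id": samples})
    bc_of = dict(zip(bmap["sample_id"], bmap["barcode"]))

    # control-only tags: present in the water control and a couple of samples
    control_tags = [f"ctl{i:03d}" for i in range(1, config.n_control_tags + 1)]
    for ct in control_tags:
        truth.tag_sequences[ct] = "CGG" + "".join(
            rng.choice(list("ACGT"), size=config.tag_length - 3)
        )
    truth.control_tags = control_tags

    counts = counts_m.counts
    clean = counts.copy()
    reads: list[tuple[str, str]] = []
    for sid in counts.columns:
        bc = bc_of[sid]
        for tag, k in counts[sid].items():
            if k > 0:
                reads.extend((f"{sid}:{tag}", bc + truth.tag_sequences[tag]) for _ in range(int(k)))
    # control-tag reads: water control + the first two real samples
    ctl_recipients = [CONTROL_SAMPLE] + list(counts.columns[:2])
    for ct in control_tags:
        for sid in ctl_recipients:
            for _ in range(3):
                reads.append((f"{sid}:{ct}", bc_of[sid] + truth.tag_sequences[ct]))

    n_clean = len(reads)
    n_contam = int(round(config.contaminant_fraction / max(1e-12, 1 - config.contaminant_fraction) * n_clean))
    valid_bc = set(bmap["barcode"])
    contam_log = {"bad_barcode": 0, "bad_cutsite": 0}
    body = lambda: "".join(rng.choice(list("ACGT"), size=config.tag_length - 3))
    for _ in range(n_contam):
        sid = samples[int(rng.integers(len(samples)))]
        bc = bc_of[sid]
        if rng.random() < 0.5:
            mutated = _mutate_barcode(rng, bc, valid_bc)
            reads.append(("contam:bad_barcode", mutated + "CGG" + body()))
            contam_log["bad_barcode"] += 1
        else:
            reads.append(("contam:bad_cutsite", bc + "CGA" + body()))
            contam_log["bad_cutsite"] += 1
    truth.contaminants = contam_log
    truth.n_reads_total = len(reads)
    truth.clean_counts = clean

    order = rng.permutation(len(reads))
    fastq_path = out / "reads.fastq"
    with open(fastq_path, "w") as fh:
        for n, i in enumerate(order):
            name, seq = reads[i]
            fh.write(f"@read{n:07d} {name}\n{seq}\n+\n{'I' * len(seq)}\n")
    bmap_path = out / "barcodes.tsv"
    bmap.to_csv(bmap_path, sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    return fastq_path, bmap_path, truth


def _prefix_free_barcodes(rng, n: int, length: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(rng.choice(list("ACGT"), size=length)))
    return sorted(out)[:n] if len(out) == n else sorted(out)


def _mutate_barcode(rng, bc: str, valid: set[str]) -> str:
    for _ in range(100):
        pos = int(rng.integers(len(bc)))
        alt = rng.choice([b for b in "ACGT" if b != bc[pos]])
        cand = bc[:pos] + alt + bc[pos + 1 :]
        if cand not in valid:
            return cand
    raise RuntimeError("could not mutate barcode away from the valid set")
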