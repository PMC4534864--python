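"""Placement of consensus tags on a genome and gene-window classification.

Tags (64-mers) are located by exact match of the sequence and its reverse
complement — at this length an exact hit is an effectively unambiguous
alignment — and each hit is classified against gene models: exon overlap,
intron (gene-body overlap without exon), within 5 kb upstream of the
strand-aware transcription start site, within 5 kb downstream of the
transcription termination site, or intergenic. An adapter accepts an
externally produced hit table (e.g. from BLAST) in place of exact search.
"""

from __future__ import annotations

import warnings

import pandas as pd
from Bio import SeqIO

from .simulate import revcomp

WINDOW = 5000  # bp, inclusive at the boundary

FEATURE_CLASSES = ("exon", "intron", "upstream_5kb", "downstream_5kb", "intergenic")


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_tags_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path) -> pd.DataFrame:
    """GFF3 gene/mRNA/exon features as a 0-based half-open table.

    GFF3 is 1-based inclusive on disk; starts are shifted by -1 here.
    Records with end < start are rejected and logged with a warning
    before the remainder is parsed with :mod:`gffutils`.
    """
    import gffutils

    kept_lines = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                kept_lines.append(line)
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                warnings.warn(f"malformed GFF line skipped: {line[:60]!r}")
                continue
            if int(parts[4]) < int(parts[3]):
                warnings.warn(f"GFF record with end < start rejected: {line[:60]!r}")
                continue
            kept_lines.append(line)
    db = gffutils.create_db(
        "".join(kept_lines), ":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for f in db.all_features():
        rows.append(
            {
                "chrom": f.seqid,
                "type": f.featuretype,
                "start": f.start - 1,
                "end": f.end,
                "strand": f.strand,
                "id": f.attributes.get("ID", [f.id])[0],
                "parent": f.attributes.get("Parent", [None])[0],
            }
        )
    return pd.DataFrame(rows)


def to_gff3_coords(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def from_gff3_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def locate_tags(tags: dict[str, str], genome: dict[str, str]) -> pd.DataFrame:
    """All exact occurrences of each tag and its reverse complement.

    Returns a hit table (tag, chrom, start, end, strand, match_type,
    multi_hit) in 0-based half-open coordinates. Tags containing
    ambiguity codes are skipped with a warning.
    """
    rows = []
    for tag_id in sorted(tags):
        seq = tags[tag_id].upper()
        if set(seq) - set("ACGT"):
            warnings.warn(f"tag {tag_id!r} contains ambiguity codes; skipped")
            continue
        queries = [(seq, "+", "exact_forward")]
        rc = revcomp(seq)
        if rc != seq:
            queries.append((rc, "-", "exact_revcomp"))
        tag_rows = []
        for query, strand, match_type in queries:
            for chrom, chrom_seq in genome.items():
                pos = chrom_seq.find(query)
                while pos != -1:
                    tag_rows.append(
                        {
                            "tag": tag_id,
                            "chrom": chrom,
                            "start": pos,
                            "end": pos + len(query),
                            "strand": strand,
                            "match_type": match_type,
                        }
                    )
                    pos = chrom_seq.find(query, pos + 1)
        for r in tag_rows:
            r["multi_hit"] = len(tag_rows) > 1
        rows.extend(tag_rows)
    cols = ["tag", "chrom", "start", "end", "strand", "match_type", "multi_hit"]
    return pd.DataFrame(rows, columns=cols)


def load_external_hits(path) -> pd.DataFrame:
    """Adapter for a user-supplied hit table (tag, chrom, start, end, strand)."""
    df = pd.read_csv(path)
    required = {"tag", "chrom", "start", "end", "strand"}
    if missing := required - set(df.columns):
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    df["match_type"] = df.get("match_type", "external")
    df["multi_hit"] = df["tag"].duplicated(keep=False)
    return df


def _gene_models(features: pd.DataFrame) -> list[dict]:
    """Collapse a feature table into per-gene records with exon lists."""
    genes = features[features["type"] == "gene"]
    mrna_parent = dict(
        zip(
            features.loc[features["type"] == "mRNA", "id"],
            features.loc[features["type"] == "mRNA", "parent"],
        )
    )
    models = []
    for _, g in genes.iterrows():
        exons = []
        for _, e in features[features["type"] == "exon"].iterrows():
            parent_gene = mrna_parent.get(e["parent"], e["parent"])
            if parent_gene == g["id"]:
                exons.append((int(e["start"]), int(e["end"])))
        models.append(
            {
                "gene_id": g["id"],
                "chrom": g["chrom"],
                "start": int(g["start"]),
                "end": int(g["end"]),
                "strand": g["strand"],
                "exons": sorted(exons),
            }
        )
    return models


def _classify_against_gene(hs: int, he: int, gene: dict) -> tuple[str, int] | None:
    """(feature_class, distance) of a hit relative to one gene, or None."""
    gs, ge = gene["start"], gene["end"]
    if hs < ge and gs < he:  # gene-body overlap
        in_exon = any(hs < ee and es < he for es, ee in gene["exons"])
        return ("exon" if in_exon else "intron"), 0
    if he <= gs:
        gap = gs - he
        side = "upstream_5kb" if gene["strand"] == "+" else "downstream_5kb"
    else:
        gap = hs - ge
        side = "downstream_5kb" if gene["strand"] == "+" else "upstream_5kb"
    if gap <= WINDOW:
        return side, gap
    return None


_CLASS_RANK = {c: i for i, c in enumerate(FEATURE_CLASSES)}


def annotate_hits(
    hits: pd.DataFrame, features: pd.DataFrame, window: int = WINDOW
) -> pd.DataFrame:
    """Classify each hit against gene models within the flanking window.

    The nearest qualifying gene wins; ties break by smaller distance, then
    gene-body over flank, then lexicographic gene id. Hits with no gene
    within the window are ``intergenic``.
    """
    models = _gene_models(features)
    rows = []
    for _, h in hits.iterrows():
        candidates = []
        for gene in models:
            if gene["chrom"] != h["chrom"]:
                continue
            res = _classify_against_gene(int(h["start"]), int(h["end"]), gene)
            if res is not None:
                cls, dist = res
                if dist <= window:
                    candidates.append((dist, _CLASS_RANK[cls], str(gene["gene_id"]), cls))
        if candidates:
            dist, _, gene_id, cls = min(candidates)
            rows.append(
                {"tag": h["tag"], "chrom": h["chrom"], "start": h["start"], "end": h["end"],
                 "strand": h["strand"], "gene_id": gene_id, "feature_class": cls,
                 "distance": dist}
            )
        else:
            rows.append(
                {"tag": h["tag"], "chrom": h["chrom"], "start": h["start"], "end": h["end"],
                 "strand": h["strand"], "gene_id": None, "feature_class": "intergenic",
                 "distance": None}
            )
    cols = ["tag", "chrom", "start", "end", "strand", "gene_id", "feature_class", "distance"]
    return pd.DataFrame(rows, columns=cols)


def write_bed6(hits: pd.DataFrame, path) -> None:
    """Hits as BED6 (0-based half-open, name=tag, score=0)."""
    with open(path, "w") as fh:
        for _, h in hits.iterrows():
            fh.write(
                f'{h["chrom"]}\t{int(h["start"])}\t{int(h["end"])}\t{h["tag"]}\t0\t{h["strand"]}\n'
            )
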