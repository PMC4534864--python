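"""msGBS read processing: demultiplex -> tag x sample matrix -> filters.

A retained read must begin with one of the exact sample barcodes followed
immediately by the CGG remnant of the MspI cut site; the barcode is
stripped and the remainder truncated to the configured tag length (64 nt,
CGG included). Tags seen in the negative water control are discarded, and
only tags observed in at least three different samples are kept.
"""

from __future__ import annotations

import gzip
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .datatypes import TagCountMatrix

CUTSITE = "CGG"


@dataclass
class BarcodeMap:
    """Barcode -> sample map; barcodes must be unique and prefix-free."""

    table: pd.DataFrame  # columns: barcode, sample_id

    def __post_init__(self) -> None:
        barcodes = self.table["barcode"].tolist()
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in map")
        if len(set(self.table["sample_id"])) != len(self.table):
            raise ValueError("duplicate sample ids in map")
        for a in barcodes:
            for b in barcodes:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a!r} is a prefix of {b!r}")
        self._lookup = dict(zip(self.table["barcode"], self.table["sample_id"]))
        self._lengths = sorted({len(b) for b in barcodes})

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def assign(self, read: str) -> tuple[str, str] | None:
        """(sample_id, barcode) if the read starts with a known barcode."""
        for ln in self._lengths:
            sid = self._lookup.get(read[:ln])
            if sid is not None:
                return sid, read[:ln]
        return None


@dataclass
class DemuxResult:
    """Per-sample tag counters plus the rejection log."""

    streams: dict[str, Counter] = field(default_factory=dict)
    rejected: dict[str, int] = field(
        default_factory=lambda: {"bad_barcode": 0, "bad_cutsite": 0, "too_short": 0}
    )
    n_reads: int = 0

    @property
    def n_retained(self) -> int:
        return sum(sum(c.values()) for c in self.streams.values())

    def write_log(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"n_reads": self.n_reads, "retained": self.n_retained, "rejected": self.rejected},
                indent=2,
            )
        )


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def demultiplex(fastq_path, barcode_map: BarcodeMap, tag_len: int = 64) -> DemuxResult:
    """Assign reads to samples by exact barcode + CGG cut-site match.

    A read is assigned to sample ``s`` iff it begins with ``s``'s exact
    barcode immediately followed by ``CGG``; the barcode is removed and the
    remainder truncated to ``tag_len`` (so every tag begins with CGG).
    Reads shorter than ``tag_len`` after barcode removal are rejected.
    The rejection log counts ``bad_barcode``, ``bad_cutsite``,
    ``too_short``; retained + rejected always equals the read count.
    """
    result = DemuxResult(streams={sid: Counter() for sid in barcode_map.table["sample_id"]})
    with _open_maybe_gzip(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seq = str(rec.seq).upper()
            result.n_reads += 1
            hit = barcode_map.assign(seq)
            if hit is None:
                result.rejected["bad_barcode"] += 1
                continue
            sid, bc = hit
            rest = seq[len(bc) :]
            if not rest.startswith(CUTSITE):
                result.rejected["bad_cutsite"] += 1
                continue
            if len(rest) < tag_len:
                result.rejected["too_short"] += 1
                continue
            result.streams[sid][rest[:tag_len]] += 1
    return result


def build_matrix(demux: DemuxResult, meta: pd.DataFrame | None = None) -> TagCountMatrix:
    """Tag x sample count matrix from demultiplexed streams.

    Rows are the distinct tag sequences in lexicographic order; samples
    follow the barcode-map order. Samples absent from ``meta`` (e.g. the
    water control) get placeholder metadata rows.
    """
    samples = list(demux.streams)
    tags = sorted(set().union(*[c.keys() for c in demux.streams.values()]) if samples else [])
    counts = pd.DataFrame(0, index=pd.Index(tags, name="tag"), columns=samples, dtype=int)
    for sid, counter in demux.streams.items():
        for tag, k in counter.items():
            counts.loc[tag, sid] = k
    if meta is None:
        meta = pd.DataFrame(
            {"variety": "NA", "condition": "field", "tissue": "young_leaf", "replicate": 0},
            index=pd.Index(samples, name="sample_id"),
        )
    else:
        missing = [s for s in samples if s not in meta.index]
        if missing:
            filler = pd.DataFrame(
                {"variety": "NA", "condition": "field", "tissue": "young_leaf", "replicate": 0},
                index=pd.Index(missing, name="sample_id"),
            )
            meta = pd.concat([meta, filler])
    return TagCountMatrix(counts, meta)


def filter_matrix(
    m: TagCountMatrix,
    negative_control_sample: str | None,
    min_samples: int = 3,
    control_first: bool = True,
) -> TagCountMatrix:
    """Apply the control filter then the >= min_samples presence filter.

    Tags with any count in the negative control are dropped, then tags
    with nonzero counts in fewer than ``min_samples`` non-control samples
    are dropped; the control column is removed from the output. With
    ``control_first=False`` the presence filter is applied before control
    removal.
    """
    counts = m.counts
    if negative_control_sample is not None and negative_control_sample not in counts.columns:
        warnings.warn(
            f"control sample {negative_control_sample!r} not in matrix; control filter skipped"
        )
        negative_control_sample = None

    def control_filter(c: pd.DataFrame) -> pd.DataFrame:
        if negative_control_sample is None:
            return c
        return c.loc[c[negative_control_sample] == 0]

    def presence_filter(c: pd.DataFrame) -> pd.DataFrame:
        data_cols = [s for s in c.columns if s != negative_control_sample]
        n_present = (c[data_cols] > 0).sum(axis=1)
        return c.loc[n_present >= min_samples]

    if control_first:
        counts = presence_filter(control_filter(counts))
    else:
        counts = control_filter(presence_filter(counts))
    data_cols = [s for s in counts.columns if s != negative_control_sample]
    meta = m.meta.loc[[s for s in data_cols]]
    return TagCountMatrix(counts[data_cols].copy(), meta)


def write_mtx(m: TagCountMatrix, prefix: Path | str) -> None:
    """Write counts as MatrixMarket with tag-FASTA and sample sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", csr_matrix(m.counts.to_numpy()))
    with open(str(prefix) + ".tags.fa", "w") as fh:
        for i, tag in enumerate(m.counts.index, 1):
            fh.write(f">tag{i:06d}\n{tag}\n")
    pd.Series(m.counts.columns).to_csv(str(prefix) + ".samples.txt", index=False, header=False)
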