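"""MSAP profile processing: peaks -> epilocus matrices -> methylation calls.

MSAP digests genomic DNA with EcoRI plus one of the isoschizomers HpaII or
MspI, which share the CCGG recognition motif but differ in methylation
sensitivity: both cut unmethylated CCGG; MspI also cuts when the internal
cytosine is methylated (CmCGG) but not when the external cytosine is
(hemi-)methylated; HpaII tolerates hemi-methylation of the external
cytosine but not full or internal methylation. Comparing the presence of a
fragment across the two enzyme profiles therefore reads out the
methylation state of its CCGG site, and a marker polymorphic in only one
enzyme's profile can only be epigenetic in origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


QUALITATIVE_WINDOW = (100.0, 580.0)  # bp, inclusive; limits size homoplasy
QUANTITATIVE_WINDOW = (50.0, 550.0)  # bp, inclusive

STATE_UNMETHYLATED = "unmethylated"
STATE_INTERNAL = "internal_mC"
STATE_HEMI_EXTERNAL = "hemi_external_mC"
STATE_HYPER_OR_ABSENT = "hypermethylated_or_absent"

#: (HpaII presence, MspI presence) -> methylation state of the CCGG site
METHYLATION_STATES = {
    (1, 1): STATE_UNMETHYLATED,
    (0, 1): STATE_INTERNAL,
    (1, 0): STATE_HEMI_EXTERNAL,
    (0, 0): STATE_HYPER_OR_ABSENT,
}

PEAK_COLUMNS = ("sample_id", "enzyme", "size_bp", "height")


@dataclass
class LocusCatalog:
    """Per-enzyme fragment-size bins produced by :func:`bin_peaks`."""

    centers: dict[str, np.ndarray] = field(default_factory=dict)
    tolerance: float = 0.5

    def enzymes(self) -> list[str]:
        return list(self.centers)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if (records["size_bp"] <= 0).any():
        raise ValueError("size_bp must be positive")
    if (records["height"] < 0).any():
        raise ValueError("height must be non-negative")
    return records


def bin_peaks(records: pd.DataFrame, tolerance_bp: float = 0.5) -> LocusCatalog:
    """Cluster fragment sizes into loci per enzyme (single linkage).

    Peaks are merged into a bin while consecutive sizes are within
    ``tolerance_bp``; two peaks from the same sample never share a bin —
    the taller keeps its place and the other seeds/joins the next bin.
    Bin centers are the mean member size, reported in ascending order.
    """
    if tolerance_bp <= 0:
        raise ValueError("tolerance_bp must be > 0")
    if len(records) == 0:
        return LocusCatalog(centers={}, tolerance=tolerance_bp)
    records = _validate_records(records)
    centers: dict[str, np.ndarray] = {}
    for enzyme, sub in records.groupby("enzyme", sort=True):
        peaks = sub.sort_values(["size_bp", "height"], kind="mergesort")
        sizes = peaks["size_bp"].to_numpy(dtype=float)
        heights = peaks["height"].to_numpy(dtype=float)
        samples = peaks["sample_id"].to_numpy()
        bins: list[list[int]] = []
        current: list[int] = []
        by_sample: dict = {}
        carry: list[int] = []  # displaced peaks waiting for the next bin

        def add_to_current(i: int) -> None:
            sid = samples[i]
            if sid in by_sample:
                j = by_sample[sid]
                if heights[i] > heights[j]:
                    current.remove(j)
                    current.append(i)
                    by_sample[sid] = i
                    carry.append(j)
                else:
                    carry.append(i)
            else:
                current.append(i)
                by_sample[sid] = i

        def open_new_bin() -> None:
            nonlocal current, by_sample, carry
            if current:
                bins.append(current)
            current, by_sample = [], {}
            waiting, carry = carry, []
            for j in waiting:
                add_to_current(j)

        for i in range(sizes.size):
            if current and sizes[i] - sizes[current[-1]] > tolerance_bp:
                open_new_bin()
            add_to_current(i)
        while current or carry:
            open_new_bin()
        ctr = np.array(sorted(float(np.mean(sizes[b])) for b in bins))
        centers[enzyme] = ctr
    return LocusCatalog(centers=centers, tolerance=tolerance_bp)


def _assign_bins(sizes: np.ndarray, centers: np.ndarray, tolerance: float) -> np.ndarray:
    """Index of the nearest catalog bin for each size, -1 when out of reach."""
    if centers.size == 0:
        return np.full(sizes.size, -1)
    idx = np.searchsorted(centers, sizes)
    idx = np.clip(idx, 0, centers.size - 1)
    left = np.clip(idx - 1, 0, centers.size - 1)
    pick = np.where(
        np.abs(centers[left] - sizes) <= np.abs(centers[idx] - sizes), left, idx
    )
    ok = np.abs(centers[pick] - sizes) <= tolerance + 1e-9
    return np.where(ok, pick, -1)


def _pivot(
    records: pd.DataFrame,
    catalog: LocusCatalog,
    size_window: tuple[float, float],
    samples: list | None,
    aggregate: str,
) -> pd.DataFrame:
    """Sample x (enzyme, bin-center) matrix of summed heights in a window."""
    records = _validate_records(records)
    if samples is None:
        samples = sorted(records["sample_id"].unique())
    else:
        absent = sorted(set(samples) - set(records["sample_id"]))
        if absent:
            warnings.warn(f"samples without peaks scored as absent: {absent}")
    lo, hi = size_window
    cols: list[tuple[str, float]] = []
    blocks: list[np.ndarray] = []
    sample_pos = {s: i for i, s in enumerate(samples)}
    for enzyme in catalog.enzymes():
        centers = catalog.centers[enzyme]
        keep = (centers >= lo) & (centers <= hi)
        kept_idx = {int(i): j for j, i in enumerate(np.flatnonzero(keep))}
        block = np.zeros((len(samples), int(keep.sum())))
        sub = records[records["enzyme"] == enzyme]
        assign = _assign_bins(
            sub["size_bp"].to_numpy(dtype=float), centers, catalog.tolerance
        )
        for (sid, h), b in zip(sub[["sample_id", "height"]].itertuples(index=False), assign):
            if b < 0 or int(b) not in kept_idx or sid not in sample_pos:
                continue
            block[sample_pos[sid], kept_idx[int(b)]] += h
        cols.extend((enzyme, float(c)) for c in centers[keep])
        blocks.append(block)
    if blocks:
        data = np.hstack(blocks)
    else:
        data = np.zeros((len(samples), 0))
    columns = pd.MultiIndex.from_tuples(cols, names=["enzyme", "size_bp"])
    out = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"), columns=columns)
    if aggregate == "binary":
        return out
    return out


def score_binary(
    records: pd.DataFrame,
    catalog: LocusCatalog,
    size_window: tuple[float, float] = QUALITATIVE_WINDOW,
    presence_threshold: float = 0.0,
    samples: list | None = None,
) -> pd.DataFrame:
    """Presence/absence (1/0) epilocus matrix.

    A cell is 1 iff the sample has at least one peak in the bin with
    height strictly above ``presence_threshold``; loci whose bin center
    falls outside the closed ``size_window`` are dropped.
    """
    heights = _pivot(records, catalog, size_window, samples, aggregate="binary")
    return (heights > presence_threshold).astype(np.int8)


def build_height_matrix(
    records: pd.DataFrame,
    catalog: LocusCatalog,
    size_window: tuple[float, float] = QUANTITATIVE_WINDOW,
    low_filter: tuple[str, float] = ("mean", 0.0),
    samples: list | None = None,
) -> pd.DataFrame:
    """Summed peak-height matrix with a low-intensity locus filter.

    ``low_filter`` is ``(mode, threshold)`` with mode ``"mean"`` or
    ``"total"``: loci whose mean (or total) height across all samples falls
    below the threshold are removed.
    """
    mode, thr = low_filter
    if mode not in ("mean", "total"):
        raise ValueError("low_filter mode must be 'mean' or 'total'")
    heights = _pivot(records, catalog, size_window, samples, aggregate="sum")
    stat = heights.mean(axis=0) if mode == "mean" else heights.sum(axis=0)
    if thr > 0:
        heights = heights.loc[:, (stat >= thr).to_numpy()]
    return heights


def match_loci(
    hpa: pd.DataFrame, msp: pd.DataFrame, tolerance: float = 0.5
) -> list[tuple[float | None, float | None]]:
    """Pair HpaII and MspI loci by bin center within ``tolerance``.

    Greedy nearest-neighbour matching over ascending size; unmatched
    centers appear with ``None`` on the other side.
    """
    hc = sorted(c for e, c in hpa.columns if e == "HpaII")
    mc = sorted(c for e, c in msp.columns if e == "MspI")
    pairs: list[tuple[float | None, float | None]] = []
    i = j = 0
    while i < len(hc) and j < len(mc):
        if abs(hc[i] - mc[j]) <= tolerance + 1e-9:
            pairs.append((hc[i], mc[j]))
            i += 1
            j += 1
        elif hc[i] < mc[j]:
            pairs.append((hc[i], None))
            i += 1
        else:
            pairs.append((None, mc[j]))
            j += 1
    pairs.extend((c, None) for c in hc[i:])
    pairs.extend((None, c) for c in mc[j:])
    return pairs


ORIGIN_EPIGENETIC = "epigenetic_only"
ORIGIN_GENETIC_OR_EPI = "genetic_or_epigenetic"
ORIGIN_MONOMORPHIC = "monomorphic"


def classify_marker_origin(
    hpa: pd.DataFrame,
    msp: pd.DataFrame,
    grouping: pd.Series,
    tolerance: float = 0.5,
) -> pd.DataFrame:
    """Classify loci as epigenetic-only, genetic-or-epigenetic, or monomorphic.

    A locus polymorphic between the two groups in exactly one enzyme's
    profile can only reflect a methylation difference (both enzymes see the
    same DNA sequence); polymorphism in both profiles is compatible with
    either a sequence or a methylation change.
    """
    if list(hpa.index) != list(msp.index):
        raise ValueError("HpaII and MspI matrices must cover the same samples")
    labels = grouping.loc[hpa.index]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("grouping must define exactly two groups")

    def polymorphic(matrix: pd.DataFrame, enzyme: str, center: float | None) -> bool:
        if center is None:
            return False
        col = matrix[(enzyme, center)]
        f = [col[np.asarray(labels == g)].mean() for g in uniq]
        return bool(abs(f[0] - f[1]) > 1e-12)

    rows = []
    for hc, mc in match_loci(hpa, msp, tolerance):
        ph = polymorphic(hpa, "HpaII", hc)
        pm = polymorphic(msp, "MspI", mc)
        if ph and pm:
            label = ORIGIN_GENETIC_OR_EPI
        elif ph or pm:
            label = ORIGIN_EPIGENETIC
        else:
            label = ORIGIN_MONOMORPHIC
        rows.append(
            {"hpa_center": hc, "msp_center": mc, "origin": label,
             "polymorphic_hpaii": ph, "polymorphic_mspi": pm}
        )
    return pd.DataFrame(rows)


def call_methylation_state(hpa_present: int, msp_present: int) -> str:
    """Methylation state of one CCGG site from paired presence calls."""
    key = (int(bool(hpa_present)), int(bool(msp_present)))
    return METHYLATION_STATES[key]


def call_methylation_states(
    hpa: pd.DataFrame, msp: pd.DataFrame, tolerance: float = 0.5
) -> pd.DataFrame:
    """Per-sample methylation-state calls for loci shared by both enzymes."""
    if list(hpa.index) != list(msp.index):
        raise ValueError("HpaII and MspI matrices must cover the same samples")
    shared = [
        (hc, mc) for hc, mc in match_loci(hpa, msp, tolerance) if hc is not None and mc is not None
    ]
    data = {}
    for hc, mc in shared:
        h = hpa[("HpaII", hc)].to_numpy()
        m = msp[("MspI", mc)].to_numpy()
        data[(hc + mc) / 2] = [
            METHYLATION_STATES[(int(a), int(b))] for a, b in zip(h, m)
        ]
    return pd.DataFrame(data, index=hpa.index)


def enzyme_partition(
    hpa: pd.DataFrame, msp: pd.DataFrame, tolerance: float = 0.5
) -> tuple[int, int, int, int]:
    """(unique HpaII, unique MspI, shared, total) locus counts."""
    pairs = match_loci(hpa, msp, tolerance)
    n_shared = sum(1 for h, m in pairs if h is not None and m is not None)
    n_hpa = sum(1 for h, m in pairs if m is None)
    n_msp = sum(1 for h, m in pairs if h is None)
    return n_hpa, n_msp, n_shared, n_hpa + n_msp + n_shared


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_peak_csv(path) -> pd.DataFrame:
    """Read a sized-peak table (sample_id, enzyme, size_bp, height)."""
    df = pd.read_csv(path)
    return _validate_records(df)


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    """Write an epilocus matrix with the two-row (enzyme, size) header."""
    matrix.to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(e, float(s)) for e, s in df.columns], names=["enzyme", "size_bp"]
    )
    return df
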