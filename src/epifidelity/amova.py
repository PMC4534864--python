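"""Distance-based population epigenetics on binary MSAP matrices.

PhiPT is the AMOVA-derived fixation analogue for dominant (presence/absence)
marker data: the proportion of total molecular variance attributable to
differences among groups, with significance assessed by permuting sample
group labels. Distances between binary profiles are squared-Euclidean,
which for 0/1 data is simply the number of mismatching loci.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .datatypes import AmovaResult, PcoaResult

__all__ = [
    "binary_distance",
    "amova_phipt",
    "pcoa",
    "diagnostic_markers",
    "tissue_divergence_summary",
]


def binary_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared-Euclidean distances between binary sample profiles.

    For 0/1 rows this equals the count of loci at which the two samples
    differ (Hamming distance), the convention used for dominant marker
    AMOVA.
    """
    x = m.to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("binary_distance expects a 0/1 matrix")
    # squared Euclidean == Hamming for binary data
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=m.index, columns=m.index)


def _ss_partition(d: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """Total and within-group sums of squares from a squared-distance matrix."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d[iu].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return float(ss_total), float(ss_within)


def _phipt_from_ss(d: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float, float]:
    """(phipt, va, vw) with negative among-group variance truncated at 0."""
    n = d.shape[0]
    sizes = np.bincount(codes, minlength=k).astype(float)
    ss_total, ss_within = _ss_partition(d, codes, k)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among if df_among > 0 else 0.0
    # standard unequal-n coefficient
    n0 = (n - (sizes**2).sum() / n) / df_among if df_among > 0 else 0.0
    va = (ms_among - ms_within) / n0 if n0 > 0 else 0.0
    va = max(va, 0.0)
    vw = ms_within
    denom = va + vw
    phipt = va / denom if denom > 0 else 0.0
    return phipt, va, vw


def _distinct_assignments(codes: np.ndarray, k: int):
    """Yield every distinct assignment of group sizes to sample positions."""
    n = codes.size
    sizes = np.bincount(codes, minlength=k)
    positions = list(range(n))

    def rec(remaining: list[int], g: int, current: np.ndarray):
        if g == k - 1:
            out = current.copy()
            out[remaining] = g
            yield out
            return
        for combo in itertools.combinations(remaining, sizes[g]):
            nxt = current.copy()
            nxt[list(combo)] = g
            rest = [p for p in remaining if p not in combo]
            yield from rec(rest, g + 1, nxt)

    yield from rec(positions, 0, np.full(n, -1, dtype=int))


def n_distinct_assignments(sizes) -> int:
    """Multinomial count of distinct group-label assignments."""
    n = int(sum(sizes))
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(int(s))
    return out


def amova_phipt(
    d: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on a squared-distance matrix with permutation test.

    Variance components come from the distance-based sums of squares
    (total vs within-group), with the among-group component obtained via
    the standard unequal-n coefficient and truncated at zero; PhiPT is
    Va / (Va + Vw), defined as 0 when both components vanish. The p-value
    is the add-one-corrected tail probability of permuted PhiPT values at
    least as large as observed; when ``n_perm`` meets or exceeds the number
    of distinct label assignments the permutation distribution is
    enumerated exactly instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = list(d.index)
    labels = groups.loc[samples]
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    codes = np.asarray([uniq.index(v) for v in labels])
    k = len(uniq)
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")

    phipt, va, vw = _phipt_from_ss(dm, codes, k)
    sizes = np.bincount(codes, minlength=k)
    n_total_assign = n_distinct_assignments(sizes)

    if n_perm >= n_total_assign:
        stats = [
            _phipt_from_ss(dm, assign, k)[0] for assign in _distinct_assignments(codes, k)
        ]
        stats = np.asarray(stats)
        p = float((stats >= phipt - 1e-12).sum() / stats.size)
        n_used = stats.size
        exact = True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _phipt_from_ss(dm, perm, k)[0] >= phipt - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
        exact = False

    return AmovaResult(
        sigma2_among=va,
        sigma2_within=vw,
        phipt=phipt,
        p_value=p,
        n_perm=n_used,
        df_among=k - 1,
        df_within=len(samples) - k,
        exact=exact,
    )


def pcoa(d: pd.DataFrame, eig_tol: float = 1e-9) -> PcoaResult:
    """Principal-coordinates analysis of a squared-distance matrix.

    ``d`` already holds squared distances, so Gower centering applies
    ``-1/2`` to its elements directly (no further squaring). Coordinates
    are eigenvectors scaled by the square root of their (positive)
    eigenvalues; negative eigenvalues are reported but their axes dropped.
    """
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ dm @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.max(np.abs(vals)) if n else 0.0
    pos = vals > eig_tol * max(scale, 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])[None, :]
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else vals[pos]
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
    )


def diagnostic_markers(m: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-locus band frequencies by group, with fixed-difference flags.

    A locus is condition-diagnostic iff its band frequency is exactly 1 in
    one group and exactly 0 in the other. The returned frame has one row
    per locus with per-group frequencies and a ``diagnostic`` flag.
    """
    labels = groups.loc[m.index]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("diagnostic markers are defined for exactly two groups")
    freqs = {g: m.loc[np.asarray(labels == g)].mean(axis=0) for g in uniq}
    out = pd.DataFrame(freqs)
    a, b = uniq
    out["diagnostic"] = ((out[a] == 1.0) & (out[b] == 0.0)) | (
        (out[a] == 0.0) & (out[b] == 1.0)
    )
    return out


def all_cultivar_diagnostics(per_cultivar: dict[str, pd.DataFrame]) -> pd.Index:
    """Loci diagnostic in every cultivar (intersection of per-cultivar sets)."""
    sets = [
        set(df.index[df["diagnostic"]]) for df in per_cultivar.values()
    ]
    if not sets:
        return pd.Index([])
    common = set.intersection(*sets)
    return pd.Index(sorted(common))


def tissue_divergence_summary(phipt_table: pd.DataFrame, decimals: int = 4) -> pd.Series:
    """Average per-cultivar PhiPT values over non-missing entries.

    ``phipt_table`` has cultivars as rows and comparison columns (e.g. one
    column per tissue-pair x enzyme x condition); NaN marks a cultivar
    missing that comparison. Values must lie in [0, 1]. Returns the
    arithmetic column means rounded to ``decimals`` (the precision at which
    such summaries are reported); all-missing columns stay missing.
    """
    vals = phipt_table.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("PhiPT values must lie in [0, 1]")
    means = phipt_table.mean(axis=0, skipna=True)
    return means.round(decimals)
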