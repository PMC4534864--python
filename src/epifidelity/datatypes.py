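"""Shared containers and label vocabularies for the MSAP / msGBS pipeline.

Sample metadata keys every matrix column in the package: each sample is one
DNA extraction from a (variety, propagation condition, tissue, replicate)
cell of the clonal-propagation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("field", "in_vitro")
TISSUES = ("young_leaf", "mature_leaf", "root")
ENZYMES = ("HpaII", "MspI")

PHASE_UP_FIELD = "up_in_field"
PHASE_UP_VITRO = "up_in_vitro"
PHASE_NONE = "none"

META_COLUMNS = ("variety", "condition", "tissue", "replicate")


def make_metadata(rows: list[dict] | pd.DataFrame) -> pd.DataFrame:
    """Build and validate a sample-metadata table.

    Parameters
    ----------
    rows
        Records with ``sample_id`` plus the design labels
        (variety, condition, tissue, replicate).

    Returns
    -------
    DataFrame indexed by ``sample_id`` with columns
    ``variety, condition, tissue, replicate``.
    """
    meta = pd.DataFrame(rows)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id: {dups}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition label(s): {sorted(bad_cond)}")
    bad_tis = set(meta["tissue"]) - set(TISSUES)
    if bad_tis:
        raise ValueError(f"unknown tissue label(s): {sorted(bad_tis)}")
    return meta[list(META_COLUMNS)]


@dataclass
class TagCountMatrix:
    """Integer tag x sample abundance matrix with library-size bookkeeping.

    ``counts`` holds non-negative values (msGBS read counts, or MSAP peak
    heights rounded to integers for the count machinery), ``meta`` the
    per-sample design labels, ``lib_size`` the column sums and
    ``norm_factor`` the TMM factors (1.0 until normalisation is run).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    lib_size: pd.Series = field(default=None)  # type: ignore[assignment]
    norm_factor: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        if self.norm_factor is None:
            self.norm_factor = pd.Series(1.0, index=self.counts.columns)
        extra = [s for s in self.counts.columns if s not in self.meta.index]
        if extra:
            raise ValueError(f"samples absent from metadata: {extra}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def tags(self) -> pd.Index:
        return self.counts.index

    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.norm_factor

    def subset_samples(self, sample_ids) -> "TagCountMatrix":
        """New matrix restricted to ``sample_ids``; lib sizes recomputed,
        norm factors reset (normalisation is per-comparison)."""
        sub = self.counts[list(sample_ids)]
        return TagCountMatrix(sub.copy(), self.meta.loc[list(sample_ids)])


@dataclass
class AmovaResult:
    """Two-level molecular-variance partition of a squared-distance matrix."""

    sigma2_among: float
    sigma2_within: float
    phipt: float
    p_value: float
    n_perm: int
    df_among: int
    df_within: int
    exact: bool = False  # True when p came from full label enumeration


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a squared-distance matrix."""

    coordinates: pd.DataFrame  # samples x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over the positive eigenvalues
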