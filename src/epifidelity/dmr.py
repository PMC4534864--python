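"""Micropropagation-induced DMR calling.

Per variety, tag abundances are compared between all *in vitro* and all
field-grown samples (tissues pooled) with the NB exact-test pipeline; a
tag becomes a consensus DMR when it is significant with the same phase
(direction of differential abundance) in at least ``min_varieties``
varieties and no variety is significant with the opposite phase. The
consistency-across-genotypes requirement is what separates reproducible
culture-induced methylation marks from variety-specific noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbstats
from .datatypes import PHASE_NONE, TagCountMatrix

__all__ = ["per_variety_tests", "consensus_dmrs", "summarize_differential", "DmrSet"]


@dataclass
class DmrSet:
    """Consensus DMR table plus the per-variety evidence behind it."""

    table: pd.DataFrame  # per tag: consensus flag, phase, n_varieties_supporting
    per_variety: dict[str, pd.DataFrame]
    fdr: float
    min_varieties: int

    @property
    def consensus_tags(self) -> pd.Index:
        return self.table.index[self.table["consensus"]]


def per_variety_tests(
    m: TagCountMatrix,
    pair: tuple[str, str] = ("in_vitro", "field"),
    prior_n: float = 10.0,
    use_tagwise: bool = True,
) -> dict[str, pd.DataFrame]:
    """Condition contrast per variety via TMM -> dispersions -> exact test.

    Samples are subset per variety with tissues pooled within condition;
    BH adjustment is applied within each variety. Varieties missing one of
    the two conditions are excluded with a warning.
    """
    results: dict[str, pd.DataFrame] = {}
    for variety in pd.unique(m.meta.loc[m.samples, "variety"]):
        sids = [s for s in m.samples if m.meta.loc[s, "variety"] == variety]
        conds = m.meta.loc[sids, "condition"]
        if set(pair) - set(conds):
            warnings.warn(f"variety {variety!r} lacks a condition; excluded")
            continue
        sub = m.subset_samples(sids)
        nbstats.normalize_tmm(sub)
        phi_common = nbstats.common_dispersion(sub, conds)
        if use_tagwise:
            phi = nbstats.tagwise_dispersion(sub, conds, phi_common, prior_n=prior_n)
        else:
            phi = phi_common
        results[str(variety)] = nbstats.exact_test(
            sub, conds, pair=pair, dispersion=phi, equalize_at=phi_common
        )
    return results


def consensus_dmrs(
    results: dict[str, pd.DataFrame],
    fdr: float = 0.05,
    min_varieties: int = 4,
    require_observed: TagCountMatrix | None = None,
) -> DmrSet:
    """Phase-conserved cross-variety consensus of per-variety tests.

    A tag is a consensus DMR iff (a) its BH q-value is below ``fdr`` in at
    least ``min_varieties`` varieties, (b) the phase is identical in every
    variety where it is significant, and (c) no variety is significant
    with the opposite phase. ``require_observed`` (the count matrix) adds
    the constraint that the tag has a nonzero count in at least one sample
    of every variety, the proxy used for "no variety-specific sequence
    variants".
    """
    varieties = list(results)
    if min_varieties > len(varieties):
        raise ValueError(
            f"min_varieties={min_varieties} exceeds the {len(varieties)} varieties tested"
        )
    tags = results[varieties[0]].index
    sig = pd.DataFrame(
        {v: results[v]["qvalue"] < fdr for v in varieties}, index=tags
    )
    phases = pd.DataFrame({v: results[v]["phase"] for v in varieties}, index=tags)
    sig_phases = phases.where(sig, other=PHASE_NONE)

    n_up = (sig_phases == "up_in_field").sum(axis=1)
    n_down = (sig_phases == "up_in_vitro").sum(axis=1)
    n_support = pd.concat([n_up, n_down], axis=1).max(axis=1)
    opposite = (n_up > 0) & (n_down > 0)
    consensus = (n_support >= min_varieties) & ~opposite
    if require_observed is not None:
        meta_ok = pd.Series(True, index=tags)
        # nonzero in >= 1 sample of every variety
        var_of = require_observed.meta.loc[require_observed.samples, "variety"]
        for v in varieties:
            cols = [s for s in require_observed.samples if var_of[s] == v]
            if cols:
                meta_ok &= (require_observed.counts[cols] > 0).any(axis=1)
        consensus &= meta_ok
    cons_phase = np.where(
        ~consensus, PHASE_NONE, np.where(n_up >= n_down, "up_in_field", "up_in_vitro")
    )
    table = pd.DataFrame(
        {
            "consensus": consensus,
            "consensus_phase": cons_phase,
            "n_varieties_supporting": n_support.where(consensus, 0),
        },
        index=tags,
    )
    for v in varieties:
        table[f"log2fc_{v}"] = results[v]["log2fc"]
        table[f"q_{v}"] = results[v]["qvalue"]
        table[f"phase_{v}"] = results[v]["phase"]
    return DmrSet(table=table, per_variety=results, fdr=fdr, min_varieties=min_varieties)


def summarize_differential(
    results: dict[str, pd.DataFrame],
    dmrs: DmrSet | None = None,
    fdr: float = 0.05,
    n_unique_tags: int | None = None,
) -> pd.DataFrame:
    """Per-variety counts of significant tags by phase, plus totals.

    Returns one row per variety with columns ``in_vitro`` (more abundant
    in vitro), ``field`` (more abundant in field) and ``total``. When a
    consensus set is given, a ``consensus`` attribute dict is attached to
    the frame with counts by phase and the consensus percentage of unique
    tags (2 decimals).
    """
    rows = {}
    for v, res in results.items():
        sig = res[res["qvalue"] < fdr]
        up_vitro = int((sig["phase"] == "up_in_vitro").sum())
        up_field = int((sig["phase"] == "up_in_field").sum())
        rows[v] = {"in_vitro": up_vitro, "field": up_field, "total": up_vitro + up_field}
    out = pd.DataFrame.from_dict(rows, orient="index")
    if dmrs is not None:
        n_cons = int(dmrs.table["consensus"].sum())
        total = n_unique_tags if n_unique_tags is not None else len(dmrs.table)
        out.attrs["consensus"] = {
            "n_consensus": n_cons,
            "up_in_field": int((dmrs.table.loc[dmrs.table["consensus"], "consensus_phase"] == "up_in_field").sum()),
            "up_in_vitro": int((dmrs.table.loc[dmrs.table["consensus"], "consensus_phase"] == "up_in_vitro").sum()),
            "n_unique_tags": total,
            "percent_of_unique": consensus_percent(n_cons, total),
        }
    return out


def consensus_percent(n_consensus: int, n_unique_tags: int) -> float:
    """Consensus DMRs as a percentage of unique tags, 2 decimals."""
    if n_unique_tags <= 0:
        return 0.0
    return round(100.0 * n_consensus / n_unique_tags, 2)
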