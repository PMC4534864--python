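"""Count statistics shared by quantitative MSAP and msGBS tracks.

Implements the classical count-based differential-abundance toolchain for
two-group comparisons: TMM (trimmed mean of M-values) between-library
normalisation, quantile-adjusted conditional maximum likelihood (qCML)
estimation of the negative-binomial dispersion (common and empirical-Bayes
tagwise), the conditional NB exact test, and Benjamini-Hochberg FDR.

The negative binomial is parameterised by mean ``mu`` and dispersion
``phi`` with variance ``mu + phi * mu**2``; ``phi = 0`` is the Poisson
limit. Peak-height matrices are admitted after rounding to integers, which
treats fluorescence intensity as a count-like abundance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .datatypes import PHASE_NONE, TagCountMatrix

PHI_MIN = 1e-6
PHI_MAX = 10.0

__all__ = [
    "tmm_factors",
    "normalize_tmm",
    "equalize_library_sizes",
    "common_dispersion",
    "tagwise_dispersion",
    "exact_test",
    "bh_fdr",
    "phase_label",
]


def phase_label(group: str) -> str:
    """Direction label for abundance higher in ``group``."""
    return {"field": "up_in_field", "in_vitro": "up_in_vitro"}.get(
        group, f"up_in_{group}"
    )


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one library against the reference.

    M-values are doubly trimmed (``trim_m`` of extreme log-ratios,
    ``trim_a`` of extreme mean abundances) and averaged with inverse
    asymptotic-binomial-variance weights.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("library shares no positive tags with reference; factor set to 1")
        return 0.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # Asymptotic binomial variance of M at a depth common to the pair; the
    # shared depth factor cancels in the weighted mean, which makes the
    # factor exactly invariant to rescaling either library.
    w = (1.0 - o) / o + (1.0 - r) / r
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    counts: pd.DataFrame,
    lib_size: pd.Series | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM normalisation factors for a tag x sample count matrix.

    The reference library is the sample whose upper-quartile abundance
    (75th percentile of counts scaled by library size) is closest to the
    mean upper-quartile. Factors are rescaled so their geometric mean is 1;
    library depth itself is carried by ``lib_size``, not by the factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    x = counts.to_numpy(dtype=float)
    if lib_size is None:
        lib_size = counts.sum(axis=0).astype(float)
    libs = lib_size.to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    uq = np.percentile(x, 75, axis=0) / libs
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_pair_factor(x[:, j], x[:, ref_idx], libs[j], libs[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def normalize_tmm(m: TagCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> TagCountMatrix:
    """Attach TMM factors to a :class:`TagCountMatrix` (in place, returned)."""
    m.norm_factor = tmm_factors(m.counts, m.lib_size, trim_m=trim_m, trim_a=trim_a)
    return m


# ---------------------------------------------------------------------------
# Quantile adjustment (pseudo-counts on a common effective library size)
# ---------------------------------------------------------------------------


def _q2q_map(y: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float) -> np.ndarray:
    """Map integer counts between NB distributions by matching CDF levels.

    For each count ``y ~ NB(mu_in, phi)`` the lower-tail probability
    ``u = F_in(y)`` is carried to the output distribution and inverted on
    the piecewise-linear interpolation of ``F_out`` between consecutive
    integers, yielding a continuous pseudo-count with the same quantile
    position at mean ``mu_out``.
    """
    y = np.asarray(y, dtype=float)
    out = y.copy()
    todo = (np.abs(mu_in - mu_out) > 1e-9 * np.maximum(mu_in, 1.0)) & (mu_in > 0) & (mu_out > 0)
    if not todo.any():
        return out
    yi = y[todo]
    mi = mu_in[todo]
    mo = mu_out[todo]
    if phi < 1e-12:
        cdf_in = stats.poisson.cdf(yi, mi)

        def cdf_out(k):
            return stats.poisson.cdf(k, mo)

        def pmf_out(k):
            return stats.poisson.pmf(k, mo)

        def ppf_out(u):
            return stats.poisson.ppf(u, mo)

    else:
        r = 1.0 / phi
        p_in = r / (r + mi)
        p_out = r / (r + mo)
        cdf_in = stats.nbinom.cdf(yi, r, p_in)

        def cdf_out(k):
            return stats.nbinom.cdf(k, r, p_out)

        def pmf_out(k):
            return stats.nbinom.pmf(k, r, p_out)

        def ppf_out(u):
            return stats.nbinom.ppf(u, r, p_out)

    u = np.clip(cdf_in, 1e-300, 1.0 - 1e-12)
    k = ppf_out(u)  # smallest integer with F_out(k) >= u
    k = np.where(np.isfinite(k), k, 0.0)
    f_km1 = np.where(k > 0, cdf_out(k - 1), 0.0)
    pk = pmf_out(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (u - f_km1) / pk
    frac = np.clip(np.nan_to_num(frac, nan=0.5, posinf=1.0, neginf=0.0), 0.0, 1.0)
    z = np.maximum(k - 1.0 + frac, 0.0)
    out[todo] = z
    return out


def equalize_library_sizes(
    counts: pd.DataFrame,
    eff_lib: pd.Series,
    groups: pd.Series,
    dispersion: float,
) -> tuple[pd.DataFrame, float]:
    """Quantile-adjust counts to the geometric-mean effective library size.

    Per-tag expected abundance is estimated within each group (group total
    over group library total) so genuine between-group fold-changes are not
    flattened by the adjustment. Returns the pseudo-count matrix and the
    common library size.
    """
    eff = eff_lib.loc[counts.columns].to_numpy(dtype=float)
    common_lib = float(np.exp(np.mean(np.log(eff))))
    x = counts.to_numpy(dtype=float)
    pseudo = np.zeros_like(x)
    glabels = groups.loc[counts.columns]
    for g in glabels.unique():
        cols = np.asarray(glabels == g)
        glib = eff[cols]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_tag = x[:, cols].sum(axis=1) / glib.sum()
        mu_in = p_tag[:, None] * glib[None, :]
        mu_out = np.broadcast_to(p_tag[:, None] * common_lib, mu_in.shape)
        pseudo[:, cols] = _q2q_map(
            x[:, cols].ravel(), mu_in.ravel(), mu_out.ravel(), dispersion
        ).reshape(mu_in.shape)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common_lib


# ---------------------------------------------------------------------------
# Conditional log-likelihood machinery
# ---------------------------------------------------------------------------


def _group_masks(groups: pd.Series, columns) -> list[np.ndarray]:
    glabels = groups.loc[columns]
    uniq = list(dict.fromkeys(glabels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    return [np.asarray(glabels == g) for g in uniq]


def _cond_loglik(z: np.ndarray, masks: list[np.ndarray], phi: np.ndarray) -> np.ndarray:
    """Per-tag conditional NB log-likelihood on equalised pseudo-counts.

    ``phi`` may be a scalar or a grid; the result has shape
    ``(n_tags,) + phi.shape`` summed over both groups. Conditioning on the
    group total removes the mean, leaving the dispersion as the only
    parameter.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    r = 1.0 / phi  # (G,)
    ll = np.zeros((z.shape[0], phi.size))
    for mask in masks:
        zg = z[:, mask]  # (T, n)
        n = zg.shape[1]
        tot = zg.sum(axis=1)  # (T,)
        ll += (
            gammaln(zg[:, :, None] + r[None, None, :]).sum(axis=1)
            + gammaln(n * r)[None, :]
            - gammaln(tot[:, None] + n * r[None, :])
            - n * gammaln(r)[None, :]
        )
    return ll


def common_dispersion(
    m: TagCountMatrix,
    groups: pd.Series,
    tol: float = 1e-4,
    max_iter: int = 6,
) -> float:
    """Common NB dispersion by quantile-adjusted conditional ML.

    Counts are equalised to a common library size, then the dispersion
    maximising the summed conditional log-likelihood over all tags is found
    by bounded search on the log scale; equalisation and maximisation are
    iterated until the estimate is stable. Degenerate likelihoods (flat or
    monotone decreasing, e.g. Poisson-like data) return the lower bound
    ``1e-6``.
    """
    if (m.counts.to_numpy() == 0).all():
        warnings.warn("all-zero matrix; common dispersion set to lower bound")
        return PHI_MIN
    masks = _group_masks(groups, m.counts.columns)
    eff = m.effective_lib_size()
    phi = 0.01
    for _ in range(max_iter):
        pseudo, _ = equalize_library_sizes(m.counts, eff, groups, phi)
        z = pseudo.to_numpy()

        def neg(logphi):
            return -float(_cond_loglik(z, masks, np.exp(logphi)).sum())

        res = minimize_scalar(
            neg, bounds=(np.log(PHI_MIN), np.log(PHI_MAX)), method="bounded",
            options={"xatol": 1e-6},
        )
        new_phi = float(np.exp(res.x))
        # Bounded search can stall just inside the bracket on monotone
        # likelihoods; snap to the bound when it is at least as good.
        if neg(np.log(PHI_MIN)) <= res.fun + 1e-9:
            new_phi = PHI_MIN
        if abs(np.log(new_phi) - np.log(phi)) < tol:
            phi = new_phi
            break
        phi = new_phi
    return phi


def tagwise_dispersion(
    m: TagCountMatrix,
    groups: pd.Series,
    phi_common: float,
    prior_n: float = 10.0,
) -> pd.Series:
    """Empirical-Bayes (weighted-likelihood) tagwise dispersions.

    Each tag maximises its own conditional log-likelihood plus ``prior_n``
    times the mean conditional log-likelihood over all tags, shrinking the
    per-tag estimate toward the common value; ``prior_n = 0`` gives the
    per-tag conditional MLE and ``prior_n -> inf`` the common dispersion.
    Maximisation is by dense log-grid search with a local refinement grid
    and quadratic interpolation around the optimum.
    """
    if prior_n < 0:
        raise ValueError("prior_n must be >= 0")
    masks = _group_masks(groups, m.counts.columns)
    pseudo, _ = equalize_library_sizes(
        m.counts, m.effective_lib_size(), groups, phi_common
    )
    z = pseudo.to_numpy()
    grid = np.log(np.logspace(np.log10(PHI_MIN), np.log10(PHI_MAX), 85))
    ll = _cond_loglik(z, masks, np.exp(grid))  # (T, G)
    shared = ll.mean(axis=0)  # (G,)
    obj = ll + prior_n * shared[None, :]
    best = np.argmax(obj, axis=1)

    # local refinement: 11 points across +-1 coarse step around the argmax
    step = grid[1] - grid[0]
    centers = grid[best]
    offsets = np.linspace(-step, step, 11)
    fine = centers[:, None] + offsets[None, :]
    fine = np.clip(fine, np.log(PHI_MIN), np.log(PHI_MAX))
    ll_fine = _cond_loglik_per_tag_grid(z, masks, np.exp(fine))
    shared_fine = _interp_shared(grid, shared, fine)
    obj_fine = ll_fine + prior_n * shared_fine
    bi = np.argmax(obj_fine, axis=1)
    idx = np.arange(z.shape[0])
    logphi = fine[idx, bi]
    # quadratic interpolation where the optimum is interior
    interior = (bi > 0) & (bi < fine.shape[1] - 1)
    if interior.any():
        i = idx[interior]
        b = bi[interior]
        x0, x1, x2 = fine[i, b - 1], fine[i, b], fine[i, b + 1]
        y0, y1, y2 = obj_fine[i, b - 1], obj_fine[i, b], obj_fine[i, b + 1]
        denom = (y0 - 2 * y1 + y2)
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (y0 - y2) / denom
        shift = np.clip(np.nan_to_num(shift, nan=0.0), -1.0, 1.0)
        logphi[interior] = x1 + shift * (x1 - x0)
    phi = np.clip(np.exp(logphi), PHI_MIN, PHI_MAX)
    return pd.Series(phi, index=m.counts.index, name="tagwise_dispersion")


def _cond_loglik_per_tag_grid(
    z: np.ndarray, masks: list[np.ndarray], phi: np.ndarray
) -> np.ndarray:
    """Like :func:`_cond_loglik` but with a per-tag grid ``phi`` (T, K)."""
    r = 1.0 / phi  # (T, K)
    ll = np.zeros_like(phi)
    for mask in masks:
        zg = z[:, mask]
        n = zg.shape[1]
        tot = zg.sum(axis=1)
        ll += (
            gammaln(zg[:, :, None] + r[:, None, :]).sum(axis=1)
            + gammaln(n * r)
            - gammaln(tot[:, None] + n * r)
            - n * gammaln(r)
        )
    return ll


def _interp_shared(grid: np.ndarray, shared: np.ndarray, x: np.ndarray) -> np.ndarray:
    # cubic, not linear: the shared curve enters the per-tag objective with a
    # potentially huge prior weight, so kinks at grid knots would pin argmaxes
    from scipy.interpolate import CubicSpline

    return CubicSpline(grid, shared)(x)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _exact_nb_pvalue(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact NB p-value by minimum-likelihood enumeration.

    Conditioning on the (rounded) total pseudo-count ``t``, the group-1 sum
    follows the normalised product of two NB mass functions; the p-value
    sums the probabilities of all outcomes no more likely than the observed
    split (tie-inclusive, no doubling).
    """
    # round per group (not the grand total) so swapping groups is symmetric
    y_obs = max(int(round(s1)), 0)
    t = y_obs + max(int(round(s2)), 0)
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi < 1e-10:
        logp = stats.binom.logpmf(y, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logp = stats.nbinom.logpmf(y, r1, p1) + stats.nbinom.logpmf(t - y, r2, p2)
        logp -= logsumexp(logp)
    prob = np.exp(logp)
    p_obs = prob[y_obs]
    pval = float(prob[prob <= p_obs * (1.0 + 1e-12)].sum())
    return min(max(pval, p_obs), 1.0)


def exact_test(
    m: TagCountMatrix,
    groups: pd.Series,
    pair: tuple[str, str],
    dispersion: float | pd.Series | np.ndarray,
    equalize_at: float | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group NB exact test per tag.

    Parameters
    ----------
    m
        Normalised count matrix (TMM factors already attached).
    groups
        Sample -> group label (exactly the two labels in ``pair`` among
        ``m``'s samples).
    pair
        ``(numerator, denominator)`` groups; positive log2 fold-change
        means more abundant in ``pair[0]``.
    dispersion
        Scalar or per-tag NB dispersion used by the test.
    equalize_at
        Dispersion used for the quantile adjustment (defaults to the
        scalar ``dispersion`` or the mean of the per-tag values).
    prior_count
        Added per observation when forming the log2 fold-change, avoiding
        log of zero.

    Returns
    -------
    DataFrame indexed by tag with columns ``log2fc, pvalue, qvalue, phase``.
    """
    g1, g2 = pair
    glabels = groups.loc[m.counts.columns]
    if set(glabels) != {g1, g2}:
        raise ValueError(f"groups must be exactly {pair}, got {sorted(set(glabels))}")
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 0:
        phi = np.full(m.counts.shape[0], float(phi))
    if (phi < 0).any():
        raise ValueError("dispersion must be >= 0")
    eq_phi = float(equalize_at) if equalize_at is not None else float(phi.mean())
    pseudo, _ = equalize_library_sizes(m.counts, m.effective_lib_size(), glabels, eq_phi)
    mask1 = np.asarray(glabels == g1)
    mask2 = ~mask1
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    z = pseudo.to_numpy()
    s1 = z[:, mask1].sum(axis=1)
    s2 = z[:, mask2].sum(axis=1)
    pvals = np.array(
        [_exact_nb_pvalue(a, b, n1, n2, f) for a, b, f in zip(s1, s2, phi)]
    )
    lfc = np.log2(((s1 + prior_count * n1) / n1) / ((s2 + prior_count * n2) / n2))
    phase = np.where(
        lfc > 0, phase_label(g1), np.where(lfc < 0, phase_label(g2), PHASE_NONE)
    )
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "qvalue": bh_fdr(pvals),
            "phase": phase,
        },
        index=m.counts.index,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
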