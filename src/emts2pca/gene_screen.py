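"""Per-design gene screening.

Two stages per 10-sample design: an exact permutation t-test removes genes
indistinguishable from noise, then a three-state expression mixture
(under / baseline / over) fitted by EM to the pooled centered/normalized
entries assigns every expression value posterior probabilities of over- and
under-expression conditional on deregulation.  A gene is a
candidate when every one of its entries is confidently assigned and the
assignments split the two subgroups in opposite directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numba import njit

from .combinatorics import TenSampleDesign
from .data_model import DataError

logger = logging.getLogger("emts2pca")

__all__ = [
    "PosteriorTable",
    "CandidateSet",
    "permutation_t_filter",
    "fit_em_posteriors",
    "select_candidates",
    "screen_design",
]

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, trace: list[float]):
        super().__init__(
            f"EM did not converge after {len(trace)} iterations "
            f"(last ll {trace[-1]:.6g})"
        )
        self.trace = trace


# ---------------------------------------------------------------------------
# Permutation t-test filter
# ---------------------------------------------------------------------------


def _t_stats(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each gene (rows of ``values``) under
    each 0/1 column-assignment row of ``masks``.  Undefined t -> NaN."""
    n = values.shape[1]
    k = int(masks[0].sum())
    m = n - k
    s1 = values @ masks.T                    # genes x assignments, group-1 sums
    q1 = (values**2) @ masks.T
    tot = values.sum(axis=1, keepdims=True)
    qtot = (values**2).sum(axis=1, keepdims=True)
    s2 = tot - s1
    q2 = qtot - q1
    mean1, mean2 = s1 / k, s2 / m
    ss1 = q1 - s1**2 / k
    ss2 = q2 - s2**2 / m
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / (n - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / k + 1.0 / m))
    return t


def permutation_t_filter(
    values: np.ndarray,
    group_mask: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation two-sample t-test per gene over a k-vs-k design.

    The null enumerates every distinct assignment of k of the n samples to
    the first group — C(10,5) = 252 for the standard design — and
    ``p = #{ |t_perm| >= |t_obs| } / #assignments``.  Genes with undefined t
    (zero pooled variance) receive p = 1 and are dropped.

    Returns ``(keep_mask, p_values)`` over the gene rows.
    """
    values = np.asarray(values, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    n = values.shape[1]
    k = int(group_mask.sum())
    masks = np.zeros((0, n))
    assign = list(combinations(range(n), k))
    masks = np.zeros((len(assign), n))
    for r, idx in enumerate(assign):
        masks[r, list(idx)] = 1.0
    t_all = _t_stats(values, masks)
    obs_col = assign.index(tuple(np.nonzero(group_mask)[0]))
    t_obs = t_all[:, obs_col]
    undefined = ~np.isfinite(t_obs)
    with np.errstate(invalid="ignore"):
        # tiny relative margin so the exact-tie count (and hence p) is
        # invariant to which group is labelled first
        exceed = np.abs(t_all) >= np.abs(t_obs)[:, None] * (1 - 1e-9)
    # NaN comparisons are False; undefined observed t gets p = 1 explicitly
    p = exceed.sum(axis=1) / len(assign)
    p[undefined] = 1.0
    keep = p < alpha
    n_undef = int(undefined.sum())
    if n_undef:
        logger.debug("permutation_t_filter: %d undefined-t genes dropped", n_undef)
    return keep, p


# ---------------------------------------------------------------------------
# EM over/under mixture
# ---------------------------------------------------------------------------


@dataclass
class PosteriorTable:
    """Per-entry posterior probabilities of over- and under-expression for a
    design's centered/normalized candidate matrix.  ``p_over + p_under = 1``
    for every entry."""

    p_over: np.ndarray
    p_under: np.ndarray
    mean_under: float
    mean_over: float
    variance: float
    n_iter: int
    baseline_weight: float = 0.0

    def __post_init__(self) -> None:
        if not np.allclose(self.p_over + self.p_under, 1.0, atol=1e-9):
            raise DataError("posteriors must sum to 1 per entry")


_VAR_FLOOR = 1e-12


@njit(cache=True)
def _em_core(
    x: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    w: np.ndarray,
    max_iter: int,
    tol: float,
):  # pragma: no cover - exercised through fit_em_posteriors
    n = x.size
    resp = np.empty((n, 3))
    ll_trace = np.empty(max_iter)
    ll_prev = 0.0
    n_iter = 0
    converged = False
    ljs = np.empty(3)
    coef = np.empty(3)
    const = np.empty(3)
    for it in range(max_iter):
        for k in range(3):
            coef[k] = -0.5 / var[k]
            const[k] = np.log(w[k]) - 0.5 * np.log(2.0 * np.pi * var[k])
        ll = 0.0
        for i in range(n):
            m = -1e300
            for k in range(3):
                d = x[i] - mu[k]
                ljs[k] = coef[k] * d * d + const[k]
                if ljs[k] > m:
                    m = ljs[k]
            s = 0.0
            for k in range(3):
                resp[i, k] = np.exp(ljs[k] - m)
                s += resp[i, k]
            for k in range(3):
                resp[i, k] /= s
            ll += m + np.log(s)
        ll_trace[it] = ll
        n_iter = it + 1
        # M-step: three means; outer components share one variance
        nk = np.full(3, 1e-12)
        for i in range(n):
            for k in range(3):
                nk[k] += resp[i, k]
        mu_new = np.zeros(3)
        for i in range(n):
            for k in range(3):
                mu_new[k] += resp[i, k] * x[i]
        for k in range(3):
            mu_new[k] /= nk[k]
        sq = np.zeros(3)
        for i in range(n):
            for k in range(3):
                d = x[i] - mu_new[k]
                sq[k] += resp[i, k] * d * d
        var_out = max((sq[0] + sq[2]) / (nk[0] + nk[2]), _VAR_FLOOR)
        var_base = max(sq[1] / nk[1], _VAR_FLOOR)
        done = it > 0 and abs(ll - ll_prev) < tol * (1.0 + abs(ll_prev))
        ll_prev = ll
        for k in range(3):
            mu[k] = mu_new[k]
            w[k] = nk[k] / (nk[0] + nk[1] + nk[2])
        var[0] = var_out
        var[1] = var_base
        var[2] = var_out
        if done:
            converged = True
            break
    return resp, mu, var, w, n_iter, ll_trace[:n_iter], converged


def fit_em_posteriors(
    values: np.ndarray,
    max_iter: int = 20000,
    tol: float = 1e-8,
) -> PosteriorTable:
    """Fit a pooled one-dimensional three-state expression mixture by EM.

    The model has an under-expressed and an over-expressed Gaussian
    component (sharing one variance) flanking a baseline Gaussian component
    with its own mean and variance that absorbs entries of genes carrying no
    group signal — the permutation filter upstream is deliberately weak, so
    the pool always contains such entries.  ``P_over`` and ``P_under`` are
    the posterior probabilities of the two deregulated states conditional on
    deregulation, so they sum to one for every entry; an entry equidistant
    from two equal components gets 0.5/0.5.

    The fit is deterministic: outer means start at minus/plus the 75th
    percentile of the absolute pooled entries, the baseline mean at 0,
    weights at (1/4, 1/2, 1/4), and all variances at the pooled sample
    variance.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise DataError("need at least 2 entries to fit the mixture")
    scale = np.percentile(np.abs(x), 75)
    if scale == 0:
        scale = max(float(np.std(x)), 1e-12)
    mu = np.array([-scale, 0.0, scale])       # under, baseline, over
    var0 = max(float(np.var(x)), _VAR_FLOOR)
    var = np.array([var0, var0, var0])        # var[0] == var[2] (shared)
    w = np.array([0.25, 0.5, 0.25])

    resp, mu, var, w, n_iter, ll_trace, converged = _em_core(
        x, mu, var, w, max_iter, tol
    )
    if not converged:
        raise EMConvergenceError(list(ll_trace))

    # order the outer components by mean: under = smaller, over = larger
    outer = [0, 2] if mu[0] <= mu[2] else [2, 0]
    r_under, r_over = resp[:, outer[0]], resp[:, outer[1]]
    denom = np.maximum(r_under + r_over, 1e-300)
    p_under = (r_under / denom).reshape(values.shape)
    p_over = (r_over / denom).reshape(values.shape)
    return PosteriorTable(
        p_over=p_over,
        p_under=p_under,
        mean_under=float(mu[outer[0]]),
        mean_over=float(mu[outer[1]]),
        variance=float(var[0]),
        n_iter=int(n_iter),
        baseline_weight=float(w[1]),
    )


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


@dataclass
class CandidateSet:
    """Candidate genes of one design, with the deregulation direction."""

    design: TenSampleDesign | None
    gene_ids: list[str]
    direction: dict[str, str]  # gene -> up_in_A / up_in_B


def select_candidates(
    gene_ids: list[str],
    posteriors: PosteriorTable,
    group_mask: np.ndarray,
    delta: float = 0.05,
    design: TenSampleDesign | None = None,
) -> CandidateSet:
    """Apply the two candidate-gene eligibility rules.

    Rule 1: every entry of the gene must be confidently assigned —
    ``1 - |P_under - P_over| < delta`` for all samples of the design.
    Rule 2: the posterior-majority component must be "over" in every sample
    of one subgroup and "under" in every sample of the other.  Ties
    (P = 0.5 exactly) fail rule 1 by construction.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    diff = np.abs(posteriors.p_under - posteriors.p_over)
    confident = (1.0 - diff) < delta           # rule 1, per entry
    over = posteriors.p_over > posteriors.p_under  # majority component
    all_confident = confident.all(axis=1)

    up_in_a = over[:, group_mask].all(axis=1) & (~over[:, ~group_mask]).all(axis=1)
    up_in_b = over[:, ~group_mask].all(axis=1) & (~over[:, group_mask]).all(axis=1)
    eligible = all_confident & (up_in_a | up_in_b)

    ids = [g for g, e in zip(gene_ids, eligible) if e]
    direction = {
        g: (UP_IN_A if a else UP_IN_B)
        for g, e, a in zip(gene_ids, eligible, up_in_a)
        if e
    }
    if not ids:
        logger.debug("select_candidates: empty candidate set")
    return CandidateSet(design=design, gene_ids=ids, direction=direction)


def screen_design(
    values: np.ndarray,
    gene_ids: list[str],
    group_mask: np.ndarray,
    alpha: float = 0.05,
    delta: float = 0.05,
    max_iter: int = 20000,
    tol: float = 1e-8,
    design: TenSampleDesign | None = None,
) -> tuple[CandidateSet, np.ndarray]:
    """Full screen of one design: permutation filter, row centering and
    normalization, EM posteriors, candidate rules.

    Returns the candidate set and the centered/normalized candidate
    sub-matrix (rows in candidate order).
    """
    from .data_model import center_normalize_rows

    keep, _ = permutation_t_filter(values, group_mask, alpha=alpha)
    if not keep.any():
        return CandidateSet(design=design, gene_ids=[], direction={}), np.empty((0, values.shape[1]))
    filt_ids = [g for g, k in zip(gene_ids, keep) if k]
    filt = values[keep]
    normed, _, _ = center_normalize_rows(filt, filt_ids)
    post = fit_em_posteriors(normed, max_iter=max_iter, tol=tol)
    cands = select_candidates(filt_ids, post, group_mask, delta=delta, design=design)
    idx = [filt_ids.index(g) for g in cands.gene_ids]
    return cands, normed[idx]
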