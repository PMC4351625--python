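"""Pairwise per-cytosine differential-methylation testing.

A cytosine is tested between two single samples ("genotypes") when it is
covered by >=4 reads in each and >=2 methylated reads in at least one.
Differential methylation at each eligible position is assessed with a
two-sided Fisher exact test on the 2x2 table of methylated/unmethylated
read counts, followed by Storey-Tibshirani q-values.  Context policies:
CG sites are called DMPs at q < 0.05 over all eligible CG sites; CHG and
CHH use a two-stage rule — only sites with raw p < 0.05 are adjusted, and
a q < 0.035 cutoff is applied within that subset.  Eligible sites not
called are NDMPs; ineligible sites are reported as untested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import MethylomeMatrix

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.95, 0.05), 2)  # 0,0.05,...,0.90


@dataclass(frozen=True)
class FdrPolicy:
    """Per-context multiple-testing policy.

    ``prefilter_p`` of None means the q-values are computed over all
    eligible sites of the context; otherwise only sites with raw
    p < prefilter_p enter the adjustment and the rest are NDMPs outright.
    """

    context: str
    fdr_threshold: float
    prefilter_p: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold outside (0,1)")
        if self.prefilter_p is not None and not 0 < self.prefilter_p < 1:
            raise ValueError("prefilter_p outside (0,1)")


def default_policies() -> dict[str, FdrPolicy]:
    return {
        "CG": FdrPolicy("CG", fdr_threshold=0.05),
        "CHG": FdrPolicy("CHG", fdr_threshold=0.035, prefilter_p=0.05),
        "CHH": FdrPolicy("CHH", fdr_threshold=0.035, prefilter_p=0.05),
    }


def eligible_sites(matrix: MethylomeMatrix, sample_a: str, sample_b: str
                   ) -> np.ndarray:
    """Coverage eligibility: >=4 reads in both samples and >=2 methylated
    reads in at least one."""
    ia, ib = matrix.sample_index(sample_a), matrix.sample_index(sample_b)
    cov_a, cov_b = matrix.cov[:, ia], matrix.cov[:, ib]
    meth_a, meth_b = matrix.meth[:, ia], matrix.meth[:, ib]
    return (cov_a >= 4) & (cov_b >= 4) & ((meth_a >= 2) | (meth_b >= 2))


def fisher_exact_2x2(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int
                     ) -> float:
    """Two-sided Fisher exact p for one 2x2 count table.

    Two-sided by the point-probability rule: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    """
    table = (meth_a, unmeth_a, meth_b, unmeth_b)
    if any(x < 0 for x in table):
        raise ValueError("negative count in 2x2 table")
    if sum(table) == 0:
        raise ValueError("empty 2x2 table")
    return float(stats.fisher_exact(
        [[meth_a, unmeth_a], [meth_b, unmeth_b]], alternative="two-sided")[1])


# tie tolerance of the point-probability rule (tables whose probability is
# within this relative factor of the observed one count as "as extreme")
_TIE_GAMMA = 1.0 + 1e-7


def _fisher_block(uniq: np.ndarray, logfact: np.ndarray) -> np.ndarray:
    """Two-sided p for a block of unique tables by direct hypergeometric
    enumeration over the shared-margin support."""
    ma, ua, mb, ub = (uniq[:, i].astype(np.int64) for i in range(4))
    n1, n2, k = ma + ua, mb + ub, ma + mb
    lo = np.maximum(0, k - n2)
    hi = np.minimum(k, n1)
    width = int((hi - lo).max()) + 1
    a = lo[:, None] + np.arange(width)[None, :]
    valid = a <= hi[:, None]
    a = np.minimum(a, hi[:, None])
    logpmf = (logfact[n1][:, None] - logfact[a] - logfact[n1[:, None] - a]
              + logfact[n2][:, None] - logfact[k[:, None] - a]
              - logfact[(n2 - k)[:, None] + a]
              - (logfact[n1 + n2] - logfact[k]
                 - logfact[n1 + n2 - k])[:, None])
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    pobs = pmf[np.arange(len(uniq)), (ma - lo)]
    p = (pmf * (pmf <= pobs[:, None] * _TIE_GAMMA)).sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_exact_many(meth_a: np.ndarray, unmeth_a: np.ndarray,
                      meth_b: np.ndarray, unmeth_b: np.ndarray,
                      block: int = 20_000) -> np.ndarray:
    """Vectorised two-sided Fisher exact p-values (point-probability rule).

    Identical tables share one computation (read-depth distributions make
    repeats common at genome scale); the hypergeometric support of each
    unique table is enumerated with a log-factorial table.  Agrees with
    ``fisher_exact_2x2`` to ~1e-12 relative error.
    """
    tables = np.column_stack([meth_a, unmeth_a, meth_b, unmeth_b])
    if (tables < 0).any():
        raise ValueError("negative count in 2x2 table")
    if len(tables) == 0:
        return np.empty(0)
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    logfact = special.gammaln(
        np.arange(int(uniq[:, :2].sum(1).max() + uniq[:, 2:].sum(1).max()) + 2,
                  dtype=np.float64) + 1.0)
    p_uniq = np.empty(len(uniq))
    for s in range(0, len(uniq), block):
        p_uniq[s:s + block] = _fisher_block(uniq[s:s + block], logfact)
    return p_uniq[inverse]


def storey_pi0(pvalues: np.ndarray,
               lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 by the Storey-Tibshirani smoother.

    pi0(lambda) = #{p > lambda} / (m (1-lambda)) is smoothed with a cubic
    polynomial over the grid and read off at the largest lambda.  The
    estimate is clipped to (0, 1]; degenerate fits (non-finite or <= 0,
    e.g. when all p-values sit below the grid, as happens after a raw-p
    prefilter) and small inputs (m < 100) fall back to pi0 = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0,1]")
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 0.95:
        raise ValueError("lambda grid must lie within [0, 0.95]")
    if p.size < 100:
        return 1.0
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    if np.all(pi0_lambda == 0):
        return 1.0
    coeffs = np.polyfit(grid, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, grid.max()))
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(pvalues: np.ndarray,
                   lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                   pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values: q_(i) = min_{j>=i} pi0 * m * p_(j) / j.

    Returns (qvalues in input order, pi0 used).  Forcing ``pi0=1``
    reproduces the classic step-up adjustment.  q is monotone
    non-decreasing in p and lies in [0,1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0,1]")
    if pi0 is None:
        pi0 = storey_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def call_dmps(matrix: MethylomeMatrix, sample_a: str, sample_b: str,
              policies: dict[str, FdrPolicy] | None = None,
              lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> pd.DataFrame:
    """Call pairwise DMPs of ``sample_a`` (test) against ``sample_b``
    (reference), per context.

    Returns one row per site with columns: chrom, pos, strand, context,
    meth_a, cov_a, meth_b, cov_b, level_a, level_b, p, q, status
    (DMP/NDMP/untested) and direction (hyper/hypo/none).  "hyper" means the
    test sample is more methylated than the reference.  Every site is
    exactly one of DMP / NDMP / untested.
    """
    policies = policies or default_policies()
    for ctx in ("CG", "CHG", "CHH"):
        if ctx not in policies:
            raise ValueError(f"missing FDR policy for context {ctx}")
    ia, ib = matrix.sample_index(sample_a), matrix.sample_index(sample_b)
    meth_a, cov_a = matrix.meth[:, ia], matrix.cov[:, ia]
    meth_b, cov_b = matrix.meth[:, ib], matrix.cov[:, ib]
    eligible = eligible_sites(matrix, sample_a, sample_b)

    n = matrix.n_sites
    p = np.full(n, np.nan)
    q = np.full(n, np.nan)
    status = np.full(n, "untested", dtype=object)
    status[eligible] = "NDMP"

    for ctx, policy in policies.items():
        mask = matrix.context_mask(ctx) & eligible
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        p[idx] = fisher_exact_many(meth_a[idx], cov_a[idx] - meth_a[idx],
                                   meth_b[idx], cov_b[idx] - meth_b[idx])
        if policy.prefilter_p is None:
            adj_idx = idx
            pi0 = None  # Storey smoother over the genome-wide p-values
        else:
            # within the prefiltered subset the smoother has no support
            # above any lambda, so the step-up adjustment (pi0=1) is used
            adj_idx = idx[p[idx] < policy.prefilter_p]
            pi0 = 1.0
        if adj_idx.size:
            q[adj_idx], _ = storey_qvalues(p[adj_idx], lambda_grid, pi0=pi0)
            sig = adj_idx[q[adj_idx] < policy.fdr_threshold]
            status[sig] = "DMP"

    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(cov_a > 0, meth_a / np.maximum(cov_a, 1), np.nan)
        level_b = np.where(cov_b > 0, meth_b / np.maximum(cov_b, 1), np.nan)
    direction = np.full(n, "none", dtype=object)
    is_dmp = status == "DMP"
    direction[is_dmp & (level_a > level_b)] = "hyper"
    direction[is_dmp & (level_a < level_b)] = "hypo"

    out = matrix.sites[["chrom", "pos", "strand", "context"]].copy()
    out["meth_a"] = meth_a
    out["cov_a"] = cov_a
    out["meth_b"] = meth_b
    out["cov_b"] = cov_b
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["p"] = p
    out["q"] = q
    out["status"] = status
    out["direction"] = direction
    out.attrs["sample_a"] = sample_a
    out.attrs["sample_b"] = sample_b
    return out
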