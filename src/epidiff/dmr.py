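"""Group-wise differentially methylated region (DMR) detection and
fixed-width tiling-window methylation levels.

The region caller is a transparent substitute for smoothed beta-regression
approaches: candidate regions are maximal runs of well-covered same-context
sites (gap- and coverage-bounded), each candidate is tested by a two-sided
Fisher exact test on the group-pooled methylated/unmethylated read totals,
p-values are step-up adjusted across candidates, and a minimum group-mean
difference gates significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmp import fisher_exact_many, storey_qvalues
from .matrix import MethylomeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmrParams:
    min_coverage: int = 4
    min_fraction_samples: float = 0.75
    max_gap: int = 100
    min_sites: int = 5
    fdr: float = 0.05
    min_diff: float = 0.1


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    context: str
    site_indices: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


def cluster_sites(matrix: MethylomeMatrix, context: str,
                  min_coverage: int = 4, min_fraction_samples: float = 0.75,
                  max_gap: int = 100, min_sites: int = 5
                  ) -> list[CandidateRegion]:
    """Maximal runs of qualifying same-context sites.

    A site qualifies when its coverage is >= min_coverage in at least
    min_fraction_samples of the samples; runs break where consecutive
    qualifying sites are more than max_gap bp apart, and runs shorter than
    min_sites are dropped.  Returned regions are disjoint and sorted.
    """
    if min(min_coverage, max_gap, min_sites) <= 0 or min_fraction_samples <= 0:
        raise ValueError("cluster parameters must be positive")
    ok = (matrix.cov >= min_coverage).mean(axis=1) >= min_fraction_samples
    ok &= matrix.context_mask(context)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    chroms = matrix.sites["chrom"].to_numpy()[idx]
    pos = matrix.sites["pos"].to_numpy()[idx]
    regions: list[CandidateRegion] = []
    breaks = np.flatnonzero(
        (chroms[1:] != chroms[:-1]) | (np.diff(pos) > max_gap))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_sites:
            regions.append(CandidateRegion(
                chrom=str(chroms[s]), start=int(pos[s]), end=int(pos[e]),
                context=context, site_indices=idx[s:e + 1]))
    return regions


def call_group_dmrs(matrix: MethylomeMatrix, groups: dict[str, str],
                    context: str, params: DmrParams = DmrParams()
                    ) -> pd.DataFrame:
    """Test candidate regions for group-wise differential methylation.

    ``groups`` maps sample name -> group name; exactly two groups are
    contrasted.  Per candidate: per-sample level = pooled meth/cov over the
    region's sites; group mean = mean of member levels; the test is a
    two-sided Fisher exact test on group-pooled (meth, unmeth) totals.
    Step-up adjustment (pi0=1) runs across all candidates; significance
    requires q < fdr AND |group mean difference| >= min_diff.  All
    candidates are returned with a status flag.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("call_group_dmrs contrasts exactly two groups; "
                         f"got {group_names}")
    cols: dict[str, list[int]] = {g: [] for g in group_names}
    for sample, g in groups.items():
        cols[g].append(matrix.sample_index(sample))
    if any(len(v) == 0 for v in cols.values()):
        raise ValueError("each group needs at least one sample")

    candidates = cluster_sites(
        matrix, context, params.min_coverage, params.min_fraction_samples,
        params.max_gap, params.min_sites)
    rows = []
    for reg in candidates:
        sl = reg.site_indices
        meth = matrix.meth[sl]
        cov = matrix.cov[sl]
        sample_levels = {}
        group_means = {}
        pooled = {}
        skip = False
        for g, js in cols.items():
            levels = []
            for j in js:
                c = cov[:, j].sum()
                levels.append(meth[:, j].sum() / c if c > 0 else np.nan)
            for s, j in zip([s for s, gg in groups.items() if gg == g], js):
                sample_levels[s] = meth[:, j].sum() / max(cov[:, j].sum(), 1)
            gm = meth[:, js].sum()
            gc = cov[:, js].sum()
            if gc == 0:
                skip = True
                break
            pooled[g] = (int(gm), int(gc - gm))
            group_means[g] = float(np.nanmean(levels))
        if skip:
            logger.warning("region %s:%d-%d skipped: a group has zero coverage",
                           reg.chrom, reg.start, reg.end)
            continue
        g1, g2 = group_names
        rows.append({
            "chrom": reg.chrom, "start": reg.start, "end": reg.end,
            "context": context, "n_sites": reg.n_sites,
            "meth_1": pooled[g1][0], "unmeth_1": pooled[g1][1],
            "meth_2": pooled[g2][0], "unmeth_2": pooled[g2][1],
            f"mean_{g1}": group_means[g1], f"mean_{g2}": group_means[g2],
            "mean_diff": group_means[g1] - group_means[g2],
            **{f"level_{s}": v for s, v in sample_levels.items()},
        })
    out = pd.DataFrame(rows)
    if out.empty:
        out["p"] = out["q"] = out["status"] = []
        return out
    out["p"] = fisher_exact_many(
        out["meth_1"].to_numpy(), out["unmeth_1"].to_numpy(),
        out["meth_2"].to_numpy(), out["unmeth_2"].to_numpy())
    out["q"], _ = storey_qvalues(out["p"].to_numpy(), pi0=1.0)
    sig = (out["q"] < params.fdr) & (out["mean_diff"].abs() >= params.min_diff)
    out["status"] = np.where(sig, "significant", "not_significant")
    out.attrs["groups"] = group_names
    return out


def tiling_methylation(matrix: MethylomeMatrix,
                       chrom_sizes: dict[str, int],
                       window: int = 340, min_sites: int = 20,
                       contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
                       min_coverage: int = 1) -> pd.DataFrame:
    """Per-sample methylation levels in fixed tiling windows.

    The genome is partitioned into consecutive ``window``-bp windows from
    position 1.  A site counts as covered when its coverage is
    >= min_coverage in every sample; windows with at least ``min_sites``
    covered sites (over the selected contexts) emit per-sample pooled
    levels, the rest are dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ctx_mask = matrix.sites["context"].isin(contexts).to_numpy()
    covered = ctx_mask & (matrix.cov >= min_coverage).all(axis=1)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom, size in chrom_sizes.items():
        n_windows = int(np.ceil(size / window))
        in_chrom = covered & (chrom_arr == chrom)
        widx = (pos_arr[in_chrom] - 1) // window
        meth = matrix.meth[in_chrom]
        cov = matrix.cov[in_chrom]
        for w in range(n_windows):
            sel = widx == w
            n_cov = int(sel.sum())
            if n_cov < min_sites:
                continue
            row = {"chrom": chrom, "start": w * window + 1,
                   "end": min((w + 1) * window, size),
                   "n_covered_sites": n_cov}
            m = meth[sel].sum(axis=0)
            c = cov[sel].sum(axis=0)
            for j, s in enumerate(matrix.samples):
                row[f"level_{s}"] = m[j] / c[j] if c[j] > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
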