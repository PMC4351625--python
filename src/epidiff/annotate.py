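"""Assign DMPs to genomic features and build summary statistics:
strand-oriented boundary-bin metaprofiles, chromosomal density tracks and
the TE-gene enrichment test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dmp import fisher_exact_2x2
from .formats_io import GenomeAnnotation

logger = logging.getLogger(__name__)

# containment tie-break priority (higher wins), then smaller interval
KIND_PRIORITY = {"te_gene": 3, "transposon": 2, "gene": 1}


def _effective_kind(kind: str, has_te_gene: bool) -> str:
    return "te_gene" if (kind == "transposon" and has_te_gene) else kind


def _oriented_offsets(pos: int, start: int, end: int, strand: str
                      ) -> tuple[int, int]:
    """Signed offsets to the feature's biological start and end.

    Negative means upstream of the respective boundary in the feature's
    reading direction; unstranded features are treated as '+'.
    """
    if strand == "-":
        return end - pos, start - pos
    return pos - start, pos - end


def assign_features(dmps: pd.DataFrame, annotation: GenomeAnnotation
                    ) -> pd.DataFrame:
    """Label each DMP with its containing feature, or the nearest one.

    Containment ties resolve by kind priority (te_gene > transposon > gene)
    then by smallest interval; otherwise the nearest feature by edge
    distance wins.  Adds columns feature_id, feature_kind (gene /
    transposon / te_gene / other), offset_start, offset_end (strand
    oriented; upstream negative).  DMPs on chromosomes without features are
    left unassigned with kind "other".
    """
    feats = annotation.features
    by_chrom: dict[str, list] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)

    n = len(dmps)
    feature_id = np.full(n, None, dtype=object)
    feature_kind = np.full(n, "other", dtype=object)
    off_start = np.full(n, np.nan)
    off_end = np.full(n, np.nan)

    missing_chroms = set()
    chrom_arr = dmps["chrom"].to_numpy()
    pos_arr = dmps["pos"].to_numpy()
    for i in range(n):
        chrom, pos = chrom_arr[i], int(pos_arr[i])
        flist = by_chrom.get(chrom)
        if not flist:
            missing_chroms.add(chrom)
            continue
        containing = [f for f in flist if f.start <= pos <= f.end]
        if containing:
            best = max(containing, key=lambda f: (
                KIND_PRIORITY[_effective_kind(f.kind, f.has_te_gene)],
                -(f.end - f.start)))
        else:
            best = min(flist, key=lambda f: (
                max(f.start - pos, pos - f.end),
                -KIND_PRIORITY[_effective_kind(f.kind, f.has_te_gene)],
                f.id))
        feature_id[i] = best.id
        feature_kind[i] = _effective_kind(best.kind, best.has_te_gene)
        off_start[i], off_end[i] = _oriented_offsets(
            pos, best.start, best.end, best.strand)
    if missing_chroms:
        logger.warning("DMPs on chromosomes without annotation: %s",
                       sorted(missing_chroms))
    out = dmps.copy()
    out["feature_id"] = feature_id
    out["feature_kind"] = feature_kind
    out["offset_start"] = off_start
    out["offset_end"] = off_end
    return out


def _bin_required_length(anchor: str, lo: int, hi: int) -> int:
    """Feature length needed to fully host a bin's offset interval.

    For the start anchor, interior bins (lo >= 0) need length >= hi;
    for the end anchor, interior bins (lo < 0) need length >= -lo.
    External (upstream/downstream) bins need nothing (return 0).
    """
    if anchor == "start":
        return hi if lo >= 0 else 0
    return -lo if lo < 0 else 0


def boundary_profile(annotated_dmps: pd.DataFrame,
                     annotation: GenomeAnnotation,
                     bin_width: int = 100, span: int = 2000,
                     group_cols: tuple[str, ...] = ("context",),
                     length_denominator: str = "features") -> pd.DataFrame:
    """DMP frequencies in fixed bins around feature starts and ends.

    For every group (by default per context) x feature kind x anchor, raw
    DMP counts are histogrammed into ``2*span/bin_width`` bins of
    ``bin_width`` bp covering offsets [-span, span).  Each interior bin's
    count is divided by the proportion of features (or of DMP-bearing
    features, with ``length_denominator='dmp_features'``) long enough to
    host it; external bins are left as is.  Finally all length-adjusted
    values in the returned set are scaled by their joint maximum, so the
    profile maximum is exactly 1 (all-zero input stays all zero).
    """
    if span % bin_width != 0:
        raise ValueError("bin_width must divide span")
    if not annotation.features:
        raise ValueError("no features to profile against")
    n_bins = 2 * span // bin_width
    feats = annotation.features_frame()
    feats["feature_kind"] = [
        _effective_kind(k, t) for k, t in zip(feats["kind"],
                                              feats["has_te_gene"])]
    feats["length"] = feats["end"] - feats["start"] + 1

    mapped = annotated_dmps[annotated_dmps["feature_id"].notna()]
    rows = []
    group_iter = (mapped.groupby(list(group_cols) + ["feature_kind"])
                  if len(mapped) else [])
    for key, sub in group_iter:
        *gvals, kind = key if isinstance(key, tuple) else (key,)
        if length_denominator == "features":
            lengths = feats.loc[feats["feature_kind"] == kind, "length"]
        elif length_denominator == "dmp_features":
            ids = sub["feature_id"].unique()
            lengths = feats.loc[feats["id"].isin(ids), "length"]
        else:
            raise ValueError(f"unknown denominator {length_denominator!r}")
        if lengths.empty:
            raise ValueError(f"zero mapped features for kind {kind!r}")
        lengths = lengths.to_numpy()
        for anchor, col in (("start", "offset_start"), ("end", "offset_end")):
            offsets = sub[col].to_numpy()
            in_span = (offsets >= -span) & (offsets < span)
            bins = np.floor((offsets[in_span] + span) / bin_width).astype(int)
            raw = np.bincount(bins, minlength=n_bins).astype(float)
            for b in range(n_bins):
                lo = b * bin_width - span
                hi = lo + bin_width
                req = _bin_required_length(anchor, lo, hi)
                prop = (lengths >= req).mean() if req > 0 else 1.0
                adj = raw[b] / prop if prop > 0 else 0.0
                rows.append({
                    **dict(zip(group_cols, gvals)),
                    "feature_kind": kind, "anchor": anchor, "bin": b,
                    "offset_lo": lo, "offset_hi": hi,
                    "raw": raw[b], "length_adjusted": adj,
                })
    prof = pd.DataFrame(rows, columns=list(group_cols) + [
        "feature_kind", "anchor", "bin", "offset_lo", "offset_hi",
        "raw", "length_adjusted"])
    peak = prof["length_adjusted"].max() if len(prof) else 0.0
    prof["scaled"] = prof["length_adjusted"] / peak if peak > 0 else 0.0
    return prof


def chromosome_density(dmps: pd.DataFrame, ndmps: pd.DataFrame,
                       chrom_sizes: dict[str, int], window: int
                       ) -> pd.DataFrame:
    """Per-window DMP and NDMP counts, all chromosomes on one scale.

    Each track is normalised by its own genome-wide maximum window count
    within the comparison, so the densest window scores 1.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        edges = np.arange(0, size + window, window)
        d_pos = dmps.loc[dmps["chrom"] == chrom, "pos"].to_numpy()
        n_pos = ndmps.loc[ndmps["chrom"] == chrom, "pos"].to_numpy()
        d_counts = np.histogram(d_pos, bins=edges)[0]
        n_counts = np.histogram(n_pos, bins=edges)[0]
        for k in range(len(edges) - 1):
            rows.append({"chrom": chrom, "start": int(edges[k]) + 1,
                         "end": int(min(edges[k + 1], size)),
                         "dmp_count": int(d_counts[k]),
                         "ndmp_count": int(n_counts[k])})
    track = pd.DataFrame(rows)
    for col in ("dmp_count", "ndmp_count"):
        peak = track[col].max() if len(track) else 0
        track[col.replace("_count", "_norm")] = (
            track[col] / peak if peak > 0 else 0.0)
    return track


def te_gene_enrichment(dmr_associated_tes: set[str],
                       all_tes: pd.DataFrame) -> tuple[float, float]:
    """Fisher test of TE-gene content among DMR-associated transposons.

    ``all_tes`` needs columns ``id`` and ``has_te_gene``.  Returns
    (odds ratio, two-sided p) for the 2x2 table (DMR-associated vs not) x
    (contains TE gene vs not); the odds ratio is ad/bc with inf allowed.
    """
    if len(all_tes) == 0 or len(dmr_associated_tes) == 0:
        raise ValueError("empty transposon sets")
    unknown = dmr_associated_tes - set(all_tes["id"])
    if unknown:
        raise ValueError(f"DMR-associated TEs not in annotation: {sorted(unknown)[:5]}")
    assoc = all_tes["id"].isin(dmr_associated_tes).to_numpy()
    flag = all_tes["has_te_gene"].to_numpy().astype(bool)
    a = int((assoc & flag).sum())
    b = int((assoc & ~flag).sum())
    c = int((~assoc & flag).sum())
    d = int((~assoc & ~flag).sum())
    p = fisher_exact_2x2(a, b, c, d)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), p
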