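"""Synthetic methylome simulator with planted, recorded differential truth.

The generator emulates the structure of a small plant methylome: a few
chromosomes whose arms carry genes and whose pericentromeres are enriched
for transposons (a configurable fraction of which contain a TE gene);
cytosine sites in CG/CHG/CHH contexts at class-specific densities;
negative-binomial read coverage; and binomial methylated counts around
context- and feature-class-specific baselines.

Group profiles plant two kinds of differential signal on top of the
baselines, and every planted effect is recorded as ground truth:

* scattered site effects ("DMP-style"): a fraction of the in-scope sites is
  shifted by +-delta — emulating, e.g., non-CG hypermethylation of
  pericentromeric transposons in a mutant, or genome-wide genic CG change
  together with transposon CG hypomethylation / CHH hypermethylation in an
  epigenetically reprogrammed line;
* region effects ("DMR-style"): whole features have every site of one
  context shifted by +-delta for all samples of a group.

Counts are drawn per sample with no biological replicate structure beyond
group membership, matching single-plant pairwise designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (FeatureInterval, GenomeAnnotation,
                         write_annotation_bed, write_centromeres,
                         write_chrom_sizes, write_table)
from .matrix import MethylomeMatrix

FEATURE_CLASSES = ("gene", "transposon", "intergenic")

# per-bp cytosine site rates by context and feature class; transposons are
# the densest compartment in the non-CG contexts
DEFAULT_SITE_DENSITY = {
    "CG": {"gene": 0.06, "transposon": 0.04, "intergenic": 0.010},
    "CHG": {"gene": 0.010, "transposon": 0.06, "intergenic": 0.003},
    "CHH": {"gene": 0.020, "transposon": 0.08, "intergenic": 0.010},
}

# baseline methylation level by feature class and context
DEFAULT_BASELINES = {
    "gene": {"CG": 0.20, "CHG": 0.05, "CHH": 0.03},
    "transposon": {"CG": 0.85, "CHG": 0.60, "CHH": 0.15},
    "intergenic": {"CG": 0.05, "CHG": 0.05, "CHH": 0.05},
}

LEVEL_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class SiteEffect:
    """Shift a random fraction of in-scope sites by delta (per group).

    ``te_gene_bias`` > 1 concentrates the planted sites in transposons
    that contain a TE gene (higher per-site selection weight).
    """

    context: str
    feature_class: str  # gene | transposon | intergenic | any
    delta: float        # signed; + hyper, - hypo relative to baseline
    region: str = "any"  # any | pericentromeric | arm
    fraction: float | None = None  # None -> config.dmp_fraction
    te_gene_bias: float = 1.0


@dataclass(frozen=True)
class RegionEffect:
    """Shift every in-context site of n_regions whole features by delta.

    ``te_gene_bias`` > 1 makes transposons that contain a TE gene
    proportionally more likely to be chosen as affected regions, emulating
    the preferential epigenetic modulation of TE genes.
    """

    context: str
    feature_class: str
    delta: float
    n_regions: int
    region: str = "any"
    min_sites: int = 10
    te_gene_bias: float = 1.0


@dataclass(frozen=True)
class GroupProfile:
    name: str
    n_samples: int
    site_effects: tuple[SiteEffect, ...] = ()
    region_effects: tuple[RegionEffect, ...] = ()


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    pericentromere_halfwidth: int = 150_000
    n_genes: int = 200
    gene_length: tuple[int, int] = (1_000, 4_000)
    n_transposons: int = 150
    te_length: tuple[int, int] = (800, 3_000)
    te_gene_fraction: float = 0.6
    te_pericentromeric_fraction: float = 0.8
    min_feature_spacing: int = 600
    site_density: dict = field(
        default_factory=lambda: {c: dict(d) for c, d in
                                 DEFAULT_SITE_DENSITY.items()})
    baselines: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_BASELINES.items()})
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    dmp_fraction: float = 0.10
    group_profiles: tuple[GroupProfile, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.te_gene_fraction <= 1:
            raise ValueError("te_gene_fraction outside [0,1]")
        if not 0 <= self.dmp_fraction <= 1:
            raise ValueError("dmp_fraction outside [0,1]")
        for cls, ctxs in self.baselines.items():
            for ctx, level in ctxs.items():
                if not 0 <= level <= 1:
                    raise ValueError(f"baseline {cls}/{ctx}={level} outside [0,1]")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if not self.group_profiles:
            self.group_profiles = default_group_profiles()


def default_group_profiles() -> tuple[GroupProfile, ...]:
    """The default three-group study design.

    ``wildtype`` is the reference.  ``mutant`` carries non-CG
    hypermethylation confined to pericentromeric transposons (scattered
    sites plus whole-transposon CHG regions).  ``epi`` carries genome-wide
    genic CG hypermethylation, transposon CG hypomethylation and transposon
    CHH hypermethylation, plus whole-gene CG regions.
    """
    return (
        GroupProfile("wildtype", 3),
        GroupProfile(
            "mutant", 3,
            site_effects=(
                SiteEffect("CHG", "transposon", +0.35,
                           region="pericentromeric", te_gene_bias=4.0),
                SiteEffect("CHH", "transposon", +0.40,
                           region="pericentromeric", te_gene_bias=4.0),
            ),
            region_effects=(
                RegionEffect("CHG", "transposon", +0.35, n_regions=15,
                             region="pericentromeric", te_gene_bias=4.0),
            ),
        ),
        GroupProfile(
            "epi", 3,
            site_effects=(
                SiteEffect("CG", "gene", +0.60),
                SiteEffect("CG", "transposon", -0.60, te_gene_bias=4.0),
                SiteEffect("CHH", "transposon", +0.40, te_gene_bias=4.0),
            ),
            region_effects=(
                RegionEffect("CG", "gene", +0.50, n_regions=15),
                RegionEffect("CG", "transposon", -0.50, n_regions=10,
                             te_gene_bias=4.0),
            ),
        ),
    )


@dataclass
class SimulationTruth:
    """Planted differential-methylation ground truth."""

    planted_dmps: pd.DataFrame   # chrom,pos,strand,context,group,direction,delta,source
    planted_dmrs: pd.DataFrame   # chrom,start,end,context,group,delta,n_sites
    profile_labels: dict[str, str]
    group_levels: pd.DataFrame   # per-site true level per group (pre-noise)


def _place_features(rng: np.random.Generator, cfg: SimulationConfig,
                    chroms: list[str], centromeres: dict[str, int]
                    ) -> list[FeatureInterval]:
    """Rejection-sample non-overlapping features; genes on arms, transposons
    concentrated in the pericentromere."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    feats: list[FeatureInterval] = []
    hw = cfg.pericentromere_halfwidth
    L = cfg.chrom_length

    def fits(chrom: str, start: int, end: int) -> bool:
        pad = cfg.min_feature_spacing
        return all(end + pad < s or start - pad > e
                   for s, e in occupied[chrom])

    def place(kind: str, idx: int, length: int) -> FeatureInterval:
        for _ in range(2000):
            chrom = chroms[rng.integers(len(chroms))]
            cent = centromeres[chrom]
            if kind == "gene":
                # arms only
                left_arm = cent - hw - length - 1
                right_lo = cent + hw + 1
                if left_arm < 1 and right_lo + length > L:
                    continue
                if left_arm >= 1 and (right_lo + length > L or rng.random() < 0.5):
                    start = int(rng.integers(1, left_arm + 1))
                else:
                    start = int(rng.integers(right_lo, L - length + 1))
            else:
                if rng.random() < cfg.te_pericentromeric_fraction:
                    lo = max(1, cent - hw)
                    hi = min(L - length, cent + hw)
                else:
                    lo, hi = 1, L - length
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            end = start + length - 1
            if 1 <= start and end <= L and fits(chrom, start, end):
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                return FeatureInterval(chrom, start, end, strand, kind,
                                       f"{kind}_{idx:04d}")
        raise ValueError(f"could not place {kind} of length {length}; "
                         "features cannot fit in the genome")

    gene_lengths = rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1,
                                size=cfg.n_genes)
    te_lengths = rng.integers(cfg.te_length[0], cfg.te_length[1] + 1,
                              size=cfg.n_transposons)
    for i in range(cfg.n_genes):
        feats.append(place("gene", i, int(gene_lengths[i])))
    te_flags = rng.random(cfg.n_transposons) < cfg.te_gene_fraction
    for i in range(cfg.n_transposons):
        te = place("transposon", i, int(te_lengths[i]))
        te.has_te_gene = bool(te_flags[i])
        feats.append(te)
    feats.sort(key=lambda f: (f.chrom, f.start))
    return feats


def build_toy_genome(config: SimulationConfig
                     ) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Build the annotation and the cytosine site scaffold.

    Returns the annotation plus a site table with one row per
    (chrom,pos,strand) carrying context, feature class (gene / transposon /
    intergenic), the enclosing feature id, a TE-gene flag and a
    pericentromere flag.  Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    chroms = [f"Chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    cents = {c: config.chrom_length // 2 for c in chroms}
    feats = _place_features(rng, config, chroms, cents)
    ann = GenomeAnnotation(sizes, cents, feats)

    rows = []
    for chrom in chroms:
        segments: list[tuple[int, int, str, str, bool]] = []
        cursor = 1
        for f in (g for g in feats if g.chrom == chrom):
            if f.start > cursor:
                segments.append((cursor, f.start - 1, "intergenic", "", False))
            segments.append((f.start, f.end, f.kind, f.id, f.has_te_gene))
            cursor = f.end + 1
        if cursor <= sizes[chrom]:
            segments.append((cursor, sizes[chrom], "intergenic", "", False))
        for start, end, cls, fid, te_gene in segments:
            seg_len = end - start + 1
            for ctx in ("CG", "CHG", "CHH"):
                dens = config.site_density[ctx][cls if cls != "te_gene" else
                                                "transposon"]
                n = rng.binomial(seg_len, min(dens, 1.0))
                if n == 0:
                    continue
                pos = np.sort(rng.choice(seg_len, size=n, replace=False)) + start
                strand = np.where(rng.random(n) < 0.5, "+", "-")
                rows.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos, "strand": strand,
                    "context": ctx, "feature_class": cls, "feature_id": fid,
                    "has_te_gene": te_gene,
                }))
    sites = pd.concat(rows, ignore_index=True)
    sites = sites.drop_duplicates(["chrom", "pos", "strand"]) \
        .sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    cent_pos = sites["chrom"].map(cents)
    sites["pericentromeric"] = (
        (sites["pos"] - cent_pos).abs() <= config.pericentromere_halfwidth)
    return ann, sites


def _effect_scope(sites: pd.DataFrame, context: str, feature_class: str,
                  region: str) -> np.ndarray:
    mask = (sites["context"] == context).to_numpy()
    if feature_class != "any":
        mask &= (sites["feature_class"] == feature_class).to_numpy()
    if region == "pericentromeric":
        mask &= sites["pericentromeric"].to_numpy()
    elif region == "arm":
        mask &= ~sites["pericentromeric"].to_numpy()
    elif region != "any":
        raise ValueError(f"unknown region scope {region!r}")
    return mask


def simulate_samples(annotation: GenomeAnnotation, sites: pd.DataFrame,
                     config: SimulationConfig
                     ) -> tuple[MethylomeMatrix, SimulationTruth]:
    """Draw per-sample counts around the planted group-level truth.

    Coverage is negative-binomial (mean ``coverage_mean``, dispersion
    ``coverage_dispersion``); methylated counts are binomial at the site's
    group-level true methylation level.  meth <= coverage by construction.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    n_sites = len(sites)

    base = np.empty(n_sites)
    for cls in FEATURE_CLASSES:
        for ctx in ("CG", "CHG", "CHH"):
            m = (sites["feature_class"] == cls).to_numpy() & \
                (sites["context"] == ctx).to_numpy()
            base[m] = config.baselines[cls][ctx]

    groups = [p.name for p in config.group_profiles]
    levels = np.tile(base[:, None], (1, len(groups)))
    dmp_rows, dmr_rows = [], []
    for gi, prof in enumerate(config.group_profiles):
        for eff in prof.site_effects:
            scope = _effect_scope(sites, eff.context, eff.feature_class,
                                  eff.region)
            idx = np.flatnonzero(scope)
            frac = config.dmp_fraction if eff.fraction is None else eff.fraction
            n_pick = int(round(frac * len(idx)))
            if n_pick == 0 or eff.delta == 0:
                continue
            w = np.where(sites["has_te_gene"].to_numpy()[idx],
                         eff.te_gene_bias, 1.0)
            picked = rng.choice(idx, size=n_pick, replace=False,
                                p=w / w.sum())
            levels[picked, gi] = np.clip(levels[picked, gi] + eff.delta,
                                         *LEVEL_CLIP)
            sel = sites.iloc[picked]
            dmp_rows.append(pd.DataFrame({
                "chrom": sel["chrom"].to_numpy(),
                "pos": sel["pos"].to_numpy(),
                "strand": sel["strand"].to_numpy(),
                "context": eff.context, "group": prof.name,
                "direction": "hyper" if eff.delta > 0 else "hypo",
                "delta": eff.delta, "source": "site",
            }))
        for eff in prof.region_effects:
            feats = [f for f in annotation.features
                     if f.kind == eff.feature_class or
                     (eff.feature_class == "any")]
            if eff.region == "pericentromeric":
                feats = [f for f in feats
                         if abs((f.start + f.end) // 2 -
                                annotation.centromeres[f.chrom])
                         <= config.pericentromere_halfwidth]
            candidates = []
            for f in feats:
                in_feat = (sites["feature_id"] == f.id).to_numpy() & \
                          (sites["context"] == eff.context).to_numpy()
                if in_feat.sum() >= eff.min_sites:
                    candidates.append((f, np.flatnonzero(in_feat)))
            if len(candidates) < eff.n_regions:
                raise ValueError(
                    f"group {prof.name}: only {len(candidates)} features with "
                    f">={eff.min_sites} {eff.context} sites for a "
                    f"{eff.n_regions}-region effect")
            weights = np.array([eff.te_gene_bias if f.has_te_gene else 1.0
                                for f, _ in candidates])
            chosen = rng.choice(len(candidates), size=eff.n_regions,
                                replace=False, p=weights / weights.sum())
            for ci in chosen:
                f, idx = candidates[ci]
                levels[idx, gi] = np.clip(levels[idx, gi] + eff.delta,
                                          *LEVEL_CLIP)
                dmr_rows.append({
                    "chrom": f.chrom, "start": f.start, "end": f.end,
                    "context": eff.context, "group": prof.name,
                    "delta": eff.delta, "n_sites": len(idx),
                })
                sel = sites.iloc[idx]
                dmp_rows.append(pd.DataFrame({
                    "chrom": sel["chrom"].to_numpy(),
                    "pos": sel["pos"].to_numpy(),
                    "strand": sel["strand"].to_numpy(),
                    "context": eff.context, "group": prof.name,
                    "direction": "hyper" if eff.delta > 0 else "hypo",
                    "delta": eff.delta, "source": "region",
                }))

    sample_names, sample_group_idx = [], []
    for gi, prof in enumerate(config.group_profiles):
        for k in range(prof.n_samples):
            sample_names.append(f"{prof.name}_{k + 1}")
            sample_group_idx.append(gi)

    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    cov = rng.negative_binomial(r, p_nb, size=(n_sites, len(sample_names)))
    meth = np.empty_like(cov)
    for j, gi in enumerate(sample_group_idx):
        meth[:, j] = rng.binomial(cov[:, j], levels[:, gi])

    matrix = MethylomeMatrix(
        sites.reset_index(drop=True), sample_names,
        meth.astype(np.int64), cov.astype(np.int64))
    dmp_cols = ["chrom", "pos", "strand", "context", "group", "direction",
                "delta", "source"]
    truth = SimulationTruth(
        planted_dmps=(pd.concat(dmp_rows, ignore_index=True)
                      if dmp_rows else pd.DataFrame(columns=dmp_cols)),
        planted_dmrs=pd.DataFrame(
            dmr_rows, columns=["chrom", "start", "end", "context", "group",
                               "delta", "n_sites"]),
        profile_labels={s: groups[gi]
                        for s, gi in zip(sample_names, sample_group_idx)},
        group_levels=pd.DataFrame(levels, columns=groups),
    )
    return matrix, truth


def simulate_study(config: SimulationConfig
                   ) -> tuple[GenomeAnnotation, MethylomeMatrix, SimulationTruth]:
    """Convenience wrapper: genome + samples in one call."""
    ann, sites = build_toy_genome(config)
    matrix, truth = simulate_samples(ann, sites, config)
    return ann, matrix, truth


def write_study(out_dir: str, annotation: GenomeAnnotation,
                matrix: MethylomeMatrix, truth: SimulationTruth) -> None:
    """Emit the study as standard files only: per-sample cytosine reports,
    BED annotation, chrom sizes / centromeres, a groups table and truth
    tables — so the rest of the pipeline consumes nothing bespoke."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    matrix.to_reports(os.path.join(out_dir, "reports"))
    write_annotation_bed(annotation.features,
                         os.path.join(out_dir, "annotation.bed"))
    write_chrom_sizes(annotation.chrom_sizes,
                      os.path.join(out_dir, "chrom_sizes.tsv"))
    write_centromeres(annotation.centromeres,
                      os.path.join(out_dir, "centromeres.tsv"))
    groups = pd.DataFrame(
        {"sample": list(truth.profile_labels),
         "group": list(truth.profile_labels.values())})
    write_table(groups, os.path.join(out_dir, "groups.tsv"))
    write_table(truth.planted_dmps, os.path.join(out_dir, "truth_dmps.tsv"))
    write_table(truth.planted_dmrs, os.path.join(out_dir, "truth_dmrs.tsv"))


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration (all groups identical to wild type)."""
    profiles = (GroupProfile("wildtype", 1), GroupProfile("null", 1))
    cfg = SimulationConfig(group_profiles=profiles, **overrides)
    return cfg


def dmr_power_config(delta: float = 0.5, n_regions: int = 15,
                     n_per_group: int = 3, **overrides) -> SimulationConfig:
    """Two groups with whole-feature region effects only: CG-hypermethylated
    genes and CG-hypomethylated transposons in the altered group.  Used for
    region-caller power experiments."""
    profiles = (
        GroupProfile("wildtype", n_per_group),
        GroupProfile("altered", n_per_group, region_effects=(
            RegionEffect("CG", "gene", +delta, n_regions=n_regions),
            RegionEffect("CHG", "transposon", -delta, n_regions=n_regions),
        )),
    )
    return SimulationConfig(group_profiles=profiles, **overrides)


def three_group_region_config(delta: float = 0.5, n_regions: int = 12,
                              n_per_group: int = 3, **overrides
                              ) -> SimulationConfig:
    """Three groups distinguished purely by planted region effects, for
    discrimination experiments: the mutant-like group carries CHG
    transposon regions, the epi-like group CG gene regions."""
    profiles = (
        GroupProfile("wildtype", n_per_group),
        GroupProfile("mutant", n_per_group, region_effects=(
            RegionEffect("CHG", "transposon", +0.35, n_regions=n_regions,
                         region="pericentromeric"),)),
        GroupProfile("epi", n_per_group, region_effects=(
            RegionEffect("CG", "gene", +delta, n_regions=n_regions),
            RegionEffect("CG", "transposon", -delta,
                         n_regions=max(2, n_regions // 2)),)),
    )
    return SimulationConfig(group_profiles=profiles, **overrides)
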