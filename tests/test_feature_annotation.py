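import numpy as np
import pandas as pd
import pytest

from epidiff.annotate import (assign_features, boundary_profile,
                              chromosome_density, te_gene_enrichment)
from epidiff.formats_io import FeatureInterval, GenomeAnnotation


def ann_of(features, size=2_000_000):
    chroms = {f.chrom for f in features} or {"Chr1"}
    return GenomeAnnotation({c: size for c in chroms}, {}, list(features))


def dmps_at(positions, chrom="Chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "strand": "+", "context": "CG"})


class TestAssignFeatures:
    def test_containment_and_offset(self):
        ann = ann_of([FeatureInterval("Chr1", 1000, 2000, "+", "gene", "g1")])
        out = assign_features(dmps_at([1500]), ann)
        row = out.iloc[0]
        assert row["feature_id"] == "g1" and row["feature_kind"] == "gene"
        assert row["offset_start"] == 500

    def test_upstream_offset_is_negative(self):
        ann = ann_of([FeatureInterval("Chr1", 1000, 2000, "+", "gene", "g1")])
        assert assign_features(dmps_at([900]), ann).iloc[0]["offset_start"] == -100

    def test_minus_strand_orientation(self):
        # biological start of a minus-strand gene is its right edge
        ann = ann_of([FeatureInterval("Chr1", 1000, 2000, "-", "gene", "g1")])
        row = assign_features(dmps_at([2100]), ann).iloc[0]
        assert row["offset_start"] == -100

    def test_te_gene_priority_over_plain_feature(self):
        ann = ann_of([
            FeatureInterval("Chr1", 1000, 3000, "+", "gene", "g1"),
            FeatureInterval("Chr1", 1500, 2500, "+", "transposon", "te1",
                            has_te_gene=True)])
        row = assign_features(dmps_at([2000]), ann).iloc[0]
        assert row["feature_kind"] == "te_gene" and row["feature_id"] == "te1"

    def test_unannotated_chromosome_left_unassigned(self):
        ann = ann_of([FeatureInterval("Chr1", 10, 20, "+", "gene", "g1")])
        out = assign_features(dmps_at([5], chrom="Chr9"), ann)
        assert out.iloc[0]["feature_kind"] == "other"
        assert out.iloc[0]["feature_id"] is None

    def test_agrees_with_brute_force_nearest_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            feats = []
            cursor = 1
            for i in range(int(rng.integers(2, 8))):
                cursor += int(rng.integers(50, 500))
                length = int(rng.integers(50, 400))
                kind = "gene" if rng.random() < 0.5 else "transposon"
                feats.append(FeatureInterval(
                    "Chr1", cursor, cursor + length,
                    "+" if rng.random() < 0.5 else "-", kind,
                    f"f{i}", has_te_gene=(kind == "transposon" and
                                          rng.random() < 0.5)))
                cursor += length
            ann = ann_of(feats)
            pos = rng.integers(1, cursor + 500, size=30)
            out = assign_features(dmps_at(pos), ann)
            for p, fid in zip(pos, out["feature_id"]):
                containing = [f for f in feats if f.start <= p <= f.end]
                if containing:
                    assert fid in {f.id for f in containing}
                else:
                    dist = min(max(f.start - p, p - f.end) for f in feats)
                    best = [f.id for f in feats
                            if max(f.start - p, p - f.end) == dist]
                    assert fid in best


class TestBoundaryProfile:
    def _annotated(self, offsets, lengths, kind="gene"):
        """Build features of given lengths and DMPs at given start-anchor
        offsets inside/around feature 0."""
        feats = [FeatureInterval("Chr1", 100_000 * (i + 1),
                                 100_000 * (i + 1) + ln - 1, "+", kind,
                                 f"f{i}")
                 for i, ln in enumerate(lengths)]
        f0 = feats[0]
        dmps = dmps_at([f0.start + o for o in offsets])
        annotated = assign_features(dmps, ann_of(feats))
        return annotated, ann_of(feats)

    def test_bin_without_length_restriction_unchanged(self):
        annotated, ann = self._annotated([110, 120, 130, 140, 150],
                                         lengths=[5000] * 3)
        prof = boundary_profile(annotated, ann)
        row = prof[(prof["anchor"] == "start") & (prof["offset_lo"] == 100)]
        assert row["raw"].iloc[0] == 5
        assert row["length_adjusted"].iloc[0] == 5

    def test_short_features_inflate_deep_bins(self):
        # 6 DMPs in bin [1500,1600); only 4 of 10 features are >=1600 bp
        lengths = [1700] * 4 + [800] * 6
        annotated, ann = self._annotated([1510, 1520, 1530, 1540, 1550, 1560],
                                         lengths=lengths)
        prof = boundary_profile(annotated, ann)
        row = prof[(prof["anchor"] == "start") & (prof["offset_lo"] == 1500)]
        assert row["raw"].iloc[0] == 6
        assert row["length_adjusted"].iloc[0] == pytest.approx(6 / 0.4)

    def test_single_nonzero_bin_scales_to_one(self):
        annotated, ann = self._annotated([250], lengths=[4000] * 2)
        prof = boundary_profile(annotated, ann)
        assert prof["scaled"].max() == 1.0
        assert (prof.loc[prof["scaled"] == 1.0, "raw"] > 0).all()

    def test_raw_counts_partition_mapped_dmps(self):
        rng = np.random.default_rng(3)
        lengths = [int(x) for x in rng.integers(200, 4000, 5)]
        offsets = [int(x) for x in rng.integers(-3000, 3000, 60)]
        annotated, ann = self._annotated(offsets, lengths=lengths)
        prof = boundary_profile(annotated, ann)
        start_rows = prof[prof["anchor"] == "start"]
        in_span = start_rows["raw"].sum()
        # out-of-span DMPs relative to their assigned feature's start
        out_span = sum(1 for _, r in annotated.iterrows()
                       if not -2000 <= r["offset_start"] < 2000)
        assert in_span + out_span == len(annotated)

    def test_scaling_invariant_to_count_rescaling(self):
        annotated, ann = self._annotated([110, 120, 1510], [2000] * 3)
        prof1 = boundary_profile(annotated, ann)
        tripled = pd.concat([annotated] * 3, ignore_index=True)
        prof3 = boundary_profile(tripled, ann)
        assert np.allclose(prof1["scaled"], prof3["scaled"])

    def test_bad_bin_width_rejected(self):
        annotated, ann = self._annotated([10], [1000])
        with pytest.raises(ValueError):
            boundary_profile(annotated, ann, bin_width=300, span=2000)


class TestChromosomeDensity:
    def test_normalisation_across_chromosomes(self):
        # Chr1 max window 40 DMPs, Chr2 max 10 -> Chr2 peak at 0.25
        dmps = pd.DataFrame({
            "chrom": ["Chr1"] * 40 + ["Chr2"] * 10,
            "pos": list(np.linspace(1, 9_999, 40).astype(int)) +
                   list(np.linspace(1, 9_999, 10).astype(int))})
        ndmps = dmps.iloc[:0]
        track = chromosome_density(dmps, ndmps,
                                   {"Chr1": 50_000, "Chr2": 50_000}, 10_000)
        c1 = track[track["chrom"] == "Chr1"]
        c2 = track[track["chrom"] == "Chr2"]
        assert c1["dmp_norm"].max() == 1.0
        assert c2["dmp_norm"].max() == pytest.approx(0.25)
        assert (track.loc[track["dmp_count"] == 0, "dmp_norm"] == 0).all()

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            chromosome_density(dmps_at([1]), dmps_at([2]), {"Chr1": 10}, 0)


class TestTeGeneEnrichment:
    def _tes(self, n_assoc_flag, n_assoc_plain, n_rest_flag, n_rest_plain):
        ids, flags = [], []
        for i in range(n_assoc_flag + n_assoc_plain +
                       n_rest_flag + n_rest_plain):
            ids.append(f"te{i}")
        flags = ([True] * n_assoc_flag + [False] * n_assoc_plain +
                 [True] * n_rest_flag + [False] * n_rest_plain)
        assoc = set(ids[:n_assoc_flag + n_assoc_plain])
        return assoc, pd.DataFrame({"id": ids, "has_te_gene": flags})

    def test_worked_odds_ratio(self):
        assoc, tes = self._tes(33, 7, 167, 293)
        odds, p = te_gene_enrichment(assoc, tes)
        assert odds == pytest.approx((33 * 293) / (7 * 167), rel=1e-12)
        assert p < 1e-6

    def test_equal_proportions_null(self):
        assoc, tes = self._tes(10, 10, 20, 20)
        odds, p = te_gene_enrichment(assoc, tes)
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_degenerate_cell_gives_infinite_odds(self):
        assoc, tes = self._tes(15, 0, 0, 25)
        odds, p = te_gene_enrichment(assoc, tes)
        assert np.isinf(odds) and p < 1e-9

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            te_gene_enrichment(set(), pd.DataFrame({"id": ["a"],
                                                    "has_te_gene": [True]}))
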