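"""Feature annotation of DMPs, boundary metaprofiles and density tracks.

Assigns every called DMP to its containing or nearest feature, builds the
100-bp boundary-bin profiles (-2..+2 kb around feature starts and ends,
length-adjusted and max-scaled) and the per-window chromosomal DMP/NDMP
density tracks normalised genome-wide.
"""

import argparse
import glob
import os

from epidiff.annotate import (assign_features, boundary_profile,
                              chromosome_density)
from epidiff.formats_io import (GenomeAnnotation, read_annotation,
                                read_centromeres, read_chrom_sizes,
                                read_table, write_table)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--dmps", default="results/dmps")
    ap.add_argument("--out", default="results/annotation")
    ap.add_argument("--density-window", type=int, default=100_000)
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    annotation = GenomeAnnotation(
        read_chrom_sizes(os.path.join(args.study, "chrom_sizes.tsv")),
        read_centromeres(os.path.join(args.study, "centromeres.tsv")),
        read_annotation(os.path.join(args.study, "annotation.bed"), "BED"))

    for path in sorted(glob.glob(os.path.join(args.dmps, "*_vs_*.tsv"))):
        tag = os.path.basename(path).removesuffix(".tsv")
        annotated = assign_features(read_table(path), annotation)
        write_table(annotated, os.path.join(args.out, f"{tag}.annotated.tsv"))
        called = annotated[annotated["status"] == "DMP"]
        print(f"\n{tag}: {len(called)} DMPs by feature kind:")
        print(called["feature_kind"].value_counts().to_string())

        if len(called):
            prof = boundary_profile(called, annotation)
            write_table(prof, os.path.join(args.out, f"{tag}.profiles.tsv"))
            peak = prof.loc[prof["scaled"].idxmax()]
            print(f"  profile peak: {peak['context']} {peak['feature_kind']} "
                  f"{peak['anchor']} anchor, offsets "
                  f"[{peak['offset_lo']},{peak['offset_hi']})")
        track = chromosome_density(
            called, annotated[annotated["status"] == "NDMP"],
            annotation.chrom_sizes, args.density_window)
        write_table(track, os.path.join(args.out, f"{tag}.density.tsv"))


if __name__ == "__main__":
    main()
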