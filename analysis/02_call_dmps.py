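"""Pairwise DMP calling: each non-reference sample against wild type.

Applies the coverage-eligibility filter (>=4 reads both samples, >=2
methylated in one), per-position Fisher exact tests, and the
context-specific FDR policies (CG: q<0.05 genome-wide; CHG/CHH: raw
p<0.05 then q<0.035).  Reports per-context DMP counts and
hyper/hypomethylation balance, and checks recovery against planted truth.
"""

import argparse
import glob
import os

from epidiff.dmp import call_dmps
from epidiff.evaluation import dmp_recovery
from epidiff.formats_io import read_table, write_table
from epidiff.matrix import MethylomeMatrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", default="results/study")
    ap.add_argument("--out", default="results/dmps")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    paths = sorted(glob.glob(os.path.join(args.study, "reports", "*.cx.tsv")))
    matrix = MethylomeMatrix.from_reports(
        {os.path.basename(p).removesuffix(".cx.tsv"): p for p in paths})
    truth = read_table(os.path.join(args.study, "truth_dmps.tsv"))

    reference = "wildtype_1"
    for test_sample, group in (("mutant_1", "mutant"), ("epi_1", "epi")):
        dmps = call_dmps(matrix, test_sample, reference)
        write_table(dmps, os.path.join(args.out,
                                       f"{test_sample}_vs_{reference}.tsv"))
        print(f"\n{test_sample} vs {reference}:")
        for ctx in ("CG", "CHG", "CHH"):
            sub = dmps[(dmps["context"] == ctx) & (dmps["status"] == "DMP")]
            hyper = (sub["direction"] == "hyper").sum()
            print(f"  {ctx}: {len(sub)} DMPs "
                  f"({hyper} hyper / {len(sub) - hyper} hypo)")
            rec = dmp_recovery(dmps, truth, group=group, context=ctx)
            if rec["n_planted_tested"]:
                print(f"      planted recovery: sensitivity "
                      f"{rec['sensitivity']:.3f}, empirical FDR "
                      f"{rec['empirical_fdr']:.3f}")


if __name__ == "__main__":
    main()
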