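"""Readers and writers for the external formats the pipeline touches.

Internal convention: all coordinates are 1-based inclusive, matching the
Bismark-style cytosine report.  Converters to/from 0-based half-open (BED)
live only here, at the I/O boundary.  Strands are never merged: the two
cytosines of a CG dyad are independent records.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_KINDS = ("gene", "transposon")

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class FeatureInterval:
    """A gene or transposon interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    id: str
    has_te_gene: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"feature {self.id}: end {self.end} < start {self.start}")
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"feature {self.id}: unknown kind {self.kind!r}")
        if self.kind == "gene" and self.has_te_gene:
            raise FormatError(f"gene {self.id} cannot carry has_te_gene")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, centromere positions and feature intervals."""

    chrom_sizes: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    features: list[FeatureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, pos in self.centromeres.items():
            size = self.chrom_sizes.get(chrom)
            if size is not None and not (1 <= pos <= size):
                raise FormatError(
                    f"centromere of {chrom} at {pos} outside [1,{size}]")
        for f in self.features:
            size = self.chrom_sizes.get(f.chrom)
            if size is not None and (f.start < 1 or f.end > size):
                raise FormatError(
                    f"feature {f.id} [{f.start},{f.end}] outside {f.chrom} "
                    f"bounds [1,{size}]")

    def features_frame(self) -> pd.DataFrame:
        """Features as a DataFrame (one row per interval)."""
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in self.features],
                "start": [f.start for f in self.features],
                "end": [f.end for f in self.features],
                "strand": [f.strand for f in self.features],
                "kind": [f.kind for f in self.features],
                "id": [f.id for f in self.features],
                "has_te_gene": [f.has_te_gene for f in self.features],
            }
        )


def read_cytosine_report(path: str | os.PathLike | io.TextIOBase,
                         sample_name: str) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a per-sample site table.

    Columns: chrom, pos (1-based), strand, meth, unmeth, context,
    trinucleotide.  Every input line yields exactly one record or an error
    naming its line number; nothing is dropped silently.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CYTOSINE_REPORT_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str,
                   "trinucleotide": str},
            na_filter=False, comment=None,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    df.attrs["sample_name"] = sample_name
    if df.empty:
        return df.astype({"pos": int, "meth": int, "unmeth": int},
                         errors="ignore")

    for col in ("pos", "meth", "unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            raise FormatError(
                f"{sample_name}: malformed {col} field at line "
                f"{int(bad.idxmax()) + 1}")
        df[col] = numeric.astype(int)
    if (df["pos"] < 1).any():
        line = int((df["pos"] < 1).idxmax()) + 1
        raise FormatError(f"{sample_name}: non-positive position at line {line}")
    if (df[["meth", "unmeth"]] < 0).to_numpy().any():
        raise FormatError(f"{sample_name}: negative read count")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise FormatError(
            f"{sample_name}: unknown context "
            f"{df['context'].iloc[line - 1]!r} at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise FormatError(f"{sample_name}: bad strand at line {line}")
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"{sample_name}: duplicate position "
            f"({row['chrom']},{row['pos']},{row['strand']})")
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=CYTOSINE_REPORT_COLUMNS)


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | os.PathLike, dialect: str) -> list[FeatureInterval]:
    """Read feature intervals from BED6+2 or GFF3.

    BED is 0-based half-open with two extra columns: kind
    (gene/transposon) and te_gene flag (0/1).  GFF3 is 1-based closed; kind
    comes from the type column (``gene`` or ``transposable_element``/
    ``transposon``) and the flag from a ``te_gene=1`` attribute.  All
    intervals are converted to 1-based inclusive.
    """
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    features: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "BED":
                    chrom, start0, end0, name = fields[0], int(fields[1]), \
                        int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                    kind = fields[6] if len(fields) > 6 else "gene"
                    te_flag = fields[7] if len(fields) > 7 else "0"
                    start, end = start0 + 1, end0  # half-open -> inclusive
                else:
                    chrom, kind_raw = fields[0], fields[2]
                    start, end = int(fields[3]), int(fields[4])
                    strand = fields[6]
                    attrs = _parse_gff3_attributes(fields[8]) if len(fields) > 8 else {}
                    name = attrs.get("ID", f"feature_{lineno}")
                    kind = {"transposable_element": "transposon",
                            "transposon": "transposon",
                            "gene": "gene"}.get(kind_raw, kind_raw)
                    te_flag = attrs.get("te_gene", "0")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            try:
                features.append(FeatureInterval(
                    chrom=chrom, start=start, end=end, strand=strand,
                    kind=kind, id=name,
                    has_te_gene=str(te_flag) in {"1", "true", "True"}))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return features


def write_annotation_bed(features: list[FeatureInterval],
                         path: str | os.PathLike) -> None:
    """Write features as BED6+2 (0-based half-open; kind and te_gene flag)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.id}\t.\t{f.strand}\t"
                f"{f.kind}\t{int(f.has_te_gene)}\n")


def flag_te_genes_by_overlap(transposons: list[FeatureInterval],
                             te_gene_intervals: list[tuple[str, int, int]]
                             ) -> list[FeatureInterval]:
    """Fallback when no te_gene flag is annotated: mark each transposon that
    contains or overlaps at least one TE-gene interval."""
    out = []
    for te in transposons:
        hit = any(c == te.chrom and s <= te.end and e >= te.start
                  for c, s, e in te_gene_intervals)
        out.append(FeatureInterval(te.chrom, te.start, te.end, te.strand,
                                   te.kind, te.id, has_te_gene=hit))
    return out


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_centromeres(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"],
                     dtype={"chrom": str})
    return dict(zip(df["chrom"], df["pos"].astype(int)))


def write_centromeres(cents: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, pos in cents.items():
            fh.write(f"{chrom}\t{pos}\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as headered TSV with >=6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results(tables: dict[str, pd.DataFrame],
                  out_dir: str | os.PathLike) -> dict[str, str]:
    """Write each named table as <name>.tsv under out_dir; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        write_table(df, p)
        paths[name] = p
    return paths
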