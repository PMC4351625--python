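"""The pipeline's central container: per-cytosine counts across samples."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import (CYTOSINE_REPORT_COLUMNS, read_cytosine_report,
                         write_cytosine_report)

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass
class MethylomeMatrix:
    """Methylated/total read counts for every cytosine site in every sample.

    ``sites`` holds one row per (chrom, pos, strand) with its context;
    ``meth`` and ``cov`` are (n_sites, n_samples) integer arrays aligned to
    ``sites`` rows and ``samples`` columns, with meth <= cov elementwise.
    Sites are unique and sorted by (chrom, pos, strand).
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        if self.meth.shape != self.cov.shape or \
                self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays misaligned with sites/samples")
        if (self.meth > self.cov).any():
            raise ValueError("methylated count exceeds coverage")
        if (self.meth < 0).any() or (self.cov < 0).any():
            raise ValueError("negative counts")
        if self.sites.duplicated(SITE_KEY).any():
            raise ValueError("duplicate site keys")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def context_mask(self, context: str) -> np.ndarray:
        return (self.sites["context"] == context).to_numpy()

    def levels(self) -> np.ndarray:
        """Per-site, per-sample methylation proportion (NaN where cov=0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.cov > 0, self.meth / np.maximum(self.cov, 1),
                            np.nan)

    def subset(self, mask: np.ndarray) -> "MethylomeMatrix":
        return MethylomeMatrix(
            self.sites.loc[mask].reset_index(drop=True), list(self.samples),
            self.meth[mask], self.cov[mask])

    @classmethod
    def from_frames(cls, frames: dict[str, pd.DataFrame]) -> "MethylomeMatrix":
        """Build from per-sample cytosine-report frames; union of sites,
        missing sites get zero coverage."""
        samples = list(frames)
        keyed = {}
        for name, df in frames.items():
            keyed[name] = df.set_index(SITE_KEY)
        all_sites = pd.concat(
            [df[SITE_KEY + ["context"]] for df in frames.values()]
        ).drop_duplicates(SITE_KEY).sort_values(SITE_KEY).reset_index(drop=True)
        idx = pd.MultiIndex.from_frame(all_sites[SITE_KEY])
        meth = np.zeros((len(all_sites), len(samples)), dtype=np.int64)
        cov = np.zeros_like(meth)
        for j, name in enumerate(samples):
            df = keyed[name].reindex(idx)
            m = df["meth"].fillna(0).to_numpy(dtype=np.int64)
            u = df["unmeth"].fillna(0).to_numpy(dtype=np.int64)
            meth[:, j] = m
            cov[:, j] = m + u
        return cls(all_sites, samples, meth, cov)

    @classmethod
    def from_reports(cls, paths: dict[str, str | os.PathLike]) -> "MethylomeMatrix":
        return cls.from_frames(
            {name: read_cytosine_report(p, name) for name, p in paths.items()})

    def to_reports(self, out_dir: str | os.PathLike,
                   trinucleotides: pd.Series | None = None) -> dict[str, str]:
        """Write one cytosine report per sample; returns sample->path."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        tri = trinucleotides if trinucleotides is not None \
            else pd.Series([""] * self.n_sites)
        for j, name in enumerate(self.samples):
            df = self.sites[SITE_KEY].copy()
            df["meth"] = self.meth[:, j]
            df["unmeth"] = self.cov[:, j] - self.meth[:, j]
            df["context"] = self.sites["context"]
            df["trinucleotide"] = tri.to_numpy()
            p = os.path.join(out_dir, f"{name}.cx.tsv")
            write_cytosine_report(df[CYTOSINE_REPORT_COLUMNS], p)
            paths[name] = p
        return paths
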