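"""Relative mitochondrial DNA coverage from per-base depth tracks.

The statistic is the mean per-base depth over the mitochondrial sequence
divided by the mean per-base depth over all nuclear positions, after masking
a high-coverage window (by default chrXII:45,000-50,000, 1-based inclusive,
covering the rDNA repeat array).  Any per-library depth normalization
applied equally to both tracks cancels in the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "Region",
    "DEFAULT_EXCLUSION",
    "relative_mtdna_coverage",
    "read_bedgraph",
    "read_per_base_tsv",
    "regions_from_bed",
]


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int  # 1-based
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @classmethod
    def from_half_open(cls, chrom: str, start0: int, end0: int) -> "Region":
        """Convert a 0-based half-open interval (BED convention)."""
        return cls(chrom, start0 + 1, end0)


DEFAULT_EXCLUSION = (Region("chrXII", 45_000, 50_000),)


@dataclass
class DepthProfile:
    """Per-base depth arrays keyed by sequence name, one of them mitochondrial."""

    depths: dict[str, np.ndarray]
    mito: str = "chrM"

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty depth track for {chrom!r}")
            if np.any(arr < 0):
                raise ValueError(f"negative depth in {chrom!r}")
            self.depths[chrom] = arr
        if self.mito not in self.depths:
            raise ValueError(f"mitochondrial sequence {self.mito!r} not in profile")
        if len(self.depths) < 2:
            raise ValueError("profile needs the mitochondrial and >= 1 nuclear sequence")

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.depths if c != self.mito]


def relative_mtdna_coverage(
    d: DepthProfile,
    exclude: tuple[Region, ...] | list[Region] = DEFAULT_EXCLUSION,
) -> float:
    """Mean mito depth over mean nuclear depth outside the excluded regions.

    Exclusions naming sequences absent from the profile are skipped with a
    warning (the default rDNA window only applies when a chrXII track is
    present).  An exclusion must lie within its chromosome; masking an
    entire chromosome triggers a warning.
    """
    mask: dict[str, np.ndarray] = {
        c: np.zeros(len(d.depths[c]), dtype=bool) for c in d.nuclear_chroms
    }
    for region in exclude:
        if region.chrom not in d.depths:
            warnings.warn(f"exclusion region on absent sequence {region.chrom!r}; skipped")
            continue
        if region.chrom == d.mito:
            raise ValueError("exclusion regions apply to nuclear sequences only")
        length = len(d.depths[region.chrom])
        if region.end > length:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"sequence length {length}"
            )
        mask[region.chrom][region.start - 1 : region.end] = True
        if mask[region.chrom].all():
            warnings.warn(f"exclusion covers all of {region.chrom!r}")

    nuclear_vals = np.concatenate(
        [d.depths[c][~mask[c]] for c in d.nuclear_chroms if (~mask[c]).any()]
    )
    if nuclear_vals.size == 0:
        raise ValueError("no nuclear positions left after exclusion")
    nuclear_mean = float(nuclear_vals.mean())
    if nuclear_mean == 0:
        raise ValueError("nuclear mean depth is zero")
    return float(d.depths[d.mito].mean()) / nuclear_mean


def read_bedgraph(path: str | Path, mito: str = "chrM") -> DepthProfile:
    """Load a bedGraph-style TSV (chrom, start, end, depth; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "depth"], header=None,
    )
    depths: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        length = int(grp["end"].max())
        arr = np.zeros(length)
        for _, r in grp.iterrows():
            arr[int(r["start"]) : int(r["end"])] = r["depth"]
        depths[str(chrom)] = arr
    return DepthProfile(depths, mito=mito)


def write_bedgraph(d: DepthProfile, path: str | Path) -> None:
    """Write run-length-compressed bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, arr in d.depths.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_per_base_tsv(path: str | Path, mito: str = "chrM") -> DepthProfile:
    """Load a 2-column per-base TSV (chrom, depth), rows in base order."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "depth"], header=None)
    depths = {
        str(chrom): grp["depth"].to_numpy(dtype=float)
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return DepthProfile(depths, mito=mito)


def regions_from_bed(path: str | Path) -> list[Region]:
    """Read exclusion regions from BED (0-based half-open) as 1-based Regions."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return [
        Region.from_half_open(str(r[0]), int(r[1]), int(r[2]))
        for _, r in df.iterrows()
    ]
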