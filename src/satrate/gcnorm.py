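"""GC-bin depth normalization of raw repeat counts.

Short-read coverage depends on the GC fraction of the sequenced fragment.
Raw tandem-repeat counts are therefore converted to copies per 1x genome
coverage by dividing each unit's count by the mean mapped depth of genomic
sites that share the unit's GC fraction: a unit of 50% GC counted 5000
times in a library whose 50%-GC regions average 35x depth has an estimated
5000/35 = 142.86 copies (displayed as 143).

Depth profiles are consumed as TSV tables of per-chromosome, per-GC-bin
(depth_sum, site_count) pairs and pooled depth-weighted across chromosomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .counter import AbundanceTable
from .units import unit_gc

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.05


@dataclass
class GCDepthProfile:
    """Mean mapped depth per GC-fraction bin.

    Bins partition [0, 1]; a bin with no genomic sites has depth NaN
    ("undefined") rather than zero.  ``genome_mean_depth`` is the
    site-weighted mean over all defined bins and serves as the fallback for
    undefined bins.
    """

    bin_edges: np.ndarray  # length n_bins + 1
    depth_sum: np.ndarray  # per-bin summed depth over sites
    site_count: np.ndarray  # per-bin site counts

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.depth_sum = np.asarray(self.depth_sum, dtype=float)
        self.site_count = np.asarray(self.site_count, dtype=float)
        if self.bin_edges[0] != 0.0 or self.bin_edges[-1] != 1.0:
            raise ValueError("bin edges must partition [0, 1]")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.depth_sum) != len(self.bin_edges) - 1:
            raise ValueError("depth_sum length must equal number of bins")

    @property
    def mean_depth(self) -> np.ndarray:
        """Per-bin mean depth; NaN where a bin has zero sites."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.site_count > 0, self.depth_sum / self.site_count, np.nan
            )

    @property
    def genome_mean_depth(self) -> float:
        total_sites = self.site_count.sum()
        if total_sites == 0:
            raise ValueError("profile has no sites in any bin")
        return float(self.depth_sum.sum() / total_sites)

    def bin_index(self, gc: float | Fraction) -> int:
        """Bin containing GC fraction ``gc`` (right edge closed at 1.0)."""
        g = float(gc)
        if not 0.0 <= g <= 1.0:
            raise ValueError(f"GC fraction {g} outside [0, 1]")
        idx = int(np.searchsorted(self.bin_edges, g, side="right")) - 1
        return min(idx, len(self.bin_edges) - 2)

    def depth_for_gc(self, gc: float | Fraction, fallback: bool = True) -> float:
        """Mean depth of the bin containing ``gc``; genome mean if undefined."""
        d = float(self.mean_depth[self.bin_index(gc)])
        if math.isnan(d):
            if not fallback:
                return float("nan")
            logger.warning(
                "GC bin for fraction %.3f has no sites; "
                "falling back to genome-wide mean depth",
                float(gc),
            )
            return self.genome_mean_depth
        return d


def uniform_bin_edges(bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    n = round(1.0 / bin_width)
    if abs(n * bin_width - 1.0) > 1e-9:
        raise ValueError("bin width must divide 1.0")
    return np.linspace(0.0, 1.0, n + 1)


def aggregate_profile(per_chromosome: pd.DataFrame) -> GCDepthProfile:
    """Pool per-chromosome GC-depth tables into one profile.

    Input columns: chromosome, bin_low, bin_high, depth_sum, site_count.
    Pooling is depth-weighted (sum of sums / sum of sites), never a
    mean-of-means; all chromosomes must share identical bin edges.
    """
    required = {"chromosome", "bin_low", "bin_high", "depth_sum", "site_count"}
    missing = required - set(per_chromosome.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    ref = None
    groups = []
    for _chrom, grp in per_chromosome.groupby("chromosome", sort=True):
        grp = grp.sort_values("bin_low").reset_index(drop=True)
        edges = np.append(grp["bin_low"].to_numpy(), grp["bin_high"].iloc[-1])
        if ref is None:
            ref = edges
        elif len(edges) != len(ref) or not np.allclose(edges, ref):
            raise ValueError("chromosomes have mismatched GC bin edges")
        groups.append(grp)
    if ref is None:
        raise ValueError("empty profile table")
    depth_sum = np.sum([g["depth_sum"].to_numpy(float) for g in groups], axis=0)
    site_count = np.sum([g["site_count"].to_numpy(float) for g in groups], axis=0)
    return GCDepthProfile(bin_edges=ref, depth_sum=depth_sum, site_count=site_count)


def normalize(raw: AbundanceTable, profile: GCDepthProfile) -> AbundanceTable:
    """Convert raw counts to copies per 1x coverage by GC-bin depth division.

    Raises if the table is already normalized (double correction) or if an
    undefined bin has no genome-wide fallback.
    """
    if raw.normalized:
        raise ValueError("table is already normalized; refusing to normalize twice")
    depths = {}
    undefined = []
    for unit in raw.units:
        d = profile.depth_for_gc(unit_gc(unit))
        if math.isnan(d) or d <= 0:
            undefined.append(unit)
        depths[unit] = d
    if undefined:
        raise ValueError(
            "no usable GC-bin depth for units: " + ", ".join(undefined)
        )
    out = raw.values.astype(float).copy()
    for unit in out.columns:
        out[unit] = out[unit] / depths[unit]
    return AbundanceTable(values=out, normalized=True)


def display_copies(value: float) -> int:
    """Copy number as printed in reports: nearest integer (5000/35 -> 143)."""
    return int(round(value))
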