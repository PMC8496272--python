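"""Complex-satellite copy number from read depth over a consensus.

Complex satellites (mouse major, 234-bp monomer; minor, 120-bp monomer;
the Y-specific Ymin higher-order repeat) are too long and too diverged for
read-level tandem detection.  Their genome-wide copy number is instead
estimated from mapping depth: reads are mapped to a multicopy consensus
construct (so boundary-spanning reads find a home) and

    copies = total mapped bases / (unit_length * genome mean depth)

which equals mean consensus depth / genome depth x (consensus length /
unit length).  Ymin copy numbers are per HOR (unit_length = HOR length);
the minor satellite is per monomer — same estimator, different unit.
Per-line satellite copies then enter the same branch-rate machinery as the
simple repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylogeny import GenerationTree, branch_rates


@dataclass
class SatelliteProfile:
    """Consensus construct plus per-position mapped depth for one satellite."""

    name: str
    consensus: str  # multicopy construct (n_copies x unit/HOR)
    unit_length: int  # monomer length, or HOR length for Ymin
    per_position_depth: np.ndarray
    genome_mean_depth: float

    def __post_init__(self) -> None:
        self.per_position_depth = np.asarray(self.per_position_depth, dtype=float)
        L = len(self.consensus)
        if self.unit_length > L:
            raise ValueError("unit length exceeds consensus length")
        if L % self.unit_length != 0:
            raise ValueError(
                f"consensus length {L} is not a multiple of unit length "
                f"{self.unit_length}"
            )
        if len(self.per_position_depth) != L:
            raise ValueError("depth vector length must equal consensus length")
        if np.any(self.per_position_depth < 0):
            raise ValueError("depths must be non-negative")


def satellite_copy_number(
    profile: SatelliteProfile, trim_edge_units: int = 1
) -> float:
    """Estimated genome-wide copies of the satellite unit (monomer or HOR).

    Equivalent to total mapped bases / (unit_length x genome depth) for a
    uniformly covered construct: with mean per-position depth d over a
    construct of n_units unit copies, copies = d x n_units / genome depth
    (7,020,000 mapped bases over a 234-bp unit at 30x genome depth give
    1000 copies).  The first and last ``trim_edge_units`` units of the
    construct are excluded from the depth average when enough interior
    units remain (boundary undercoverage).
    """
    if profile.genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    depth = profile.per_position_depth
    L = len(profile.consensus)
    k = profile.unit_length
    n_units = L // k
    t = trim_edge_units
    if t > 0 and n_units > 2 * t:
        depth = depth[t * k : L - t * k]
    mean_depth = float(depth.mean())
    return mean_depth * n_units / profile.genome_mean_depth


def satellite_rates(
    tree: GenerationTree, copies: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Branch rates for satellite copy numbers (lines x satellite names)."""
    return branch_rates(tree, copies, **kwargs)


def kmer_exclusive(consensus_a: str, consensus_b: str, k: int = 31) -> bool:
    """True when two consensus sequences share no exact k-mer (either strand).

    A cheap guard against cross-mapping between similar satellites (e.g.
    Ymin vs the minor satellite).
    """
    from .units import reverse_complement

    def kmers(s: str) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    a = kmers(consensus_a) | kmers(reverse_complement(consensus_a))
    return not (a & kmers(consensus_b))
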