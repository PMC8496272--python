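"""Synthetic data with known ground truth for the whole pipeline.

Emulates a mutation-accumulation panel of inbred lines: a fixed 14-tip
two-clade tree (terminal branches 64-294 generations, 850 generations of
separation across the basal split), per-unit copy numbers evolving along
the tree by per-generation steps whose variance is proportional to the
current copy number (rates in such panels scale with abundance), optional
signed per-line drift ("hypermutator" tips), 150-bp reads carrying planted
tandem arrays with GC-dependent sampling bias and per-base error, matching
GC depth profiles, and Poisson satellite depth tables.

Everything is driven by one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gcnorm import GCDepthProfile, uniform_bin_edges
from .phylogeny import GenerationTree
from .units import canonical_unit

READ_LENGTH = 150
GENOME_GC = 0.41  # genome-wide average GC fraction being emulated

# 14 tips in two clades of 7; terminal branches span 64-294 generations,
# basal split totals 850 generations (425 per root branch).
STUDY_TREE_NEWICK = (
    "("
    "((((A1:64,A2:87):40,A3:120):35,(A4:150,A5:170):30):25,(A6:200,A7:294):20):425,"
    "((((B1:70,B2:95):45,B3:130):30,(B4:160,B5:180):28):22,(B6:210,B7:260):18):425"
    ");"
)


def study_tree() -> GenerationTree:
    """The fixture phylogeny mirroring the study design."""
    return GenerationTree.from_newick(STUDY_TREE_NEWICK)


@dataclass
class UnitSpec:
    """One simulated repeat unit: canonical sequence, root copies, step sd."""

    unit: str
    ancestral_copies: float
    sigma: float  # per-generation step sd is sigma * sqrt(copies)

    def __post_init__(self) -> None:
        self.unit = canonical_unit(self.unit).sequence


@dataclass
class SimulationConfig:
    units: list[UnitSpec]
    tree: GenerationTree = field(default_factory=study_tree)
    # signed per-line drift in copies/generation/copy on the terminal branch
    bias: dict[str, float] = field(default_factory=dict)
    read_length: int = READ_LENGTH
    coverage: float = 30.0
    error_rate: float = 0.001
    genome_gc: float = GENOME_GC
    background_length: int = 20_000
    gc_bin_width: float = 0.05
    # per-GC-bin read acceptance multipliers in (0, 1]; 1.0 = no bias
    gc_bias: np.ndarray | None = None
    # per-generation step variance: "copy" scales sigma^2 by the current
    # copy number (rates grow with abundance, the study's regime; the
    # resulting multiplicative skew makes losses outnumber gains even
    # without drift); "constant" freezes the scale at the ancestral copies,
    # giving symmetric gains/losses (a fair-coin null for the sign test)
    variance_mode: str = "copy"
    # deterministic emission: reads tiled every tile_stride bases with no
    # sampling noise (coverage = read_length / stride); GC bias is applied
    # by systematic per-bin thinning instead of random acceptance
    tile_stride: int | None = None
    seed: int = 0

    def bias_multipliers(self) -> np.ndarray:
        edges = uniform_bin_edges(self.gc_bin_width)
        if self.gc_bias is None:
            return np.ones(len(edges) - 1)
        m = np.asarray(self.gc_bias, dtype=float)
        if len(m) != len(edges) - 1 or np.any(m <= 0) or np.any(m > 1):
            raise ValueError("gc_bias must give one multiplier in (0,1] per bin")
        return m


# ---------------------------------------------------------------------------
# copy-number evolution


def _evolve_branch(
    rng: np.random.Generator,
    start: np.ndarray,
    generations: float,
    sigma: np.ndarray,
    drift_per_copy: float,
    variance_scale: np.ndarray | None = None,
    n_substeps: int = 8,
) -> np.ndarray:
    """Accumulate per-generation steps over a branch, reflecting at zero.

    Step variance is sigma^2 * copies per generation (or sigma^2 *
    variance_scale when a fixed scale is given); drift is drift_per_copy *
    copies per generation.  Substeps keep the state-dependent variance
    honest without a per-generation loop.
    """
    c = start.astype(float).copy()
    g = generations / n_substeps
    for _ in range(n_substeps):
        scale = np.maximum(c, 0.0) if variance_scale is None else variance_scale
        sd = sigma * np.sqrt(scale * g)
        c = c + drift_per_copy * c * g + rng.normal(0.0, 1.0, c.size) * sd
        c = np.abs(c)  # reflect at zero
    return c


def simulate_tree_evolution(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenerationTree, pd.DataFrame, pd.DataFrame]:
    """Evolve copy numbers along the tree.

    Returns (tree, truth, tips): ``truth`` holds every node (internal
    nodes included, so reconstruction accuracy is directly scorable),
    ``tips`` the per-line copy numbers.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree
    units = [u.unit for u in cfg.units]
    sigma = np.array([u.sigma for u in cfg.units])
    if cfg.variance_mode not in ("copy", "constant"):
        raise ValueError(f"unknown variance_mode {cfg.variance_mode!r}")
    scale = (
        np.array([u.ancestral_copies for u in cfg.units])
        if cfg.variance_mode == "constant"
        else None
    )
    states = np.zeros((tree.n_nodes, len(units)))
    root = tree.root_index()
    states[root] = [u.ancestral_copies for u in cfg.units]
    for i in range(tree.n_nodes):  # preorder: parents precede children
        p = tree.parent[i]
        if p < 0:
            continue
        drift = cfg.bias.get(tree.labels[i], 0.0) if tree.is_tip[i] else 0.0
        states[i] = _evolve_branch(
            rng, states[p], tree.length[i], sigma, drift, variance_scale=scale
        )
    truth = pd.DataFrame(states, index=tree.labels, columns=units)
    tips = truth.loc[tree.tips]
    return tree, truth, tips


# ---------------------------------------------------------------------------
# read emission


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _build_genome(
    rng: np.random.Generator, tip_copies: pd.Series, cfg: SimulationConfig
) -> tuple[np.ndarray, dict[str, int]]:
    """Background genome with one planted tandem array per unit.

    Arrays are separated by background stretches so no read spans two
    arrays.  Returns (genome bytes, planted whole-copy counts per unit).
    """
    gap = cfg.background_length // (len(tip_copies) + 1)
    gap = max(gap, 2 * cfg.read_length)
    parts = [_random_dna(rng, gap, cfg.genome_gc)]
    planted: dict[str, int] = {}
    for unit, copies in tip_copies.items():
        n = int(round(float(copies)))
        planted[unit] = n
        arr = np.frombuffer((unit * n).encode(), dtype=np.uint8)
        parts.append(arr.copy())
        parts.append(_random_dna(rng, gap, cfg.genome_gc))
    return np.concatenate(parts), planted


_GC_MASK = np.frombuffer(b"GC", dtype=np.uint8)


def emit_reads(
    tip_copies: pd.Series, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], dict[str, int]]:
    """Sample error-bearing reads from a genome with planted arrays.

    Read start positions are uniform; each candidate read is accepted with
    the GC-bin multiplier of its own GC fraction, then per-base
    substitution errors are applied.  Returns (reads, planted truth
    counts).  Coverage 0 gives no reads.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome, planted = _build_genome(rng, tip_copies, cfg)
    L = genome.size
    rl = cfg.read_length
    reads: list[str] = []
    mult = cfg.bias_multipliers()
    edges = uniform_bin_edges(cfg.gc_bin_width)
    if cfg.tile_stride is not None:
        is_gc = np.isin(genome, _GC_MASK)
        gc_cum = np.concatenate(([0], np.cumsum(is_gc)))
        acc = np.zeros(mult.size)  # systematic thinning accumulator per bin
        for s in range(0, L - rl + 1, cfg.tile_stride):
            gc_frac = (gc_cum[s + rl] - gc_cum[s]) / rl
            b = min(int(np.searchsorted(edges, gc_frac, side="right")) - 1,
                    mult.size - 1)
            acc[b] += mult[b]
            if acc[b] >= 1.0 - 1e-12:
                acc[b] -= 1.0
                reads.append(genome[s : s + rl].tobytes().decode())
        return reads, planted
    n_reads = int(round(cfg.coverage * L / rl))
    if n_reads == 0:
        return reads, planted
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    accept_u = rng.random(n_reads)
    is_gc = np.isin(genome, _GC_MASK)
    gc_cum = np.concatenate(([0], np.cumsum(is_gc)))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for s, uacc in zip(starts, accept_u):
        gc_frac = (gc_cum[s + rl] - gc_cum[s]) / rl
        b = min(int(np.searchsorted(edges, gc_frac, side="right")) - 1, mult.size - 1)
        if uacc >= mult[b]:
            continue
        read = genome[s : s + rl].copy()
        if cfg.error_rate > 0:
            errs = np.nonzero(rng.random(rl) < cfg.error_rate)[0]
            for e in errs:
                read[e] = rng.choice(bases[bases != read[e]])
        reads.append(read.tobytes().decode())
    return reads, planted


def emit_gc_profile(
    cfg: SimulationConfig, n_chromosomes: int = 2, sites_per_bin: int = 10_000
) -> pd.DataFrame:
    """Per-chromosome GC depth tables consistent with the read sampler.

    Mean depth in a bin equals coverage x that bin's acceptance
    multiplier; sites are split evenly across chromosomes.  Output matches
    the aggregate_profile() input schema.
    """
    edges = uniform_bin_edges(cfg.gc_bin_width)
    mult = cfg.bias_multipliers()
    rows = []
    per_chrom = sites_per_bin // n_chromosomes
    for chrom in range(1, n_chromosomes + 1):
        for b in range(len(mult)):
            depth = cfg.coverage * mult[b]
            rows.append(
                {
                    "chromosome": f"chr{chrom}",
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "depth_sum": depth * per_chrom,
                    "site_count": per_chrom,
                }
            )
    return pd.DataFrame(rows)


def gc_profile(cfg: SimulationConfig) -> GCDepthProfile:
    """Aggregated GCDepthProfile for the configured bias."""
    from .gcnorm import aggregate_profile

    return aggregate_profile(emit_gc_profile(cfg))


# ---------------------------------------------------------------------------
# satellite depth


def emit_satellite_depth(
    copies: float,
    consensus_length: int,
    unit_length: int,
    genome_depth: float,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Per-position depth over a multicopy consensus for a known copy number.

    Mean per-position depth is copies x genome_depth x unit_length /
    consensus_length (all genomic copies share the construct's units);
    ``noise`` draws Poisson counts around that mean, otherwise the exact
    mean is returned at every position.
    """
    mean = copies * genome_depth * unit_length / consensus_length
    if not noise:
        return np.full(consensus_length, mean)
    if rng is None:
        rng = np.random.default_rng(0)
    return rng.poisson(mean, size=consensus_length).astype(float)


def random_consensus(
    rng: np.random.Generator, unit_length: int, n_units: int = 3, gc: float = 0.5
) -> str:
    """A synthetic satellite consensus: one random monomer repeated n_units times."""
    monomer = _random_dna(rng, unit_length, gc).tobytes().decode()
    return monomer * n_units


def default_units(n: int = 50, rng: np.random.Generator | None = None) -> list[UnitSpec]:
    """A spread of unit specs spanning the study's abundance range.

    Copy numbers are log-spaced over 10-10^5 and per-unit sigmas log-spaced
    over more than an order of magnitude, so rate-recovery rankings are
    informative.  Unit sequences are distinct canonical 4-6-mers.
    """
    if rng is None:
        rng = np.random.default_rng(12345)
    seqs: list[str] = []
    seen = set()
    while len(seqs) < n:
        k = int(rng.integers(4, 7))
        s = _random_dna(rng, k, 0.5).tobytes().decode()
        try:
            c = canonical_unit(s).sequence
        except ValueError:
            continue
        if len(c) == k and c not in seen:
            seen.add(c)
            seqs.append(c)
    copies = np.logspace(1, 5, n)
    sigmas = np.logspace(-2.0, -0.5, n)
    order = rng.permutation(n)
    return [
        UnitSpec(unit=seqs[i], ancestral_copies=float(copies[i]), sigma=float(sigmas[order[i]]))
        for i in range(n)
    ]
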