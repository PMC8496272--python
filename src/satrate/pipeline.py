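"""End-to-end pipeline: simulate -> count -> normalize -> rates -> signal ->
satellite -> correlate, with a reproducibility manifest.

The default configuration simulates its own inputs (the synthetic module),
so a full run needs nothing but a seed; stage outputs are TSV files whose
bytes depend only on (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .comparative import build_rate_matrix, classify_pairs, correlation_matrix
from .counter import count_sample, counts_to_table, filter_units
from .gcnorm import normalize
from .phylogeny import branch_rates, per_line_summary, per_unit_summary
from .satellite import SatelliteProfile, satellite_copy_number
from .signal import signal_scan
from .simulate import (
    SimulationConfig,
    UnitSpec,
    emit_gc_profile,
    emit_reads,
    emit_satellite_depth,
    random_consensus,
    simulate_tree_evolution,
    study_tree,
)

DEFAULT_SATELLITES = {
    # name: (unit/HOR length, construct unit copies, ancestral genome copies, sigma)
    "major": (234, 3, 5000.0, 0.02),
    "minor": (120, 3, 2000.0, 0.015),
    "Ymin": (121 * 4, 3, 200.0, 0.03),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "n_units": 8,
    "coverage": 4.0,
    "error_rate": 0.001,
    "background_length": 8000,
    "min_copies": 10,
    "min_samples": 1,
    "common_mean": 100,
    "n_perm": 200,
    "n_rand": 100,
    "genome_depth": 30.0,
    "satellites": {name: list(v) for name, v in DEFAULT_SATELLITES.items()},
}


def _sim_units(n: int, rng: np.random.Generator) -> list[UnitSpec]:
    from .simulate import default_units

    units = default_units(max(n, 4), rng=rng)[:n]
    # keep simulated genomes small: cap planted copies for read emission
    for u in units:
        u.ancestral_copies = float(min(u.ancestral_copies, 2000.0))
        u.ancestral_copies = float(max(u.ancestral_copies, 150.0))
    return units


def run_all(config: dict | None = None, outdir: str | Path = "satrate_out",
            seed: int | None = None) -> Path:
    """Execute every stage on simulated inputs; returns the output directory.

    ``config`` overrides DEFAULT_CONFIG keys; ``seed`` overrides the config
    seed.  Idempotent: identical (config, seed) give identical bytes.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    (out / "fixtures").mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(cfg["seed"])

    # -- simulate ----------------------------------------------------------
    tree = study_tree()
    units = _sim_units(int(cfg["n_units"]), master)
    sim = SimulationConfig(
        units=units,
        tree=tree,
        coverage=float(cfg["coverage"]),
        error_rate=float(cfg["error_rate"]),
        background_length=int(cfg["background_length"]),
        seed=int(cfg["seed"]),
    )
    tree, truth, tips = simulate_tree_evolution(sim, rng=master)
    with open(out / "fixtures" / "tree.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    sio.write_table(truth.reset_index(names="node"), out / "fixtures" / "truth_copies.tsv")

    fastqs: dict[str, Path] = {}
    for line in tree.tips:
        reads, _ = emit_reads(tips.loc[line], sim, rng=master)
        p = out / "fixtures" / f"{line}.fastq"
        sio.write_fastq(reads, p)
        fastqs[line] = p
    profile_df = emit_gc_profile(sim)
    sio.write_gc_profile(profile_df, out / "fixtures" / "gc_profile.tsv")

    # satellites: evolve copy numbers on the same tree, emit depth tables
    sat_specs = cfg["satellites"]
    sat_units = [
        UnitSpec(unit="A", ancestral_copies=v[2], sigma=v[3]) for v in sat_specs.values()
    ]
    # UnitSpec canonicalizes sequences; reuse only the evolution machinery
    sat_sim = SimulationConfig(units=sat_units, tree=tree, seed=int(cfg["seed"]))
    for u, name in zip(sat_sim.units, sat_specs):
        u.unit = name
    _, _, sat_tips = simulate_tree_evolution(sat_sim, rng=master)
    sat_tips.columns = list(sat_specs)
    genome_depth = float(cfg["genome_depth"])
    sat_copy_rows = {}
    for name, (unit_len, n_copies, _anc, _sig) in sat_specs.items():
        consensus = random_consensus(master, int(unit_len), n_units=int(n_copies))
        sio.write_fasta(name, consensus, out / "fixtures" / f"{name}.fa")
        est = {}
        for line in tree.tips:
            depth = emit_satellite_depth(
                float(sat_tips.at[line, name]), len(consensus), int(unit_len),
                genome_depth, rng=master,
            )
            sio.write_depth(depth, out / "fixtures" / f"{name}.{line}.depth.tsv")
            prof = SatelliteProfile(
                name=name, consensus=consensus, unit_length=int(unit_len),
                per_position_depth=depth, genome_mean_depth=genome_depth,
            )
            est[line] = satellite_copy_number(prof)
        sat_copy_rows[name] = est
    sat_copies = pd.DataFrame(sat_copy_rows).loc[tree.tips]

    # -- count -------------------------------------------------------------
    rows = [count_sample(p, sample=line) for line, p in fastqs.items()]
    raw = counts_to_table(rows)
    sio.write_counts(raw, out / "counts.tsv")

    # -- normalize ---------------------------------------------------------
    profile = sio.read_gc_profile(out / "fixtures" / "gc_profile.tsv")
    norm = normalize(raw, profile)
    sio.write_counts(norm, out / "norm.tsv")

    # -- filter + rates ----------------------------------------------------
    retained, common = filter_units(
        norm, min_copies=cfg["min_copies"], min_samples=cfg["min_samples"],
        common_mean=cfg["common_mean"],
    )
    rates = branch_rates(tree, retained.values)
    sio.write_table(rates, out / "rates.tsv")
    sio.write_table(per_line_summary(rates), out / "line_summary.tsv")
    sio.write_table(per_unit_summary(rates), out / "unit_summary.tsv")

    # -- signal ------------------------------------------------------------
    sig = signal_scan(
        tree, retained.values, n_perm=int(cfg["n_perm"]),
        n_rand=int(cfg["n_rand"]), seed=int(cfg["seed"]),
    )
    sio.write_table(sig, out / "signal.tsv")

    # -- satellite rates ---------------------------------------------------
    sat_rates = branch_rates(tree, sat_copies)
    sio.write_table(sat_rates, out / "satellite_rates.tsv")

    # -- correlate ---------------------------------------------------------
    matrix_units = common if len(common.units) >= 2 else retained
    mat = build_rate_matrix(
        rates[rates["unit"].isin(matrix_units.units)], sat_rates
    )
    corr, pvals = correlation_matrix(mat)
    corr.index.name = pvals.index.name = "unit"
    corr.to_csv(out / "correlations.tsv", sep="\t", float_format="%.10g")
    pvals.to_csv(out / "correlation_pvals.tsv", sep="\t", float_format="%.10g")
    cls = classify_pairs(corr, pvals)
    with open(out / "pair_classification.json", "w") as fh:
        json.dump(cls, fh, indent=2, sort_keys=True)
        fh.write("\n")

    sio.write_manifest(
        out / "manifest.json", cfg, int(cfg["seed"]),
        inputs={**{f"fastq:{k}": v for k, v in fastqs.items()},
                "gc_profile": out / "fixtures" / "gc_profile.tsv"},
        parameters={k: v for k, v in cfg.items() if k != "satellites"},
    )
    return out
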