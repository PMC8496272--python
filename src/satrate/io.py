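"""Table, sequence and tree I/O shared by the CLI stages.

All tables are TSV with a header row; floats are serialized with 10
significant digits so write-read round trips are lossless at the precision
the pipeline uses.  Count tables follow the `unit<TAB>sample...` layout
(units as rows).  Newick branch lengths are in generations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .counter import AbundanceTable
from .gcnorm import GCDepthProfile, aggregate_profile

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(table: AbundanceTable, path) -> None:
    """Write an abundance table as unit rows x sample columns."""
    df = table.values.T
    df.index.name = "unit"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_counts(path, normalized: bool = False) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col="unit")
    return AbundanceTable(values=df.T, normalized=normalized)


def write_gc_profile(per_chromosome: pd.DataFrame, path) -> None:
    write_table(per_chromosome, path)


def read_gc_profile(path) -> GCDepthProfile:
    return aggregate_profile(read_table(path))


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fasta_first(path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_fasta(name: str, seq: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_depth(depth: np.ndarray, path) -> None:
    df = pd.DataFrame({"position": np.arange(len(depth)), "depth": depth})
    write_table(df, path)


def read_depth(path) -> np.ndarray:
    df = read_table(path)
    return df.sort_values("position")["depth"].to_numpy(float)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, inputs: dict[str, Path],
                   parameters: dict) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {
            name: file_sha256(p) for name, p in sorted(inputs.items())
        },
        "parameters": parameters,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
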