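"""Detection and counting of simple tandem repeats directly from short reads.

No genome mapping is involved: each read is scanned for maximal tandem
stretches of every primitive unit of 1-20 bp.  A stretch qualifies when it
covers at least ``min_span`` bases (default 50).  Within a stretch, one base
substitution is tolerated per interior unit copy (units of 3 bp and longer;
for shorter units a one-substitution copy is not evidence of anything) and
single-base indels are tolerated between complete copies; the first and
last complete copies of a stretch must match the unit exactly, so that
flanking sequence is never absorbed as a "mutated copy".  Per read a single best unit is counted,
chosen to maximise total covered bases (ties: longer unit, then
lexicographically smallest canonical form).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .units import (
    RepeatUnit,
    _rotations,
    canonical_unit,
    reverse_complement,
)

MIN_SPAN = 50
MAX_UNIT = 20
# a stretch is abandoned after this many consecutive inexact copies
# (substituted or indel-bearing) with no exact anchor copy in between;
# trimming would discard such a tail anyway, and the bound stops runaway
# walks through sequence that is periodic at a different unit length
MAX_GAP = 4


@dataclass(frozen=True)
class ReadHit:
    """One maximal tandem stretch on a read.

    ``span`` is a 0-based half-open interval; ``copies`` is the number of
    complete unit copies, i.e. floor(span length / unit length);
    ``mismatches`` counts accepted interior substitutions.
    """

    unit: RepeatUnit
    copies: int
    span: tuple[int, int]
    mismatches: int

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class AbundanceTable:
    """Sample x unit matrix of repeat abundances.

    ``values`` is a DataFrame with samples as the index and canonical unit
    sequences as columns.  Raw tables hold integer read-derived copy counts;
    normalized tables hold copies per 1x genome coverage.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate sample or unit labels")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def units(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# read scanning


_N = ord("N")


@njit(cache=True)
def _extend(arr, start, k, max_gap):  # pragma: no cover - exercised via scan_read
    """Greedily extend tandem copies of the unit ``arr[start:start+k]``.

    Accepts, per step: an exact copy (an anchor), a copy with one
    substitution (units over 2 bp), one inserted base before an exact copy,
    or a copy with one base deleted (units over 2 bp).  At most ``max_gap``
    consecutive inexact copies are allowed between anchors.  The stretch is
    trimmed back to the last anchor, then grown by an exact partial copy.
    Returns (end, copies, mismatches, raw_break_pos); end == -1 when fewer
    than two anchors were found.
    """
    n = arr.size
    for j in range(start, start + k):
        if arr[j] == _N:
            return -1, 0, 0, start + k
    pos = start + k
    copies = 1
    mismatches = 0
    exact_end, exact_copies, exact_mm = pos, 1, 0
    gap = 0
    while pos + k <= n and gap <= max_gap:
        mm = 0
        has_n = False
        for j in range(k):
            b = arr[pos + j]
            if b == _N:
                has_n = True
            if b != arr[start + j]:
                mm += 1
        if has_n:
            mm = k if k > 1 else 1
        if mm == 0:
            pos += k
            copies += 1
            gap = 0
            exact_end, exact_copies, exact_mm = pos, copies, mismatches
            continue
        if k == 1:
            break  # 1-bp units: substitution/indel tolerance is degenerate
        # one substitution per copy, but only where that is < 50% divergence;
        # for 2-bp units a "1-substitution copy" admits half of all sequence
        if mm == 1 and k > 2:
            pos += k
            copies += 1
            mismatches += 1
            gap += 1
            continue
        # single-base indel between complete copies: insertion of one base
        # (an N is a broken position, never an insertion)
        if arr[pos] != _N and pos + 1 + k <= n:
            ok = True
            for j in range(k):
                if arr[pos + 1 + j] != arr[start + j]:
                    ok = False
                    break
            if ok:
                pos += 1 + k
                copies += 1
                gap += 1
                continue
        # deletion of one base from the next copy (k-1 remaining bases are
        # too little evidence below 3-bp units)
        if k > 2 and pos + k - 1 <= n:
            found = False
            for d in range(k):
                ok = True
                for j in range(k - 1):
                    src = start + j if j < d else start + j + 1
                    if arr[pos + j] != arr[src]:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if found:
                pos += k - 1
                copies += 1
                gap += 1
                continue
        break
    raw_end = pos
    if exact_copies < 2:
        return -1, 0, 0, raw_end
    # exact partial copy at the stretch end
    end = exact_end
    t = 0
    while end < n and t < k - 1 and arr[end] == arr[start + t]:
        end += 1
        t += 1
    return end, exact_copies, exact_mm, raw_end


class _LagCums:
    """Cached cumulative lag-mismatch counts over one read."""

    def __init__(self, arr: np.ndarray):
        self.arr = arr
        self._cums: dict[int, np.ndarray] = {}

    def __call__(self, k: int) -> np.ndarray:
        c = self._cums.get(k)
        if c is None:
            a = self.arr
            c = np.concatenate(([0], np.cumsum(a[:-k] != a[k:], dtype=np.int32)))
            self._cums[k] = c
        return c


def _candidate_starts(lag: _LagCums, k: int) -> np.ndarray:
    """Positions that can open a tandem stretch of a primitive period-k unit.

    A viable start has a second copy immediately after the template (at
    most one substitution for units over 2 bp), or after a single-base
    insertion, or with a single-base deletion — the same moves the extender
    accepts.  Starts whose template is non-primitive are excluded.
    """
    n = lag.arr.size
    if n < 2 * k:
        return np.empty(0, dtype=np.intp)
    c = lag(k)
    if k == 1:
        return np.nonzero(c[1:n] - c[: n - 1] == 0)[0]
    limit = n - 2 * k + 1
    window = c[k : k + limit] - c[:limit]
    ok = window <= (1 if k > 2 else 0)
    # insertion boundary: copy 2 starts one base late and matches exactly
    if n >= 2 * k + 1:
        ci = lag(k + 1)
        lim_i = min(limit, n - 2 * k)
        ok[:lim_i] |= (ci[k : k + lim_i] - ci[:lim_i]) == 0
    # deletion boundary: copy 2 is the template minus one base at offset
    # `drop` (3-bp units and longer): bases before align at lag k, after at
    # lag k-1; only worth checking where nothing simpler matched
    if k > 2 and n >= 2 * k - 1 and not ok.all():
        cd = lag(k - 1)
        idx = np.nonzero(~ok)[0]
        if idx.size:
            hit = np.zeros(idx.size, dtype=bool)
            for drop in range(k):
                pre = c[idx + drop] - c[idx]
                post = cd[idx + k] - cd[np.minimum(idx + drop + 1, idx + k)]
                hit |= (pre + post) == 0
            ok[idx[hit]] = True
    # non-primitive templates: periodic at some proper divisor of k
    idx = np.nonzero(ok)[0]
    if idx.size:
        for p in range(1, k):
            if k % p == 0:
                cp = lag(p)
                ok[idx[(cp[idx + k - p] - cp[idx]) == 0]] = False
                idx = np.nonzero(ok)[0]
                if not idx.size:
                    break
    return np.nonzero(ok)[0]


def scan_read(
    read: str, min_span: int = MIN_SPAN, max_unit: int = MAX_UNIT
) -> list[ReadHit]:
    """Find the best-unit tandem stretches on one read.

    Returns the (non-overlapping) stretches of the single best canonical
    unit, or an empty list when no stretch reaches ``min_span`` bases.
    """
    read = read.upper()
    n = len(read)
    if n < min_span:
        return []
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    # raw stretches per canonical unit: unit -> list of (start, end, copies, mm)
    lag = _LagCums(arr)
    stretches: dict[str, list[tuple[int, int, int, int]]] = {}
    for k in range(1, min(max_unit, n // 2) + 1):
        starts = _candidate_starts(lag, k)
        if not starts.size:
            continue
        lagk = lag(k)
        by_phase: dict[int, tuple[int, int]] = {}
        for start in starts:
            start = int(start)
            # a same-phase start inside a perfectly periodic region has the
            # identical template and can only re-find a suffix of the
            # stretch already extended from the earlier start
            prev = by_phase.get(start % k)
            if (
                prev is not None
                and start + k <= prev[1]
                and lagk[start] == lagk[prev[0]]
            ):
                continue
            end, copies, mm, raw_end = _extend(arr, start, k, MAX_GAP)
            by_phase[start % k] = (start, raw_end)
            if end < 0 or end - start < min_span:
                continue
            canon = canonical_unit(read[start : start + k]).sequence
            stretches.setdefault(canon, []).append((start, end, copies, mm))
    if not stretches:
        return []
    best_unit, best_hits, best_cov = None, None, -1
    for canon in sorted(stretches, key=lambda u: (-len(u), u)):
        hits = _select_nonoverlapping(stretches[canon])
        cov = sum(e - s for s, e, _, _ in hits)
        if cov > best_cov:
            best_unit, best_hits, best_cov = canon, hits, cov
    unit = RepeatUnit(best_unit)
    return [
        ReadHit(unit=unit, copies=(e - s) // len(best_unit), span=(s, e), mismatches=mm)
        for s, e, _, mm in best_hits
    ]


def _select_nonoverlapping(
    stretches: list[tuple[int, int, int, int]],
) -> list[tuple[int, int, int, int]]:
    chosen: list[tuple[int, int, int, int]] = []
    for s in sorted(stretches, key=lambda t: (-(t[1] - t[0]), t[0])):
        if all(s[1] <= c[0] or s[0] >= c[1] for c in chosen):
            chosen.append(s)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# FASTQ counting


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ path or open text handle."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    handle = _open_maybe_gzip(source) if isinstance(source, (str, Path)) else source
    close = isinstance(source, (str, Path))
    idx = 0
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq
            idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
    finally:
        if close:
            handle.close()


def count_reads(
    reads: Iterable[str], min_span: int = MIN_SPAN, max_unit: int = MAX_UNIT
) -> dict[str, int]:
    """Sum unit copies over reads; one best unit counted per read."""
    counts: dict[str, int] = {}
    for read in reads:
        for hit in scan_read(read, min_span=min_span, max_unit=max_unit):
            key = hit.unit.sequence
            counts[key] = counts.get(key, 0) + hit.copies
    return counts


def count_sample(
    source, sample: str = "sample", min_span: int = MIN_SPAN, max_unit: int = MAX_UNIT
) -> pd.Series:
    """Count repeats in one FASTQ file; returns a unit -> copies row."""
    counts = count_reads(iter_fastq(source), min_span=min_span, max_unit=max_unit)
    return pd.Series(counts, name=sample, dtype=float).sort_index()


def counts_to_table(rows: Sequence[pd.Series]) -> AbundanceTable:
    """Stack per-sample count rows into a raw AbundanceTable (absent units = 0)."""
    df = pd.DataFrame(rows).fillna(0.0)
    df = df[sorted(df.columns)]
    return AbundanceTable(values=df, normalized=False)


# ---------------------------------------------------------------------------
# filtering


def filter_units(
    table: AbundanceTable,
    min_copies: float = 10,
    min_samples: int = 1,
    common_mean: float = 100,
) -> tuple[AbundanceTable, AbundanceTable]:
    """Retain units seen at >= min_copies in >= min_samples samples.

    Returns (retained table, common-unit subset) where "common" units
    additionally have a cross-sample mean >= ``common_mean``.
    """
    df = table.values
    if df.empty:
        empty = AbundanceTable(values=df.copy(), normalized=table.normalized)
        return empty, empty
    keep = (df >= min_copies).sum(axis=0) >= min_samples
    retained = df.loc[:, keep]
    common = retained.loc[:, retained.mean(axis=0) >= common_mean]
    return (
        AbundanceTable(values=retained, normalized=table.normalized),
        AbundanceTable(values=common.copy(), normalized=table.normalized),
    )


# ---------------------------------------------------------------------------
# relatedness graph


def _strand_rotations(seq: str) -> set[str]:
    out = set(_rotations(seq))
    out.update(_rotations(reverse_complement(seq)))
    return out


def _one_substitution(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return any(
        sum(x != y for x, y in zip(ra, b)) == 1 for ra in _strand_rotations(a)
    )


def _one_indel(a: str, b: str) -> bool:
    # a is b plus one inserted base, under some rotation/strand
    if len(a) != len(b) + 1:
        return False
    for ra in _strand_rotations(a):
        for d in range(len(ra)):
            if ra[:d] + ra[d + 1 :] == b:
                return True
    return False


def _subcopy_duplication(a: str, b: str) -> bool:
    # a aligns to a doubled b with at most one substitution (e.g. AAAG-derived)
    if len(a) != 2 * len(b):
        return False
    bb = b + b
    return any(
        sum(x != y for x, y in zip(ra, bb)) <= 1 for ra in _strand_rotations(a)
    )


def relatedness_graph(
    units: Sequence[RepeatUnit | str],
    abundances: dict[str, float] | None = None,
) -> nx.Graph:
    """Graph of single-mutation relationships between canonical units.

    Edges carry ``edge_type``: "substitution" for a single-base difference at
    equal length (under rotation/strand), "indel/copy" for a single-base
    indel or a unit-duplication relationship.  Nodes carry ``abundance_rank``
    (1 = most abundant) when abundances are given.
    """
    canon = sorted({canonical_unit(str(u)).sequence for u in units})
    if len(canon) < 2:
        g = nx.Graph()
        g.add_nodes_from(canon)
        return g
    g = nx.Graph()
    g.add_nodes_from(canon)
    for i, a in enumerate(canon):
        for b in canon[i + 1 :]:
            la, lb = len(a), len(b)
            long, short = (a, b) if la >= lb else (b, a)
            if la == lb and _one_substitution(a, b):
                g.add_edge(a, b, edge_type="substitution")
            elif abs(la - lb) == 1 and _one_indel(long, short):
                g.add_edge(a, b, edge_type="indel/copy")
            elif _subcopy_duplication(long, short):
                g.add_edge(a, b, edge_type="indel/copy")
    if abundances:
        order = sorted(canon, key=lambda u: -abundances.get(u, 0.0))
        for rank, u in enumerate(order, start=1):
            g.nodes[u]["abundance_rank"] = rank
    return g
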