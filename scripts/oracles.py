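"""Independent reference implementations used for cross-checking.

Everything here is deliberately brute-force and self-contained (no imports
from the package under test): an exhaustive-alignment tandem-repeat scanner,
a numeric minimizer for Brownian-motion ancestral states, and a direct
enumeration of the exact two-sided binomial tail.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

_RC = str.maketrans("ACGT", "TGCA")


def _canonical(seq: str) -> str:
    # primitive period
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and seq[:p] * (n // p) == seq:
            seq = seq[:p]
            break
    cands = []
    for s in (seq, seq.translate(_RC)[::-1]):
        for i in range(len(s)):
            cands.append(s[i:] + s[:i])
    return min(cands)


def _is_primitive(seq: str) -> bool:
    n = len(seq)
    for p in range(1, n):
        if n % p == 0 and seq[:p] * (n // p) == seq:
            return False
    return True


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_exhaustive(read: str, i: int, k: int):
    """Forward greedy extension under the shared tandem-stretch contract."""
    unit = read[i : i + k]
    if "N" in unit:
        return None
    pos = i + k
    ncop = 1
    mism = 0
    gap = 0  # inexact copies since the last exact copy; at most 4 allowed
    chk = (pos, 1, 0)  # last position/copies/mismatches ending on an exact copy
    n = len(read)
    while pos + k <= n and gap <= 4:
        w = read[pos : pos + k]
        if w == unit:
            pos += k
            ncop += 1
            gap = 0
            chk = (pos, ncop, mism)
            continue
        if k > 2 and "N" not in w and _hamming(w, unit) == 1:
            pos += k
            ncop += 1
            mism += 1
            gap += 1
            continue
        if (k > 1 and read[pos] != "N" and pos + 1 + k <= n
                and read[pos + 1 : pos + 1 + k] == unit):
            pos += 1 + k
            ncop += 1
            gap += 1
            continue
        if k > 2:
            w2 = read[pos : pos + k - 1]
            if len(w2) == k - 1 and any(
                unit[:d] + unit[d + 1 :] == w2 for d in range(k)
            ):
                pos += k - 1
                ncop += 1
                gap += 1
                continue
        break
    end, ncop, mism = chk
    if ncop < 2:
        return None
    t = 0
    while end < n and t < k - 1 and read[end] == unit[t]:
        end += 1
        t += 1
    return end, mism


def oracle_scan_read(read: str, min_span: int = 50, max_unit: int = 20):
    """Exhaustive best-unit scan: every unit length at every offset.

    Returns (canonical unit, total copies, covered bases) of the single
    best unit, or None; the best unit maximises covered bases, ties broken
    by longer unit then lexicographically smallest canonical form.
    """
    read = read.upper()
    n = len(read)
    if n < min_span:
        return None
    per_unit: dict[str, list[tuple[int, int, int]]] = {}
    for k in range(1, min(max_unit, n // 2) + 1):
        for i in range(0, n - 2 * k + 1):
            tmpl = read[i : i + k]
            if k > 1 and not _is_primitive(tmpl):
                continue
            res = _extend_exhaustive(read, i, k)
            if res is None:
                continue
            end, _m = res
            if end - i >= min_span:
                per_unit.setdefault(_canonical(tmpl), []).append((i, end, k))
    if not per_unit:
        return None
    best = None
    for canon, stretches in per_unit.items():
        chosen: list[tuple[int, int, int]] = []
        for s in sorted(stretches, key=lambda t: (-(t[1] - t[0]), t[0])):
            if all(s[1] <= c[0] or s[0] >= c[1] for c in chosen):
                chosen.append(s)
        covered = sum(e - s for s, e, _ in chosen)
        copies = sum((e - s) // k for s, e, k in chosen)
        key = (covered, len(canon), [-ord(c) for c in canon])
        if best is None or key > best[0]:
            best = (key, canon, copies, covered)
    _, canon, copies, covered = best
    return canon, copies, covered


def bm_states_bruteforce(parent, length, is_tip, labels, tip_values: dict):
    """Ancestral states by numeric minimization of sum((dx)^2 / branch).

    ``parent``/``length``/``is_tip``/``labels`` describe the tree arrays;
    ``tip_values`` maps tip label -> value.  Returns internal label -> state.
    """
    parent = np.asarray(parent)
    length = np.asarray(length, dtype=float)
    is_tip = np.asarray(is_tip, dtype=bool)
    n = len(labels)
    int_idx = [i for i in range(n) if not is_tip[i]]
    pos_of = {i: j for j, i in enumerate(int_idx)}
    fixed = np.zeros(n)
    for i in range(n):
        if is_tip[i]:
            fixed[i] = tip_values[labels[i]]
    edges = [(i, parent[i], 1.0 / length[i]) for i in range(n) if parent[i] >= 0]

    def assemble(z):
        x = fixed.copy()
        for i, j in pos_of.items():
            x[i] = z[j]
        return x

    def cost(z):
        x = assemble(z)
        return sum(w * (x[i] - x[p]) ** 2 for i, p, w in edges)

    def grad(z):
        x = assemble(z)
        g = np.zeros(n)
        for i, p, w in edges:
            d = 2.0 * w * (x[i] - x[p])
            g[i] += d
            g[p] -= d
        return np.array([g[i] for i in int_idx])

    z0 = np.full(len(int_idx), np.mean(list(tip_values.values())))
    res = minimize(cost, z0, jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    return {labels[i]: float(res.x[pos_of[i]]) for i in int_idx}


def exact_binomial_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p-value at p=0.5 by direct enumeration.

    Sums P(X=i) over all outcomes no more probable than the observed one.
    """
    if n == 0:
        return float("nan")
    probs = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    pk = probs[k]
    return min(1.0, sum(p for p in probs if p <= pk * (1 + 1e-12)))
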