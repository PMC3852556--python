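"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dict counters, explicit loops,
no shared code with the package) so that package implementations are
checked against a genuinely independent path.
"""

from itertools import product

import numpy as np

BASES = "ACGT"


def random_dna(rng, length, ambiguous_rate=0.0):
    """A random nucleotide string, optionally salted with 'N's."""
    chars = []
    for _ in range(length):
        if ambiguous_rate and rng.random() < ambiguous_rate:
            chars.append("N")
        else:
            chars.append(BASES[rng.integers(4)])
    return "".join(chars)


def slide_count(bases, k, phase=None):
    """Dict of k-mer counts by explicit window sliding.

    Windows with non-ACGT characters are skipped; with ``phase`` only
    start positions congruent to it mod 3 are counted.
    """
    counts = {}
    for i in range(len(bases) - k + 1):
        if phase is not None and i % 3 != phase:
            continue
        w = bases[i : i + k]
        if any(c not in BASES for c in w):
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_freq_oracle(bases, k):
    counts = slide_count(bases, k)
    total = sum(counts.values())
    return np.array(
        [counts.get("".join(m), 0) / total for m in product(BASES, repeat=k)]
    )


def zcurve_oracle(bases):
    """252 Z-curve components by direct per-prefix frequency evaluation."""
    out = []
    for phase in (None, 0, 1, 2):
        for k in (1, 2, 3):
            counts = slide_count(bases, k, phase)
            prefixes = ["".join(p) for p in product(BASES, repeat=k - 1)] or [""]
            for s in prefixes:
                n = {b: counts.get(s + b, 0) for b in BASES}
                tot = sum(n.values())
                if tot == 0:
                    out.extend([0.0, 0.0, 0.0])
                    continue
                f = {b: n[b] / tot for b in BASES}
                out.append((f["A"] + f["G"]) - (f["C"] + f["T"]))
                out.append((f["A"] + f["C"]) - (f["G"] + f["T"]))
                out.append((f["A"] + f["T"]) - (f["G"] + f["C"]))
    return np.array(out)


def gc_oracle(bases):
    good = [c for c in bases if c in BASES]
    return (good.count("G") + good.count("C")) / len(good)


def rho_oracle(bases):
    mono = slide_count(bases, 1)
    tot1 = sum(mono.values())
    di = slide_count(bases, 2)
    tot2 = sum(di.values())
    out = []
    for x in BASES:
        for y in BASES:
            fx = mono.get(x, 0) / tot1
            fy = mono.get(y, 0) / tot1
            fxy = di.get(x + y, 0) / tot2
            out.append(fxy / (fx * fy) if fx * fy > 0 else 0.0)
    return np.array(out)


def dinuc_profile_oracle(bases, table):
    """Window-by-window average of property rows (pandas DataFrame)."""
    sums = None
    n = 0
    for i in range(len(bases) - 1):
        w = bases[i : i + 2]
        if any(c not in BASES for c in w):
            continue
        row = table.loc[w].to_numpy(dtype=float)
        sums = row if sums is None else sums + row
        n += 1
    return sums / n


def pls1_oracle(X, y, n_components):
    """Textbook PLS1 with normalized weights and X-side deflation."""
    Xc = np.array(X, dtype=float)
    yc = np.array(y, dtype=float) - float(np.mean(y))
    W, P, C = [], [], []
    for _ in range(n_components):
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        c = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        W.append(w)
        P.append(p)
        C.append(c)
    W = np.array(W).T
    P = np.array(P).T
    C = np.array(C)
    return W @ np.linalg.solve(P.T @ W, C)


def soft_threshold_objective(u, m, lam, omega):
    """The penalized rank-one objective for a candidate weight vector."""
    return float(np.sum((m - u) ** 2) + 2.0 * lam * np.sum(omega * np.abs(u)))
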