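"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (pure-Python
dynamic programming, normal equations, union-find over all pairs) so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Classic O(nm) edit-distance DP."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def identity_oracle(a: str, b: str) -> float:
    """Orientation-insensitive identity: 1 − editDistance/max length."""
    d = min(levenshtein(a, b), levenshtein(a, rc(b)))
    return 1.0 - d / max(len(a), len(b))


def single_linkage_partition(seqs: list[str], threshold: float) -> list[set[int]]:
    """Brute-force single linkage: connected components of the all-pairs
    identity-threshold graph."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identity_oracle(seqs[i], seqs[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)


def ols_normal_equations(x, y) -> tuple[float, float, float]:
    """Closed-form OLS (slope, intercept, R²) via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot else np.nan
    return float(beta[0]), float(beta[1]), r2


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions at distinct positions, each to a different base."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def clustering_instance(seed: int) -> tuple[list[str], float]:
    """A random locus-clustering instance: 2–5 independent families of
    100–150 bp founders, each copied with 0–10% per-copy substitution
    divergence (so within-family pairwise divergence spans 0–20%), at most
    50 loci total."""
    rng = np.random.default_rng(seed)
    n_fam = int(rng.integers(2, 6))
    seqs: list[str] = []
    for _ in range(n_fam):
        length = int(rng.integers(100, 151))
        founder = "".join(rng.choice(list("ACGT"), size=length))
        n_copies = int(rng.integers(3, 11))
        for _ in range(n_copies):
            if len(seqs) >= 50:
                break
            d = rng.uniform(0.0, 0.10)
            copy = mutate(founder, int(round(d * length)), rng)
            if rng.random() < 0.5:
                copy = rc(copy)
            seqs.append(copy)
    return seqs, 0.90
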