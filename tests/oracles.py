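"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles against the stated
definitions (window complementarity, exhaustive duplex alignments,
hypergeometric enumeration, permutation tests) and never calls the code
paths it checks.
"""

import itertools
import math

import numpy as np

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_seed_sites(mirna_seq: str, transcript_seq: str) -> list[int]:
    """1-based starts of windows reverse-complementary to miRNA pos 2-8."""
    seed = mirna_seq[1:8]  # positions 2..8, 1-based inclusive
    starts = []
    for s in range(len(transcript_seq) - 6):
        window = transcript_seq[s:s + 7]
        # window (5'->3') pairs antiparallel with the seed (5'->3'):
        # window base t pairs with seed base 6-t
        if all(_COMP[seed[6 - t]] == window[t] for t in range(7)):
            starts.append(s + 1)
    return starts


def _pair_energy(x: str, y: str, model):
    pair = x + y
    if pair in ("GC", "CG"):
        return model.gc
    if pair in ("AU", "UA"):
        return model.au
    if pair in ("GU", "UG"):
        return model.gu
    return None


def brute_force_duplex_mfe(a: str, b: str, model) -> float:
    """Exhaustive enumeration of all antiparallel duplex alignments.

    Pairs (i, j) advance with i increasing on strand a and j decreasing
    on strand b; adjacent pairs stack with the mean of their per-pair
    energies, non-adjacent steps pay an affine loop penalty, lone pairs
    and dangling ends are free.
    """
    n, m = len(a), len(b)
    best = 0.0

    def extend(li, lj, energy):
        nonlocal best
        best = min(best, energy)
        for i in range(li + 1, n):
            for j in range(lj - 1, -1, -1):
                pe = _pair_energy(a[i], b[j], model)
                if pe is None:
                    continue
                if i == li + 1 and j == lj - 1:
                    step = (_pair_energy(a[li], b[lj], model) + pe) / 2.0
                else:
                    gap = (i - li - 1) + (lj - j - 1)
                    step = model.loop_open + model.loop_extend * gap
                extend(i, j, energy + step)

    for i in range(n):
        for j in range(m):
            if _pair_energy(a[i], b[j], model) is not None:
                extend(i, j, 0.0)
    return best


def brute_force_hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of counting ratios."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def exhaustive_ttest_permutation_p(case, control) -> float:
    """Exact permutation p for |t| over all group relabelings."""
    pooled = np.concatenate([np.asarray(case, float), np.asarray(control, float)])
    n_case = len(case)

    def welch_abs_t(a, b):
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        if se == 0.0:
            return 0.0
        return abs((a.mean() - b.mean()) / se)

    observed = welch_abs_t(pooled[:n_case], pooled[n_case:])
    idx = set(range(len(pooled)))
    hits = total = 0
    for combo in itertools.combinations(sorted(idx), n_case):
        a = pooled[list(combo)]
        b = pooled[sorted(idx - set(combo))]
        total += 1
        if welch_abs_t(a, b) >= observed - 1e-12:
            hits += 1
    return hits / total


def permutation_pearson_p(x, y, n_perm: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo permutation p for |r| with add-one smoothing."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    xc = (x - x.mean()) / x.std()
    pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    r_perm = np.abs(pc @ xc / len(x))
    return (1 + int((r_perm >= r_obs - 1e-12).sum())) / (n_perm + 1)
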