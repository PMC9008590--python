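"""Independent oracles used by the test suite.

Each oracle deliberately takes a different computational route from the
implementation it checks: recursive kinship coefficients and Monte-Carlo
gene dropping for the tabular relationship matrix; a fine grid search over
the two-locus haplotype-frequency simplex for the EM linkage-disequilibrium
estimates; exhaustive enumeration of candidate marker ranges for the
solid-spine block builder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN = "0"


# ---------------------------------------------------------------------------
# kinship oracles
# ---------------------------------------------------------------------------

def kinship_recursive(pedigree: pd.DataFrame) -> np.ndarray:
    """Expected additive relationship by the recursive kinship coefficient.

    a_ij = 2 * phi_ij with phi the probability that one allele sampled from
    each individual is identical by descent; phi(i,i) = 1/2 + phi(s,d)/2.
    """
    ids = pedigree["id"].tolist()
    idx = {v: k for k, v in enumerate(ids)}
    par = [(idx.get(s, -1) if s != UNKNOWN else -1,
            idx.get(d, -1) if d != UNKNOWN else -1)
           for s, d in zip(pedigree["sire"], pedigree["dam"])]
    n = len(ids)
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        key = (min(i, j), max(i, j))
        if key in memo:
            return memo[key]
        if i == j:
            s, d = par[i]
            val = 0.5 + 0.5 * phi(s, d)
        else:
            # recurse on the later-born individual (parents precede offspring)
            a, b = (i, j) if i > j else (j, i)
            s, d = par[a]
            val = 0.5 * (phi(s, b) + phi(d, b))
        memo[key] = val
        return val

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2 * phi(i, j) if i != j else 2 * phi(i, i)
    return A


def gene_dropping(pedigree: pd.DataFrame, n_rep: int, seed: int):
    """Monte-Carlo additive relationships by dropping unique founder alleles.

    Returns (estimate, standard error) matrices. The relationship estimate
    for a pair is twice the average IBD probability over the four
    allele-pair comparisons, estimated across replicates (vectorized over
    the replicate axis).
    """
    rng = np.random.default_rng(seed)
    ids = pedigree["id"].tolist()
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    alleles = np.empty((n, 2, n_rep), dtype=np.int32)
    counter = 0
    for k, (s, d) in enumerate(zip(pedigree["sire"], pedigree["dam"])):
        for slot, parent in enumerate((s, d)):
            if parent == UNKNOWN or parent not in idx:
                alleles[k, slot, :] = counter
                counter += 1
            else:
                p = idx[parent]
                pick = rng.integers(0, 2, size=n_rep)
                alleles[k, slot, :] = alleles[p, 0, :] * (pick == 0) \
                    + alleles[p, 1, :] * (pick == 1)
    est = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            share = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    share += alleles[i, a, :] == alleles[j, b, :]
            vals = share / 2.0     # 2 * mean over the 4 comparisons
            est[i, j] = est[j, i] = vals.mean()
            se[i, j] = se[j, i] = vals.std(ddof=1) / np.sqrt(n_rep)
    return est, se


def random_pedigree(n: int, seed: int) -> pd.DataFrame:
    """Random multi-generation pedigree (parents precede offspring)."""
    rng = np.random.default_rng(seed)
    rows = []
    n_founders = max(3, n // 3)
    for i in range(n):
        if i < n_founders:
            sire = dam = UNKNOWN
        else:
            k = rng.integers(0, i, size=2)
            sire = f"I{min(k)}" if rng.random() < 0.85 else UNKNOWN
            dam = f"I{max(k)}" if rng.random() < 0.9 else UNKNOWN
            if sire == dam:
                sire = UNKNOWN
        rows.append((f"I{i}", sire, dam, "F0", "P0", 0, 0 if i < n_founders else 1))
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "family",
                                       "provenance", "block", "generation"])


# ---------------------------------------------------------------------------
# LD oracle
# ---------------------------------------------------------------------------

def grid_search_pair_ld(g1: np.ndarray, g2: np.ndarray, n_grid: int = 4001):
    """ML two-locus haplotype frequency by direct grid search.

    Allele frequencies are fixed by the genotype counts; the only free
    parameter is the AB-haplotype frequency, scanned on a fine grid over its
    feasible interval. Returns (dprime, lod, r2) from the grid maximizer.
    """
    from cyanophen.ldblocks import _genotype_loglik, _genotype_table, haplotype_ld

    tab = _genotype_table(np.asarray(g1), np.asarray(g2))
    n_g = 2.0 * tab.sum()
    p_a = (2 * tab[2, :].sum() + tab[1, :].sum()) / n_g
    p_b = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / n_g
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.linspace(lo + 1e-9, hi - 1e-9, n_grid)
    best_ll, best_pab = -np.inf, p_a * p_b
    for pab in grid:
        freqs = np.array([pab, p_a - pab, p_b - pab, 1 - p_a - p_b + pab])
        ll = _genotype_loglik(tab, freqs)
        if ll > best_ll:
            best_ll, best_pab = ll, pab
    dprime, r2 = haplotype_ld(best_pab, p_a, p_b)
    indep = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                      (1 - p_a) * (1 - p_b)])
    lod = (best_ll - _genotype_loglik(tab, indep)) / np.log(10.0)
    return dprime, max(lod, 0.0), r2


# ---------------------------------------------------------------------------
# solid-spine enumeration oracle
# ---------------------------------------------------------------------------

def spine_blocks_bruteforce(D: np.ndarray, L: np.ndarray, dprime_min: float,
                            lod_min: float) -> list[tuple[int, int]]:
    """All-ranges enumeration with the same selection semantics as the
    greedy builder: at each anchor take the longest spine-valid range,
    emit it only if the block-summary retention passes, resume after it."""
    m = D.shape[0]

    def valid(i, j):
        if not (np.isfinite(D[i, j]) and D[i, j] >= dprime_min):
            return False
        return all(np.isfinite(D[i, k]) and D[i, k] >= dprime_min
                   and np.isfinite(D[k, j]) and D[k, j] >= dprime_min
                   for k in range(i + 1, j))

    candidates = {(i, j) for i in range(m) for j in range(i + 1, m) if valid(i, j)}
    out = []
    i = 0
    while i < m - 1:
        ext = [j for (a, j) in candidates if a == i]
        if not ext:
            i += 1
            continue
        j = max(ext)
        pairs = [(p, q) for p in range(i, j + 1) for q in range(p + 1, j + 1)]
        mean_d = np.nanmean([D[p, q] for p, q in pairs])
        mean_l = np.nanmean([L[p, q] for p, q in pairs])
        if mean_d >= dprime_min and mean_l >= lod_min:
            out.append((i, j))
        i = j + 1
    return out
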