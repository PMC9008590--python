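"""Additive relationship matrices and their factorizations.

Implements the pedigree numerator relationship matrix A (tabular method),
the VanRaden method-1 genomic relationship matrix G, fixed covariates for
population structure, and the eigen-factorization used to fit
relationship-matrix random effects as ordinary regressor blocks inside the
Gibbs samplers (a = L alpha with L L' = K, alpha ~ N(0, sigma2 I)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .syndata import UNKNOWN


@dataclass
class RelationshipMatrix:
    values: np.ndarray      # (n, n) symmetric
    ids: list[str]
    kind: str               # "pedigree" | "genomic"

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class FactorLoadings:
    """L with L L' ~= K over the retained eigenmodes."""

    loadings: np.ndarray    # (n, r)
    eigenvalues: np.ndarray
    ids: list[str]
    kind: str

    @property
    def rank(self) -> int:
        return self.loadings.shape[1]

    def rows(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(i) for i in ids]
        return self.loadings[idx]


def a_matrix(pedigree: pd.DataFrame, reorder: bool = True) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a(sire,dam)/2 (0 when either parent is unknown);
    a_ij = (a(j,sire_i) + a(j,dam_i)) / 2 for j preceding i. Unknown parents
    are unrelated, non-inbred founders.
    """
    ped = pedigree[["id", "sire", "dam"]].copy()
    order = _topological_order(ped)
    if order is None:
        raise ValueError("pedigree contains a cycle")
    if list(order) != list(range(len(ped))):
        if not reorder:
            raise ValueError("pedigree not topologically ordered")
        ped = ped.iloc[order].reset_index(drop=True)
    ids = ped["id"].tolist()
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [index.get(s, -1) if s != UNKNOWN else -1 for s in ped["sire"]]
    dams = [index.get(d, -1) if d != UNKNOWN else -1 for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    return RelationshipMatrix(A, ids, "pedigree")


def _topological_order(ped: pd.DataFrame):
    """Parents-before-offspring order, or None on a cycle."""
    ids = ped["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    index = {i: k for k, i in enumerate(ids)}
    state = np.zeros(len(ids), dtype=np.int8)   # 0 new, 1 active, 2 done
    order: list[int] = []
    parents = [[index[p] for p in (s, d) if p != UNKNOWN and p in index]
               for s, d in zip(ped["sire"], ped["dam"])]
    for start in range(len(ids)):
        if state[start]:
            continue
        stack = [(start, 0)]
        while stack:
            node, pi = stack[-1]
            if state[node] == 2:
                stack.pop()
                continue
            state[node] = 1
            if pi < len(parents[node]):
                stack[-1] = (node, pi + 1)
                nxt = parents[node][pi]
                if state[nxt] == 1:
                    return None
                if state[nxt] == 0:
                    stack.append((nxt, 0))
            else:
                state[node] = 2
                order.append(node)
                stack.pop()
    return order


def g_matrix(genotypes) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = W W' / (2 sum p_k (1 - p_k)) with W the dosage matrix centered at
    twice the observed allele frequency. Monomorphic markers carry no
    information and are excluded from the denominator and numerator alike.
    """
    dos = np.asarray(genotypes.dosages, dtype=float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers")
    W = dos[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return RelationshipMatrix(W @ W.T / denom, list(genotypes.ids), "genomic")


def structure_covariates(source, n_components: int = 0) -> pd.DataFrame:
    """Fixed covariates standing in for the population-structure matrix Q.

    Group mode (``source`` is a label sequence): treatment-coded indicator
    columns with the first level as reference. PC mode (``source`` is a
    RelationshipMatrix): leading eigenvectors of the doubly centered kinship.
    """
    if isinstance(source, RelationshipMatrix):
        K = source.values
        n = K.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        vals, vecs = np.linalg.eigh(J @ K @ J)
        order = np.argsort(vals)[::-1][:n_components]
        return pd.DataFrame(vecs[:, order], index=source.ids,
                            columns=[f"PC{k + 1}" for k in range(len(order))])
    labels = pd.Series(list(source))
    dummies = pd.get_dummies(labels, prefix="grp", drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        import warnings
        warnings.warn("single structure group: empty covariate set")
    return dummies


def decompose(K: RelationshipMatrix, tol: float = 1e-8) -> FactorLoadings:
    """Eigen-factorization K = U L U'; returns L_r = U_r diag(sqrt(lambda_r)).

    Eigenvalues below ``tol * lambda_max`` (including numerically negative
    modes) are truncated; asymmetry beyond 1e-8 is an error.
    """
    M = K.values
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("relationship matrix is not symmetric")
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    lam_max = max(vals.max(), 0.0)
    keep = vals > tol * lam_max
    vals_k = vals[keep]
    L = vecs[:, keep] * np.sqrt(vals_k)[None, :]
    return FactorLoadings(L, vals_k, list(K.ids), K.kind)
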