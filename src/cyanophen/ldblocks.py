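"""Linkage disequilibrium, solid-spine haplotype blocks, haplotype design.

Pairwise D', LOD and r2 are computed per chromosome inside a physical
window, either from phased gamete counts or by two-locus EM on unphased
dosages. Blocks follow the solid-spine rule: both end markers of a block
must be in strong LD (D' above threshold) with every interior marker and
with each other; a block is retained only if its mean pairwise D' and mean
LOD clear the published thresholds (D' >= 0.9, LOD >= 2). Retained blocks
are expanded into haplotype-allele dosage columns used as the haplotype
regressor block g2 of the prediction models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_LOG10 = np.log(10.0)


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def haplotype_ld(p_ab: float, p_a: float, p_b: float) -> tuple[float, float]:
    """(D', r2) from the AB-haplotype frequency and the two allele
    frequencies (upper-case = allele counted by the dosage)."""
    D = p_ab - p_a * p_b
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if min(p_a, qa, p_b, qb) <= 0:
        return np.nan, np.nan
    if D >= 0:
        dmax = min(p_a * qb, qa * p_b)
    else:
        dmax = min(p_a * p_b, qa * qb)
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (p_a * qa * p_b * qb)
    return min(dprime, 1.0), min(r2, 1.0)


def _hap_loglik(freqs: np.ndarray, counts: np.ndarray) -> float:
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.maximum(freqs[mask], 1e-300))))


def phased_pair_ld(h1: np.ndarray, h2: np.ndarray) -> tuple[float, float, float]:
    """D', LOD, r2 from phased gametes (arrays of 0/1 alleles per gamete)."""
    n = h1.size
    counts = np.array([
        np.sum((h1 == 1) & (h2 == 1)), np.sum((h1 == 1) & (h2 == 0)),
        np.sum((h1 == 0) & (h2 == 1)), np.sum((h1 == 0) & (h2 == 0)),
    ], dtype=float)
    freqs = counts / n
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    dprime, r2 = haplotype_ld(freqs[0], p_a, p_b)
    indep = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                      (1 - p_a) * (1 - p_b)])
    lod = (_hap_loglik(freqs, counts) - _hap_loglik(indep, counts)) / _LOG10
    return dprime, max(lod, 0.0), r2


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    tab = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            tab[a, b] = np.sum((g1 == a) & (g2 == b))
    return tab


def _genotype_loglik(tab: np.ndarray, p: np.ndarray) -> float:
    """Log-likelihood of a 3x3 two-locus genotype table given haplotype
    frequencies p = (pAB, pAb, paB, pab) under random mating."""
    pab, pAb, paB, pAB = p[3], p[1], p[2], p[0]
    cell = np.empty((3, 3))
    cell[2, 2] = pAB ** 2
    cell[2, 1] = 2 * pAB * pAb
    cell[2, 0] = pAb ** 2
    cell[1, 2] = 2 * pAB * paB
    cell[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    cell[1, 0] = 2 * pAb * pab
    cell[0, 2] = paB ** 2
    cell[0, 1] = 2 * paB * pab
    cell[0, 0] = pab ** 2
    mask = tab > 0
    return float(np.sum(tab[mask] * np.log(np.maximum(cell[mask], 1e-300))))


def em_pair_ld(g1: np.ndarray, g2: np.ndarray, max_iter: int = 200,
               tol: float = 1e-10) -> tuple[float, float, float]:
    """D', LOD, r2 from unphased dosages via the two-locus EM algorithm.

    Only the coupling of the double heterozygote is latent; EM iterates the
    expected AB-gamete count. The LOD compares the maximized likelihood with
    the linkage-equilibrium likelihood at the same allele frequencies.
    """
    tab = _genotype_table(np.asarray(g1), np.asarray(g2))
    n_g = 2.0 * tab.sum()
    p_a = (2 * tab[2, :].sum() + tab[1, :].sum()) / n_g
    p_b = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / n_g
    p_ab = p_a * p_b
    n_dh = tab[1, 1]
    # fixed gamete contributions from unambiguous genotypes
    fixed_ab = (2 * tab[2, 2] + tab[2, 1] + tab[1, 2])
    for _ in range(max_iter):
        p_Ab = max(p_a - p_ab, 0.0)
        p_aB = max(p_b - p_ab, 0.0)
        p_small = max(1.0 - p_a - p_b + p_ab, 0.0)
        denom = p_ab * p_small + p_Ab * p_aB
        frac = 0.5 if denom <= 0 else p_ab * p_small / denom
        # a coupling-phase double het carries exactly one AB gamete
        new = (fixed_ab + n_dh * frac) / n_g
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    freqs = np.array([p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab])
    freqs = np.clip(freqs, 0.0, 1.0)
    dprime, r2 = haplotype_ld(p_ab, p_a, p_b)
    indep = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                      (1 - p_a) * (1 - p_b)])
    lod = (_genotype_loglik(tab, freqs) - _genotype_loglik(tab, indep)) / _LOG10
    return dprime, max(lod, 0.0), r2


@dataclass
class LDStats:
    """Dense within-window D'/LOD/r2 matrices, one set per chromosome.

    Entries outside the physical window, or involving a monomorphic marker,
    are NaN. ``offsets`` maps each chromosome to the global index of its
    first marker so blocks can address genotype columns.
    """

    chroms: list[int]
    dprime: dict[int, np.ndarray]
    lod: dict[int, np.ndarray]
    r2: dict[int, np.ndarray]
    offsets: dict[int, int]
    pos: dict[int, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            D = self.dprime[c]
            for i, j in zip(*np.triu_indices_from(D, k=1)):
                if np.isfinite(D[i, j]):
                    rows.append((c, i, j, D[i, j], self.lod[c][i, j], self.r2[c][i, j]))
        return pd.DataFrame(rows, columns=["chrom", "i", "j", "dprime", "lod", "r2"])


def pairwise_ld(genotypes, max_pair_distance: int = 500_000) -> LDStats:
    """All intra-chromosome marker pairs within ``max_pair_distance`` bp.

    Uses direct gamete counting when phased haplotypes are available,
    otherwise the two-locus EM. Pairs involving a monomorphic marker are
    skipped (NaN) with a warning.
    """
    chroms = sorted(set(int(c) for c in genotypes.chrom))
    dpr, lods, r2s, offs, poss = {}, {}, {}, {}, {}
    phased = genotypes.haplotypes is not None
    skipped = 0
    for c in chroms:
        sel = np.where(genotypes.chrom == c)[0]
        offs[c] = int(sel[0])
        poss[c] = genotypes.pos[sel]
        m = sel.size
        D = np.full((m, m), np.nan)
        L = np.full((m, m), np.nan)
        R = np.full((m, m), np.nan)
        G = genotypes.dosages[:, sel]
        freq = G.mean(axis=0) / 2.0
        poly = (freq > 0) & (freq < 1)
        skipped += int((~poly).sum())
        pos = genotypes.pos[sel]
        if phased:
            H = np.ascontiguousarray(
                genotypes.haplotypes[:, sel, :].transpose(0, 2, 1)
                .reshape(-1, m).astype(np.float64))
            n_g = H.shape[0]
            p = H.mean(axis=0)
            max_off = 0
            for i in range(m):
                jmax = np.searchsorted(pos, pos[i] + max_pair_distance, "right")
                max_off = max(max_off, jmax - 1 - i)
            for o in range(1, max_off + 1):
                i_idx = np.arange(0, m - o)
                ok = (pos[i_idx + o] - pos[i_idx] <= max_pair_distance) \
                    & poly[i_idx] & poly[i_idx + o]
                i_idx = i_idx[ok]
                if i_idx.size == 0:
                    continue
                j_idx = i_idx + o
                p_ab = np.einsum("gi,gi->i", H[:, i_idx], H[:, j_idx]) / n_g
                d, l, r = _vector_ld(p_ab, p[i_idx], p[j_idx], n_g)
                D[i_idx, j_idx] = D[j_idx, i_idx] = d
                L[i_idx, j_idx] = L[j_idx, i_idx] = l
                R[i_idx, j_idx] = R[j_idx, i_idx] = r
        else:
            for i in range(m - 1):
                if not poly[i]:
                    continue
                jmax = np.searchsorted(pos, pos[i] + max_pair_distance, "right")
                for j in range(i + 1, jmax):
                    if not poly[j]:
                        continue
                    D[i, j], L[i, j], R[i, j] = em_pair_ld(G[:, i], G[:, j])
                    D[j, i], L[j, i], R[j, i] = D[i, j], L[i, j], R[i, j]
        dpr[c], lods[c], r2s[c] = D, L, R
    if skipped:
        warnings.warn(f"{skipped} monomorphic markers skipped in LD computation")
    return LDStats(chroms, dpr, lods, r2s, offs, poss)


def _vector_ld(p_ab, p_a, p_b, n_g):
    """Vectorized D'/LOD/r2 from gamete frequencies (phased counting)."""
    qa, qb = 1.0 - p_a, 1.0 - p_b
    Dc = p_ab - p_a * p_b
    dmax = np.where(Dc >= 0, np.minimum(p_a * qb, qa * p_b),
                    np.minimum(p_a * p_b, qa * qb))
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(dmax > 0, np.abs(Dc) / dmax, 0.0)
        r2 = Dc * Dc / (p_a * qa * p_b * qb)
    counts = np.stack([p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab]) * n_g
    counts = np.clip(counts, 0.0, None)
    freqs = counts / n_g
    indep = np.stack([p_a * p_b, p_a * qb, qa * p_b, qa * qb])
    with np.errstate(divide="ignore", invalid="ignore"):
        ll1 = np.where(counts > 0, counts * np.log(np.maximum(freqs, 1e-300)), 0.0)
        ll0 = np.where(counts > 0, counts * np.log(np.maximum(indep, 1e-300)), 0.0)
    lod = (ll1.sum(axis=0) - ll0.sum(axis=0)) / _LOG10
    return np.minimum(dprime, 1.0), np.maximum(lod, 0.0), np.minimum(r2, 1.0)


# ---------------------------------------------------------------------------
# solid-spine blocks
# ---------------------------------------------------------------------------

@dataclass
class Block:
    chrom: int
    start: int            # local marker index on the chromosome, inclusive
    stop: int             # inclusive
    global_start: int
    global_stop: int
    mean_dprime: float
    mean_lod: float

    @property
    def size(self) -> int:
        return self.stop - self.start + 1


@dataclass
class BlockSet:
    blocks: list[Block] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def to_frame(self, ld: LDStats | None = None) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            start_pos = stop_pos = -1
            if ld is not None:
                start_pos = int(ld.pos[b.chrom][b.start])
                stop_pos = int(ld.pos[b.chrom][b.stop])
            rows.append((b.chrom, b.start, b.stop, start_pos, stop_pos, b.size,
                         b.mean_dprime, b.mean_lod))
        return pd.DataFrame(rows, columns=["chrom", "start", "stop", "startPos",
                                           "stopPos", "nMarkers", "meanDprime",
                                           "meanLOD"])


def _spine_valid(D: np.ndarray, i: int, j: int, t: float) -> bool:
    """Both endpoints in strong LD with every interior marker and each other."""
    if not np.isfinite(D[i, j]) or D[i, j] < t:
        return False
    for k in range(i + 1, j):
        if not (np.isfinite(D[i, k]) and D[i, k] >= t):
            return False
        if not (np.isfinite(D[k, j]) and D[k, j] >= t):
            return False
    return True


def _block_summary(D: np.ndarray, L: np.ndarray, i: int, j: int) -> tuple[float, float]:
    idx = np.arange(i, j + 1)
    sub_d = D[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
    sub_l = L[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
    return float(np.nanmean(sub_d)), float(np.nanmean(sub_l))


def solid_spine_blocks(ld: LDStats, dprime_min: float = 0.9, lod_min: float = 2.0,
                       pairwise_filter: bool = False) -> BlockSet:
    """Greedy left-to-right solid-spine block construction.

    From each anchor marker the longest spine-valid extension is taken; the
    candidate block is emitted only if its retention summary passes
    (block-mean pairwise D' >= ``dprime_min`` and mean LOD >= ``lod_min``; or
    every pair individually when ``pairwise_filter``). The scan resumes after
    the candidate's right end whether or not it was retained, so the result
    matches exhaustive enumeration under the same selection rule.
    """
    out = BlockSet()
    for c in ld.chroms:
        D, L = ld.dprime[c], ld.lod[c]
        m = D.shape[0]
        i = 0
        while i < m - 1:
            best = -1
            for j in range(i + 1, m):
                if _spine_valid(D, i, j, dprime_min):
                    best = j
                elif not np.isfinite(D[i, j]):
                    # outside window or monomorphic: no longer extension possible
                    break
            if best < 0:
                i += 1
                continue
            if pairwise_filter:
                idx = np.arange(i, best + 1)
                sub_d = D[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
                sub_l = L[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
                ok = bool(np.all(sub_d >= dprime_min) and np.all(sub_l >= lod_min))
                mean_d, mean_l = float(np.nanmean(sub_d)), float(np.nanmean(sub_l))
            else:
                mean_d, mean_l = _block_summary(D, L, i, best)
                ok = mean_d >= dprime_min and mean_l >= lod_min
            if ok:
                out.blocks.append(Block(c, i, best, ld.offsets[c] + i,
                                        ld.offsets[c] + best, mean_d, mean_l))
            i = best + 1
    return out


# ---------------------------------------------------------------------------
# haplotype design matrix
# ---------------------------------------------------------------------------

@dataclass
class HaploMatrix:
    values: np.ndarray             # (n, H) dosages of non-reference alleles
    columns: list[tuple[int, str]]  # (block index, haplotype-allele string)
    ids: list[str]
    reference: list[str]           # reference allele per block
    block_dosages: list[np.ndarray]  # per block: (n, n_alleles) incl. reference

    def to_frame(self) -> pd.DataFrame:
        cols = [f"blk{b}_{h}" for b, h in self.columns]
        return pd.DataFrame(self.values, index=self.ids, columns=cols)


def _phase_block_em(G: np.ndarray, max_iter: int = 100):
    """Multi-locus EM phasing of one short block from unphased dosages.

    Enumerates the haplotype pairs compatible with each genotype vector,
    iterates haplotype frequencies, and assigns each individual its most
    probable pair. Intended for short blocks (< ~12 heterozygous sites).
    """
    n, m = G.shape
    pair_sets = []
    hap_ids: dict[tuple, int] = {}

    def hid(h):
        return hap_ids.setdefault(tuple(h), len(hap_ids))

    for g in G:
        het = np.where(g == 1)[0]
        base1 = np.where(g == 2, 1, 0)
        if het.size == 0:
            pairs = [(hid(base1), hid(base1))]
        else:
            if het.size > 12:
                raise ValueError("block too heterozygous for enumeration EM")
            pairs = []
            for assign in itertools.product([0, 1], repeat=het.size - 1):
                h1 = base1.copy()
                h2 = base1.copy()
                h1[het[0]] = 1
                for k, a in enumerate(assign):
                    h1[het[k + 1]] = a
                    h2[het[k + 1]] = 1 - a
                pairs.append((hid(h1), hid(h2)))
        pair_sets.append(pairs)
    H = len(hap_ids)
    freqs = np.full(H, 1.0 / H)
    for _ in range(max_iter):
        new = np.zeros(H)
        for pairs in pair_sets:
            w = np.array([freqs[a] * freqs[b] * (1 if a == b else 2) for a, b in pairs])
            tot = w.sum()
            w = np.full(len(pairs), 1.0 / len(pairs)) if tot <= 0 else w / tot
            for (a, b), wk in zip(pairs, w):
                new[a] += wk
                new[b] += wk
        new /= 2 * n
        if np.max(np.abs(new - freqs)) < 1e-10:
            freqs = new
            break
        freqs = new
    inv = {v: np.array(k) for k, v in hap_ids.items()}
    assigned = np.zeros((n, m, 2), dtype=np.int8)
    for r, pairs in enumerate(pair_sets):
        w = [freqs[a] * freqs[b] * (1 if a == b else 2) for a, b in pairs]
        a, b = pairs[int(np.argmax(w))]
        assigned[r, :, 0] = inv[a]
        assigned[r, :, 1] = inv[b]
    return assigned


def haplotype_design(genotypes, blocks: BlockSet, rare_freq: float = 0.01) -> HaploMatrix:
    """Haplotype-allele dosage design (the Z2 regressor block).

    Per block, observed haplotype alleles are enumerated over the 2n gametes
    (EM-phased if no phase is available); alleles rarer than ``rare_freq``
    are pooled into the most frequent (reference) allele, whose column is
    dropped. Within a block every individual's dosages over all alleles
    (reference included) sum to 2.
    """
    n = genotypes.n
    cols, names, refs, block_dos = [], [], [], []
    for b_idx, b in enumerate(blocks.blocks):
        sl = slice(b.global_start, b.global_stop + 1)
        if genotypes.haplotypes is not None:
            hap = genotypes.haplotypes[:, sl, :]
        else:
            hap = _phase_block_em(genotypes.dosages[:, sl].astype(np.int8))
        gam = hap.transpose(0, 2, 1).reshape(2 * n, -1)
        codes = np.array(["".join(map(str, g)) for g in gam])
        alleles, counts = np.unique(codes, return_counts=True)
        freqs = counts / (2 * n)
        ref = alleles[np.argmax(counts)]
        common = [a for a, f in zip(alleles, freqs) if a != ref and f >= rare_freq]
        rare = [a for a, f in zip(alleles, freqs) if a != ref and f < rare_freq]
        pooled = set(rare) | {ref}
        per_ind = codes.reshape(n, 2)
        dos_all = np.zeros((n, len(common) + 1))
        for k, a in enumerate(common):
            dos_all[:, k] = (per_ind == a).sum(axis=1)
        dos_all[:, -1] = np.isin(per_ind, list(pooled)).sum(axis=1)
        block_dos.append(dos_all)
        refs.append(ref)
        if not common:
            warnings.warn(f"block {b_idx} has a single common haplotype; no columns")
            continue
        for k, a in enumerate(common):
            cols.append(dos_all[:, k])
            names.append((b_idx, a))
    values = np.column_stack(cols) if cols else np.zeros((n, 0))
    return HaploMatrix(values, names, list(genotypes.ids), refs, block_dos)
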