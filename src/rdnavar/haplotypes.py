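"""Haplotype deconvolution from pooled allele-frequency matrices.

Model: an individual's rDNA pool is a mixture of K sequence haplotypes.
With F the observed N-samples × S-sites allele-2 frequency matrix, we seek
a binary haplotype matrix H (K × S, allele-2 indicators) and per-sample
mixture weights P (N × K, each row on the probability simplex) minimising
``‖F − P·H‖²`` over observed cells. The simplex constraint is the
"frequencies sum to 1 within an individual" contract; its known cost is
that minor haplotypes carrying low-frequency variants can be absorbed
into larger ones.

Fitting alternates two exact conditional steps from multiple starts:

* P-step — per sample, least squares on the simplex, solved exactly by
  enumerating support sets and solving the KKT system of each (vectorised
  across samples when no cells are missing);
* H-step — per SNP column, exhaustive choice among the 2^K binary columns.

K is capped at floor(log2 S): with S informative biallelic sites one
cannot hope to resolve more than log2(S) mixture components reliably.
Also here: expected heterozygosity He = 1 − Σ p_i², Hamming distances
between haplotypes, and a minimum-spanning network (union of all minimum
spanning trees) standing in for a statistical-parsimony network — at the
K ≤ 5 scale typical here the two are topology-equivalent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import ols

logger = logging.getLogger(__name__)


def haplotype_cap(n_snps: int) -> int:
    """Maximum resolvable haplotype count: floor(log2 of the SNP count)."""
    if n_snps < 2:
        raise ValueError("need >= 2 SNP sites")
    return int(np.floor(np.log2(n_snps)))


def capped_haplotype_count(anticipated: int, n_snps: int) -> int:
    """The smaller of the anticipated haplotype count and the log2-of-SNPs cap."""
    if anticipated < 1:
        raise ValueError("anticipated haplotype count must be >= 1")
    return min(anticipated, haplotype_cap(n_snps))


@dataclass
class HaplotypeModel:
    """Fitted binary haplotypes and simplex sample frequencies."""

    H: np.ndarray           # K x S binary
    P: np.ndarray           # N x K, rows on the simplex
    sse: float              # Frobenius residual of F - P @ H over observed cells
    K: int
    converged: bool = True
    n_iter: int = 0
    rank_deficient: bool = False

    def frequencies_frame(self, sample_ids: Sequence[str] | None = None
                          ) -> pd.DataFrame:
        n = self.P.shape[0]
        ids = list(sample_ids) if sample_ids is not None else [
            f"sample{i + 1}" for i in range(n)]
        df = pd.DataFrame(self.P, columns=[f"hap{k + 1}" for k in range(self.K)])
        df.insert(0, "sample_id", ids)
        df["He"] = [expected_heterozygosity(p) for p in self.P]
        return df


def _supports(K: int) -> list[np.ndarray]:
    """All non-empty support subsets of {0..K-1}, singletons first."""
    subsets = []
    for bits in range(1, 2**K):
        idx = np.flatnonzero([(bits >> k) & 1 for k in range(K)])
        subsets.append(idx)
    subsets.sort(key=len)
    return subsets


def _kkt_factor(A: np.ndarray) -> np.ndarray | None:
    """Inverse of the simplex-LS KKT matrix for design A (S x k), or None
    if singular (duplicate haplotype rows during iteration)."""
    k = A.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * (A.T @ A)
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    try:
        return np.linalg.inv(kkt)
    except np.linalg.LinAlgError:
        return None


def simplex_lstsq(A: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact ``argmin_p ‖f − A p‖²`` s.t. p ≥ 0, Σp = 1, by support
    enumeration (A is S × K with K small)."""
    K = A.shape[1]
    best_p, best_sse = None, np.inf
    for idx in _supports(K):
        M = _kkt_factor(A[:, idx])
        if M is None:
            continue
        rhs = np.concatenate([2.0 * (A[:, idx].T @ f), [1.0]])
        sol = M @ rhs
        p_sub = sol[:-1]
        if (p_sub < -1e-10).any():
            continue
        resid = f - A[:, idx] @ p_sub
        sse = float(resid @ resid)
        if sse < best_sse - 1e-15:
            best_sse = sse
            p = np.zeros(K)
            p[idx] = np.clip(p_sub, 0.0, None)
            best_p = p / p.sum()
    assert best_p is not None  # singleton supports are always feasible
    return best_p


def _p_step(F: np.ndarray, H: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Simplex least squares for every sample given H."""
    N, S = F.shape
    K = H.shape[0]
    A_full = H.T.astype(float)  # S x K
    P = np.empty((N, K))
    complete = observed.all(axis=1)
    if complete.any():
        # shared designs: precompute one KKT inverse per support
        Fc = F[complete]
        best_sse = np.full(Fc.shape[0], np.inf)
        best_P = np.zeros((Fc.shape[0], K))
        for idx in _supports(K):
            M = _kkt_factor(A_full[:, idx])
            if M is None:
                continue
            rhs = np.concatenate(
                [2.0 * (A_full[:, idx].T @ Fc.T), np.ones((1, Fc.shape[0]))])
            sol = M @ rhs            # (k+1) x n
            p_sub = sol[:-1].T       # n x k
            feasible = (p_sub >= -1e-10).all(axis=1)
            if not feasible.any():
                continue
            resid = Fc - p_sub @ A_full[:, idx].T
            sse = (resid**2).sum(axis=1)
            better = feasible & (sse < best_sse - 1e-15)
            if better.any():
                best_sse[better] = sse[better]
                full = np.zeros((int(better.sum()), K))
                full[:, idx] = np.clip(p_sub[better], 0.0, None)
                best_P[better] = full / full.sum(axis=1, keepdims=True)
        P[complete] = best_P
    for i in np.flatnonzero(~complete):
        obs = observed[i]
        if not obs.any():
            P[i] = np.full(K, 1.0 / K)
            continue
        P[i] = simplex_lstsq(A_full[obs], F[i, obs])
    return P


def _h_step(F: np.ndarray, P: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Per-column exhaustive binary choice given P."""
    K = P.shape[1]
    candidates = np.array(list(product((0, 1), repeat=K)), dtype=np.int8)  # 2^K x K
    R = P @ candidates.T  # N x 2^K predicted frequencies per candidate
    W = observed.astype(float)
    # weighted SSE of column s under candidate c, dropping the constant
    # sum-of-F² term (argmin unchanged)
    errors = np.einsum("ns,nc->sc", W, R**2) - 2.0 * ((F * W).T @ R)
    choice = errors.argmin(axis=1)
    return candidates[choice].T.copy()  # K x S


def _sse(F: np.ndarray, P: np.ndarray, H: np.ndarray,
         observed: np.ndarray) -> float:
    resid = (F - P @ H) * observed
    return float((resid**2).sum())


def _canonicalize(H: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order haplotypes by decreasing mean frequency, lexicographic H rows
    breaking ties, so reported labels are deterministic."""
    means = P.mean(axis=0)
    order = sorted(range(H.shape[0]),
                   key=lambda k: (-means[k], tuple(H[k])))
    return H[order], P[:, order]


def _init_P(F: np.ndarray, K: int, restart: int, rng: np.random.Generator
            ) -> np.ndarray:
    N = F.shape[0]
    if restart == 0 and N >= K:
        from scipy.cluster.vq import kmeans2

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Ffill = np.nan_to_num(F, nan=0.5)
            _, labels = kmeans2(Ffill, K, minit="++",
                                seed=int(rng.integers(2**31)))
        P = np.full((N, K), 0.2 / K)
        P[np.arange(N), labels] += 0.8
        return P / P.sum(axis=1, keepdims=True)
    return rng.dirichlet(np.ones(K), size=N)


def deconvolve(F: np.ndarray | pd.DataFrame, K: int, n_restarts: int = 20,
               seed: int = 0, max_iter: int = 500, tol: float = 1e-8
               ) -> HaplotypeModel:
    """Fit the K-haplotype mixture model to an allele-frequency matrix.

    ``F`` may contain NaN for missing cells; those are masked out of the
    objective, never imputed. The best of ``n_restarts`` alternating fits
    is returned with haplotypes in canonical order. A model whose fitted
    P matrix is column-rank deficient (indistinguishable mixtures, e.g.
    compositions constant across samples) is flagged ``rank_deficient``.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("F must be 2-D (samples x sites)")
    N, S = F.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if S < 63 and K > 2**S:
        raise ValueError(f"{K} distinct binary rows over {S} sites are impossible")
    observed = ~np.isnan(F)
    Fz = np.where(observed, F, 0.0)
    obs_vals = Fz[observed]
    if obs_vals.size and np.ptp(obs_vals) < 1e-12:
        warnings.warn("allele-frequency matrix is constant; returning a "
                      "single-haplotype model", stacklevel=2)
        H = np.full((1, S), int(round(float(obs_vals[0]))), dtype=np.int8)
        P = np.ones((N, 1))
        return HaplotypeModel(H=H, P=P, sse=_sse(Fz, P, H, observed), K=1,
                              rank_deficient=False)
    rng = np.random.default_rng(seed)
    best: HaplotypeModel | None = None
    for restart in range(n_restarts):
        P = _init_P(Fz, K, restart, rng)
        H = _h_step(Fz, P, observed)
        sse_prev = _sse(Fz, P, H, observed)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            P = _p_step(Fz, H, observed)
            H = _h_step(Fz, P, observed)
            sse = _sse(Fz, P, H, observed)
            if sse_prev - sse <= tol * max(sse_prev, 1e-300):
                converged = True
                break
            sse_prev = sse
        sse = _sse(Fz, P, H, observed)
        if best is None or sse < best.sse - 1e-12:
            best = HaplotypeModel(H=H.copy(), P=P.copy(), sse=sse, K=K,
                                  converged=converged, n_iter=n_iter)
    assert best is not None
    # drop duplicate haplotype rows (merge their frequencies) to honour the
    # pairwise-distinct invariant; duplicates arise when K over-fits
    uniq, inverse = np.unique(best.H, axis=0, return_inverse=True)
    if uniq.shape[0] < best.K:
        P_merged = np.zeros((N, uniq.shape[0]))
        for k in range(best.K):
            P_merged[:, inverse[k]] += best.P[:, k]
        best = HaplotypeModel(H=uniq.astype(np.int8), P=P_merged, sse=best.sse,
                              K=uniq.shape[0], converged=best.converged,
                              n_iter=best.n_iter)
    H, P = _canonicalize(best.H.astype(np.int8), best.P)
    rank = np.linalg.matrix_rank(P, tol=1e-6)
    rank_deficient = rank < best.K
    if rank_deficient:
        warnings.warn("fitted sample-frequency matrix is rank deficient; "
                      "haplotype recovery is not unique", stacklevel=2)
    return HaplotypeModel(H=H, P=P, sse=best.sse, K=best.K,
                          converged=best.converged, n_iter=best.n_iter,
                          rank_deficient=rank_deficient)


def select_k(F: np.ndarray | pd.DataFrame, tol: float = 0.05,
             n_restarts: int = 5, seed: int = 0) -> int:
    """Choose the haplotype count by an SSE elbow, capped at floor(log2 S).

    Models are fitted for k = 1..cap; the candidate is k−1 for the first
    k whose relative SSE improvement over k−1 drops below ``tol`` (the
    extra haplotype no longer pays for itself), or the cap if every step
    keeps improving.
    """
    F = np.asarray(F, dtype=float)
    N, S = F.shape
    if S < 2 or N < 2:
        raise ValueError("need >= 2 samples and >= 2 sites")
    cap = haplotype_cap(S)
    sse_prev = None
    candidate = cap
    for k in range(1, cap + 1):
        model = deconvolve(F, k, n_restarts=n_restarts,
                           seed=seed + k)
        if sse_prev is not None:
            improvement = (sse_prev - model.sse) / max(sse_prev, 1e-300)
            if improvement < tol:
                candidate = k - 1
                break
        if model.sse <= 1e-12:
            candidate = k
            break
        sse_prev = model.sse
    return min(candidate, cap)


def expected_heterozygosity(p: Sequence[float]) -> float:
    """He = 1 − Σ p_i² over within-sample haplotype frequencies."""
    p = np.asarray(p, dtype=float)
    if p.size < 1 or (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must lie on the probability simplex")
    return float(1.0 - (p**2).sum())


def he_cn_regression(he_values: Sequence[float],
                     diploid_cn: Sequence[float]) -> dict:
    """OLS of expected heterozygosity on diploid copy number.

    A positive slope indicates that copy-number gains preferentially
    expand minor haplotypes (diversifying the pool); a flat line means
    gains are haplotype-blind.
    """
    return ols(diploid_cn, he_values)


def pairwise_differences(H: np.ndarray) -> tuple[np.ndarray, dict]:
    """Hamming distances between haplotype rows, with off-diagonal stats."""
    H = np.asarray(H)
    K = H.shape[0]
    if K < 2:
        raise ValueError("need >= 2 haplotypes")
    D = (H[:, None, :] != H[None, :, :]).sum(axis=2).astype(int)
    off = D[np.triu_indices(K, k=1)]
    return D, {"min": int(off.min()), "max": int(off.max()),
               "mean": float(off.mean())}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def build_network(D: np.ndarray) -> list[tuple[int, int, int]]:
    """Minimum-spanning network: the union of all minimum spanning trees.

    Group-wise Kruskal: edges are processed in weight order; within each
    weight class, every edge joining two still-separate components is
    retained (so equal-weight alternatives all survive), then the whole
    class is merged. Edge weights are nucleotide differences.
    """
    D = np.asarray(D)
    K = D.shape[0]
    if D.shape != (K, K) or (D != D.T).any() or np.diag(D).any():
        raise ValueError("D must be symmetric with zero diagonal")
    edges = [(int(D[i, j]), i, j) for i in range(K) for j in range(i + 1, K)]
    edges.sort()
    uf = _UnionFind(K)
    kept: list[tuple[int, int, int]] = []
    i = 0
    while i < len(edges):
        w = edges[i][0]
        group = []
        while i < len(edges) and edges[i][0] == w:
            group.append(edges[i])
            i += 1
        for _, u, v in group:
            if uf.find(u) != uf.find(v):
                kept.append((u, v, w))
        for _, u, v in group:
            uf.union(u, v)
    return kept


def network_frame(edges: Sequence[tuple[int, int, int]],
                  labels: Sequence[str] | None = None) -> pd.DataFrame:
    rows = []
    for u, v, w in edges:
        lu = labels[u] if labels else f"hap{u + 1}"
        lv = labels[v] if labels else f"hap{v + 1}"
        rows.append({"from": lu, "to": lv, "differences": w})
    return pd.DataFrame(rows)
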