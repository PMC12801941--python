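"""Recombination screening of single-copy gene alignments.

Three permutation tests on each alignment, analogous to the classic
PHI / max-chi-squared / neighbour-similarity trio:

* **PHI**: mean pairwise incompatibility between parsimony-informative
  sites that lie within ``window`` informative-site positions of each
  other.  Recombination makes nearby sites *more* compatible than
  distant ones, so the observed statistic is in the lower permutation
  tail.
* **Max chi^2**: the largest 2x2 chi-squared over putative breakpoints in
  the match/mismatch profiles of all sequence pairs.
* **NSS**: fraction of adjacent informative-site pairs that are
  compatible; clustering of topology signal pushes it above permuted
  values.

Site compatibility uses the four-gamete condition on binarized
(major/minor) states; gap and ambiguous characters are excluded per site
pair.  Permutations shuffle informative-site order; p-values carry the
(b+1)/(m+1) correction and are invariant to sequence-label order
(sequences are processed in sorted-id order).  A gene is called
recombinant when at least two of the three tests give p < 0.05.

Topology-based screening clusters gene trees by Robinson-Foulds (RF)
distance: a silhouette scan over hierarchical, k-means (on a classical
MDS embedding) and k-medoids partitions for k = 2..10.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .alnstats import AMBIGUOUS, GAP_CHARS, MSA

DEFAULT_PERMUTATIONS = 100_000  # reference tool default; tests use fewer
METHOD_ORDER = ("hierarchical", "kmeans", "kmedoids")


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p: float
    n_informative: int


@dataclass(frozen=True)
class RecombTestResult:
    gene_id: str
    phi_p: Optional[float]
    maxchi_p: Optional[float]
    nss_p: Optional[float]
    n_informative_sites: int
    consensus_call: Optional[bool]  # None = untestable


# --- informative sites and compatibility ---------------------------------

def _informative_matrix(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    """Binarized informative columns.

    Returns (B, M): K x n boolean arrays over informative columns, B true
    where the sequence carries the column's major state, M true where the
    character is a valid (unambiguous, non-gap) state.
    """
    ids = sorted(msa.sequences)
    rows = [msa.sequences[i].upper() for i in ids]
    n = len(rows)
    B_cols, M_cols = [], []
    for i in range(msa.n_columns):
        col = [r[i] for r in rows]
        counts: dict[str, int] = {}
        for c in col:
            if c in GAP_CHARS or c in AMBIGUOUS:
                continue
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) < 2:
            continue
        major = max(sorted(counts), key=lambda s: counts[s])
        B_cols.append([c == major for c in col])
        M_cols.append([c not in GAP_CHARS and c not in AMBIGUOUS
                       for c in col])
    if not B_cols:
        return (np.zeros((0, n), dtype=bool), np.zeros((0, n), dtype=bool))
    return np.array(B_cols), np.array(M_cols)


def _incompatibility(B: np.ndarray, M: np.ndarray) -> np.ndarray:
    """K x K boolean: four-gamete incompatibility between site pairs."""
    A = (B & M).astype(np.float32)
    notA = (~B & M).astype(np.float32)
    c11 = A @ A.T
    c10 = A @ notA.T
    c01 = notA @ A.T
    c00 = notA @ notA.T
    return (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)


def _perm_p(count_extreme: int, m: int) -> float:
    return (count_extreme + 1) / (m + 1)


# --- the three tests -----------------------------------------------------

def phi_statistic(msa: MSA, window: int = 50,
                  n_permutations: int = DEFAULT_PERMUTATIONS,
                  seed: int = 0) -> Optional[PermTestResult]:
    """Windowed mean pairwise incompatibility with a permutation p-value.

    The p-value is the fraction of site-order shuffles whose statistic is
    less than or equal to the observed one (low observed incompatibility
    among nearby sites indicates recombination).  Returns ``None``
    (no-test) with fewer than 2 informative sites.
    """
    B, M = _informative_matrix(msa)
    K = B.shape[0]
    if K < 2:
        return None
    inc = _incompatibility(B, M).astype(np.float64)
    ii, jj = np.triu_indices(K, k=1)
    sel = (jj - ii) <= window
    ii, jj = ii[sel], jj[sel]
    obs = float(inc[ii, jj].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        pi = rng.permutation(K)
        if inc[pi[ii], pi[jj]].mean() <= obs:
            count += 1
    return PermTestResult(obs, _perm_p(count, n_permutations), K)


def _mismatch_profiles(msa: MSA) -> Optional[np.ndarray]:
    """0/1 mismatch profiles over informative columns, one row per
    sequence pair.  Sites with a gap/ambiguity in either sequence count
    as matches (no breakpoint signal)."""
    B, M = _informative_matrix(msa)
    if B.shape[0] < 2:
        return None
    n = B.shape[1]
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            valid = M[:, a] & M[:, b]
            rows.append(((B[:, a] != B[:, b]) & valid).astype(np.int64))
    return np.array(rows)  # pairs x K


def _max_chi2_stat(mism: np.ndarray) -> float:
    """Largest 2x2 chi-squared over breakpoints and sequence pairs."""
    P, K = mism.shape
    cums = np.cumsum(mism, axis=1)[:, :-1]       # mismatches left of bp
    total = mism.sum(axis=1, keepdims=True)
    k = np.arange(1, K)[None, :]
    x = cums
    y = total - cums
    n2 = K - k
    # chi2 of [[k-x, x], [n2-y, y]]
    colm = (k - x) + (n2 - y)
    colx = x + y
    denom = k * n2 * colm * colx
    num = K * ((k - x) * y - x * (n2 - y)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, num / denom, 0.0)
    return float(chi.max())


def max_chi2(msa: MSA, n_permutations: int = DEFAULT_PERMUTATIONS,
             seed: int = 0) -> Optional[PermTestResult]:
    """Maximum breakpoint chi-squared over all sequence pairs.

    For every sequence pair the mismatch profile over informative sites
    is scanned at every breakpoint; the statistic is the largest 2x2
    chi-squared (left/right x match/mismatch) over pairs and
    breakpoints.  p = fraction of joint site-order shuffles with a
    statistic at least as large.
    """
    mism = _mismatch_profiles(msa)
    if mism is None or mism.shape[1] < 2:
        return None
    K = mism.shape[1]
    obs = _max_chi2_stat(mism)
    rng = np.random.default_rng(seed + 1)
    count = 0
    for _ in range(n_permutations):
        pi = rng.permutation(K)
        if _max_chi2_stat(mism[:, pi]) >= obs:
            count += 1
    return PermTestResult(obs, _perm_p(count, n_permutations), K)


def nss(msa: MSA, n_permutations: int = DEFAULT_PERMUTATIONS,
        seed: int = 0) -> Optional[PermTestResult]:
    """Neighbour-similarity score: compatible fraction of adjacent
    informative-site pairs; p = fraction of shuffles at least as large."""
    B, M = _informative_matrix(msa)
    K = B.shape[0]
    if K < 2:
        return None
    compat = ~_incompatibility(B, M)
    idx = np.arange(K - 1)
    obs = float(compat[idx, idx + 1].mean())
    rng = np.random.default_rng(seed + 2)
    count = 0
    for _ in range(n_permutations):
        pi = rng.permutation(K)
        if compat[pi[idx], pi[idx + 1]].mean() >= obs:
            count += 1
    return PermTestResult(obs, _perm_p(count, n_permutations), K)


def consensus_recombination_call(p_values: Sequence[Optional[float]],
                                 alpha: float = 0.05,
                                 min_significant: int = 2) -> Optional[bool]:
    """Recombinant iff at least ``min_significant`` tests have p < alpha.

    Returns ``None`` (untestable) when fewer than ``min_significant``
    tests produced a p-value.
    """
    ran = [p for p in p_values if p is not None]
    if len(ran) < min_significant:
        return None
    return sum(1 for p in ran if p < alpha) >= min_significant


def screen_gene(gene_id: str, msa: MSA, window: int = 50,
                n_permutations: int = DEFAULT_PERMUTATIONS,
                seed: int = 0) -> RecombTestResult:
    """Run all three tests plus the consensus rule on one alignment."""
    phi = phi_statistic(msa, window, n_permutations, seed)
    mx = max_chi2(msa, n_permutations, seed)
    ns = nss(msa, n_permutations, seed)
    n_inf = _informative_matrix(msa)[0].shape[0]
    ps = [r.p if r else None for r in (phi, mx, ns)]
    return RecombTestResult(gene_id, ps[0], ps[1], ps[2], n_inf,
                            consensus_recombination_call(ps))


# --- Robinson-Foulds and topology clustering -----------------------------

def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted RF distance: size of the symmetric difference of the
    non-trivial bipartition sets.  Leaf sets must match."""
    la = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    if la != lb:
        raise ValueError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=tree_a.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=tree_b.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    ta.is_rooted = False
    tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def rf_matrix(trees: Sequence[dendropy.Tree]) -> np.ndarray:
    n = len(trees)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rf_distance(trees[i], trees[j])
    return mat


def _classical_mds(dist: np.ndarray, n_dims: int) -> np.ndarray:
    d2 = dist.astype(float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(n_dims, int((vals > 1e-9).sum()))
    keep = max(keep, 1)
    return vecs[:, :keep] * np.sqrt(np.clip(vals[:keep], 0, None))


def _pam_kmedoids(dist: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PAM: greedy BUILD then SWAP to convergence."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_cand = -np.inf, None
        cur = dist[:, medoids].min(axis=1)
        for cand in range(n):
            if cand in medoids:
                continue
            gain = np.maximum(cur - dist[:, cand], 0).sum()
            if gain > best_gain:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)
    improved = True
    while improved:
        improved = False
        cost = dist[:, medoids].min(axis=1).sum()
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                tc = dist[:, trial].min(axis=1).sum()
                if tc < cost - 1e-12:
                    medoids, cost, improved = trial, tc, True
    return np.argmin(dist[:, medoids], axis=1)


@dataclass
class TopologyClusterScan:
    rf: np.ndarray
    silhouette: pd.DataFrame        # columns: method, k, silhouette
    best: Optional[tuple[str, int, float]]
    degenerate: bool


def topology_cluster_scan(trees: Sequence[dendropy.Tree], k_min: int = 2,
                          k_max: int = 10, seed: int = 0
                          ) -> TopologyClusterScan:
    """Silhouette scan of RF-distance clusterings over k = k_min..k_max.

    k-means runs on a classical MDS embedding (up to min(10, n-1)
    dimensions); hierarchical (average linkage) and k-medoids run on the
    distances directly.  Best = highest silhouette, ties broken by
    smaller k then method order.  An all-zero RF matrix is degenerate.
    """
    n = len(trees)
    if n < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} trees")
    mat = rf_matrix(trees)
    if not mat.any():
        return TopologyClusterScan(mat, pd.DataFrame(
            columns=["method", "k", "silhouette"]), None, True)
    dist = mat.astype(float)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    emb = _classical_mds(dist, 10)
    rows = []
    for k in range(k_min, k_max + 1):
        with warnings.catch_warnings():
            # duplicate topologies collapse to one embedding point; fewer
            # distinct centroids than k is expected, not an error
            warnings.simplefilter("ignore")
            km_labels = KMeans(n_clusters=k, n_init=10,
                               random_state=seed).fit_predict(emb)
        labellings = {
            "hierarchical": fcluster(Z, t=k, criterion="maxclust"),
            "kmeans": km_labels,
            "kmedoids": _pam_kmedoids(dist, k),
        }
        for method in METHOD_ORDER:
            labels = labellings[method]
            if len(np.unique(labels)) < 2:
                score = np.nan
            else:
                score = float(silhouette_score(dist, labels,
                                               metric="precomputed"))
            rows.append({"method": method, "k": k, "silhouette": score})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["silhouette"])
    best = None
    if not valid.empty:
        ranked = sorted(
            valid.itertuples(index=False),
            key=lambda r: (-r.silhouette, r.k, METHOD_ORDER.index(r.method)))
        top = ranked[0]
        best = (top.method, int(top.k), float(top.silhouette))
    return TopologyClusterScan(mat, table, best, False)
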