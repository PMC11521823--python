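"""Cross-omics integration at the participant level.

Participant change vectors (AT - BT per feature) from the two epigenetic
blocks are turned into affinity matrices with the scaled-exponential kernel
and fused by similarity network fusion (SNF): each view's full and
K-nearest-neighbour transition matrices are cross-diffused for t iterations,
so similarity supported by one view propagates through the other.  Spectral
clustering of the fused matrix (normalized Laplacian, eigengap-selected k)
yields latent participant subgroups.

Across omics types, sample dendrograms are compared by cophenetic
correlation, and PTM-protein co-response is summarised as a network with an
edge wherever the Pearson correlation of the two features' change vectors
exceeds 0.7 in absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .datamodel import OmicsBlock, PairedDesign, ValidationError, logger


@dataclass
class Affinity:
    """Symmetric nonnegative participant x participant similarity matrix."""

    matrix: pd.DataFrame
    K: int | None = None
    mu: float | None = None
    t: int | None = None

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1] or list(self.matrix.index) != list(self.matrix.columns):
            raise ValidationError("affinity must be square with matching labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("affinity must be symmetric")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValidationError("affinity must be nonnegative and finite")

    @property
    def ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class EdgeList:
    """PTM-protein change-correlation edges with |r| >= threshold."""

    edges: pd.DataFrame  # columns: ptm, protein, r, sign
    threshold: float = 0.7

    def to_graphml(self, path) -> None:
        import networkx as nx
        g = nx.Graph(threshold=self.threshold)
        for _, e in self.edges.iterrows():
            g.add_node(e["ptm"], kind="ptm")
            g.add_node(e["protein"], kind="protein")
            g.add_edge(e["ptm"], e["protein"], r=float(e["r"]), sign=e["sign"])
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Change matrices and affinities
# ---------------------------------------------------------------------------

def participant_change_matrix(block: OmicsBlock, design: PairedDesign,
                              sample_type: str | None = None) -> pd.DataFrame:
    """Participants x features matrix of AT - BT changes; unpaired
    participants are excluded with a log entry."""
    from .preprocess import _infer_sample_type
    stype = sample_type or _infer_sample_type(block, design)
    rows, index = [], []
    for p in design.pairs_for(stype):
        if (p.bt_sample not in block.values.columns
                or p.at_sample not in block.values.columns):
            logger.info("participant %s excluded from change matrix "
                        "(missing sample)", p.participant_id)
            continue
        rows.append(block.values[p.at_sample] - block.values[p.bt_sample])
        index.append(p.participant_id)
    for pid, tp, sid in design.unpaired.get(stype, []):
        logger.info("unpaired participant %s (%s only) excluded", pid, tp)
    return pd.DataFrame(rows, index=index)


def build_affinity(changes: pd.DataFrame, K: int = 4,
                   mu: float = 0.5) -> Affinity:
    """Scaled-exponential kernel affinity from Euclidean distances.

    W_ij = exp(-d_ij^2 / (mu * eps_ij)) with the local bandwidth
    eps_ij = (mean of i's K-NN distances + mean of j's + d_ij) / 3.
    """
    n = changes.shape[0]
    if n < 3:
        raise ValidationError("affinity needs >= 3 participants")
    if K >= n:
        raise ValidationError(f"K={K} must be < number of participants ({n})")
    d = squareform(pdist(changes.to_numpy(dtype=float)))
    sorted_d = np.sort(d, axis=1)
    knn_mean = sorted_d[:, 1:K + 1].mean(axis=1)  # exclude self (distance 0)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(d ** 2) / (mu * eps))
    W = (W + W.T) / 2.0
    return Affinity(pd.DataFrame(W, index=changes.index, columns=changes.index),
                    K=K, mu=mu)


# ---------------------------------------------------------------------------
# Similarity network fusion
# ---------------------------------------------------------------------------

def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Full transition matrix: rows sum to 1 with half the mass on the
    diagonal (keeps the diffusion well conditioned)."""
    P = W.copy().astype(float)
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic KNN kernel: mass only on each row's K nearest
    neighbours (by affinity, excluding self)."""
    n = W.shape[0]
    S = np.zeros_like(W, dtype=float)
    for i in range(n):
        w = W[i].copy()
        w[i] = -np.inf
        nn = np.argsort(w)[::-1][:K]
        vals = W[i, nn]
        tot = vals.sum()
        if tot > 0:
            S[i, nn] = vals / tot
    return S


def snf_fuse(affinities: list[Affinity], K: int | None = None,
             t: int = 20) -> Affinity:
    """Cross-diffuse two or more affinity matrices into one fused matrix.

    Each view's status matrix is repeatedly replaced by
    S_v @ mean(P_u, u != v) @ S_v', renormalized and symmetrized; after t
    iterations the views are averaged.  The diagonal of the fused matrix is
    set to the median of the whole matrix for downstream display and
    clustering.
    """
    if len(affinities) < 2:
        raise ValidationError("snf_fuse needs >= 2 affinity matrices")
    ids = affinities[0].ids
    for a in affinities[1:]:
        if a.ids != ids:
            raise ValidationError("affinities have mismatched participant ids")
    n = len(ids)
    if K is None:
        K = max(2, n // 3)
    Ws = [a.matrix.to_numpy(dtype=float) for a in affinities]
    Ps = [_full_kernel(W) for W in Ws]
    Ss = [_local_kernel(W, K) for W in Ws]
    for _ in range(t):
        new = []
        for v in range(len(Ps)):
            others = [Ps[u] for u in range(len(Ps)) if u != v]
            avg = np.mean(others, axis=0)
            Pn = Ss[v] @ avg @ Ss[v].T
            Pn = _full_kernel((Pn + Pn.T) / 2.0)
            new.append(Pn)
        Ps = new
    fused = np.mean(Ps, axis=0)
    fused = (fused + fused.T) / 2.0
    # the diffusion keeps half the mass on the diagonal, which is an
    # artifact; replace it with the median off-diagonal similarity
    med = float(np.median(fused[~np.eye(n, dtype=bool)]))
    np.fill_diagonal(fused, med)
    fused = np.maximum(fused, 0.0)
    return Affinity(pd.DataFrame(fused, index=ids, columns=ids),
                    K=K, t=t)


def spectral_cluster(fused: Affinity, k: int | str = "auto",
                     seed: int = 0) -> tuple[pd.Series, dict]:
    """Normalized-Laplacian spectral clustering of an affinity matrix.

    With ``k="auto"`` the cluster count maximizing the eigengap of the
    normalized Laplacian over [2, n/2] is used.  The final k-means step is
    seeded, so results are deterministic given the seed.  A disconnected
    affinity graph falls back to its connected components with a warning.
    """
    W = fused.matrix.to_numpy(dtype=float).copy()
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    ncomp, comp = connected_components(W > 0, directed=False)
    if ncomp > 1:
        logger.warning("affinity graph disconnected: %d components", ncomp)
        labels = pd.Series(comp, index=fused.ids, name="cluster")
        return labels, {"k": ncomp, "disconnected": True}
    deg = W.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(n) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(L)
    kmax = max(2, n // 2)
    gaps = {kk: float(evals[kk] - evals[kk - 1]) for kk in range(2, kmax + 1)}
    if k == "auto":
        k_use = max(gaps, key=gaps.get)
    else:
        k_use = int(k)
        if k_use < 2:
            raise ValidationError("k must be >= 2")
        if k_use > n:
            raise ValidationError(f"k={k_use} exceeds {n} participants")
    U = evecs[:, :k_use]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k_use, n_init=20, random_state=seed).fit(U)
    labels = pd.Series(km.labels_, index=fused.ids, name="cluster")
    return labels, {"k": k_use, "eigenvalues": evals.tolist(),
                    "eigengaps": gaps, "disconnected": False}


# ---------------------------------------------------------------------------
# Change-correlation network
# ---------------------------------------------------------------------------

def change_correlation_network(ptm_changes: pd.DataFrame,
                               protein_changes: pd.DataFrame,
                               threshold: float = 0.7) -> EdgeList:
    """Pearson correlation of every (PTM change, protein change) pair over
    the shared participants; edges wherever |r| >= threshold."""
    shared = ptm_changes.index.intersection(protein_changes.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared participants for correlations")
    A = ptm_changes.loc[shared]
    B = protein_changes.loc[shared]

    def _drop_constant(df: pd.DataFrame, label: str) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=1)
        const = list(df.columns[(sd == 0) | sd.isna()])
        if const:
            logger.warning("%s: excluding zero-variance columns %s", label, const)
        return df.drop(columns=const)

    A = _drop_constant(A, "ptm_changes")
    B = _drop_constant(B, "protein_changes")
    Az = (A - A.mean()) / A.std(ddof=1)
    Bz = (B - B.mean()) / B.std(ddof=1)
    R = Az.T @ Bz / (len(shared) - 1)
    rows = []
    for ptm in R.index:
        for prot in R.columns:
            r = float(R.loc[ptm, prot])
            if abs(r) >= threshold:
                rows.append({"ptm": ptm, "protein": prot, "r": r,
                             "sign": "+" if r >= 0 else "-"})
    edges = pd.DataFrame(rows, columns=["ptm", "protein", "r", "sign"])
    return EdgeList(edges=edges, threshold=threshold)


def high_degree_nodes(edges: EdgeList, min_degree: int = 1) -> list[str]:
    """PTM nodes with degree >= min_degree, sorted by degree then id."""
    if edges.edges.empty:
        return []
    deg = edges.edges.groupby("ptm").size().rename("degree").reset_index()
    keep = deg[deg["degree"] >= min_degree]
    keep = keep.sort_values(["degree", "ptm"], ascending=[False, True])
    return list(keep["ptm"])


# ---------------------------------------------------------------------------
# Dendrogram comparison
# ---------------------------------------------------------------------------

def cophenetic_compare(matrix_a: pd.DataFrame,
                       matrix_b: pd.DataFrame) -> float:
    """Cophenetic correlation between the average-linkage dendrograms of two
    samples x features matrices sharing the same samples."""
    if list(matrix_a.index) != list(matrix_b.index):
        shared = matrix_a.index.intersection(matrix_b.index)
        if len(shared) < 3:
            raise ValidationError("matrices share fewer than 3 samples")
        matrix_a, matrix_b = matrix_a.loc[shared], matrix_b.loc[shared]
    if matrix_a.shape[0] < 3:
        raise ValidationError("cophenetic comparison needs >= 3 samples")
    ca = cophenet(linkage(matrix_a.to_numpy(dtype=float), method="average"))
    cb = cophenet(linkage(matrix_b.to_numpy(dtype=float), method="average"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(ca, cb)[0, 1]
    return float(r)
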