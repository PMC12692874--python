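"""Logit-embedding analysis.

Each sentence's position-averaged logit vector is one row of a logit matrix
(N sentences x V vocabulary tokens).  The analysis pipeline mirrors standard
single-cell practice: keep the highest-standard-deviation token columns,
reduce by PCA, embed with UMAP, cluster Louvain-style on a k-nearest-neighbor
graph built in PC space, then characterize clusters by one-vs-rest rank-sum
markers (BH-adjusted within cluster), hierarchical grouping of cluster mean
vectors, and hypergeometric term enrichment.  New samples are projected by
joint re-embedding with the reference matrix.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import false_discovery_control, hypergeom, ranksums
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .corpus import encode_sample
from .model import ModelState, sequence_logits

logger = logging.getLogger("bindtext")

DEFAULT_N_NEIGHBORS = 15
DEFAULT_RESOLUTION = 1.0
DEFAULT_N_COMPONENTS = 100
DEFAULT_MAX_TERM_CLUSTERS = 10   # enrichment terms seen in more clusters are dropped


def default_n_keep(n_columns: int) -> int:
    """Default count of high-variance token columns retained."""
    return min(750, max(1, n_columns - 3))


@dataclass
class LogitMatrix:
    """N x V matrix of per-sentence average logits with row/column metadata."""

    values: np.ndarray
    row_meta: pd.DataFrame          # columns: target, ligand_id, pose_id
    tokens: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("logit matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("logit matrix contains non-finite entries")
        if self.values.shape[1] != len(self.tokens):
            raise ValueError("column metadata does not match matrix width")
        if len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row metadata does not match matrix height")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset_columns(self, col_idx: np.ndarray) -> "LogitMatrix":
        return LogitMatrix(values=self.values[:, col_idx],
                           row_meta=self.row_meta.reset_index(drop=True),
                           tokens=[self.tokens[i] for i in col_idx])

    def save(self, prefix: str) -> None:
        np.savetxt(f"{prefix}.matrix.tsv", self.values, delimiter="\t")
        self.row_meta.to_csv(f"{prefix}.rows.tsv", sep="\t", index=False)
        pd.DataFrame({"token": self.tokens}).to_csv(f"{prefix}.cols.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str) -> "LogitMatrix":
        values = np.loadtxt(f"{prefix}.matrix.tsv", delimiter="\t", ndmin=2)
        rows = pd.read_csv(f"{prefix}.rows.tsv", sep="\t").fillna("")
        cols = pd.read_csv(f"{prefix}.cols.tsv", sep="\t")
        return cls(values=values, row_meta=rows, tokens=list(cols["token"]))


@dataclass
class ClusterModel:
    coords2d: np.ndarray                  # N x 2 embedding
    labels: np.ndarray                    # N cluster ids
    centroids: dict[int, np.ndarray]      # cluster -> 2-D mean
    selected_token_idx: np.ndarray        # columns retained before PCA
    pca: PCA                              # fitted projection
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords2d.shape[0] != self.labels.shape[0]:
            raise ValueError("labels must cover all embedded rows")
        if set(self.centroids) != set(np.unique(self.labels).tolist()):
            raise ValueError("centroid count must equal distinct label count")


# ---------------------------------------------------------------------------
# matrix construction and reduction
# ---------------------------------------------------------------------------

def build_logit_matrix(model: ModelState, sentences, vocab,
                       max_seq_len: int | None = None) -> LogitMatrix:
    """Row i = average-logit vector of sentence i.  Sentences that fail to
    encode are skipped with a log entry."""
    max_seq_len = max_seq_len or model.config.max_seq_len
    rows, meta = [], []
    for s in sentences:
        try:
            sample = encode_sample(s, vocab, max_seq_len)
            rows.append(sequence_logits(model, sample))
        except ValueError as exc:
            logger.warning("sentence skipped in logit matrix: %s", exc)
            continue
        meta.append({"target": s.target, "ligand_id": s.ligand_id, "pose_id": s.pose_id})
    if not rows:
        raise ValueError("no sentence could be encoded")
    tokens = [vocab.token_of(i) if hasattr(vocab, "token_of") else vocab.vocab.token_of(i)
              for i in range(len(getattr(vocab, "vocab", vocab)))]
    return LogitMatrix(values=np.stack(rows), row_meta=pd.DataFrame(meta), tokens=tokens)


def select_high_variance_tokens(matrix: LogitMatrix, n_keep: int | None = None,
                                return_index: bool = False):
    """Keep the ``n_keep`` columns with the largest standard deviation across
    rows (ties break toward the lower column index); column order preserved."""
    if n_keep is None:
        n_keep = default_n_keep(len(matrix.tokens))
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    n_keep = min(n_keep, matrix.values.shape[1])
    sd = matrix.values.std(axis=0)
    order = np.lexsort((np.arange(sd.size), -sd))[:n_keep]
    keep = np.sort(order)
    sub = matrix.subset_columns(keep)
    return (sub, keep) if return_index else sub


def reduce_pca(matrix: LogitMatrix | np.ndarray,
               n_components: int = DEFAULT_N_COMPONENTS,
               return_model: bool = False):
    """Column-centered PCA scores with deterministic sign (the largest-
    magnitude loading of each component is made positive)."""
    X = matrix.values if isinstance(matrix, LogitMatrix) else np.asarray(matrix, float)
    max_comp = min(X.shape)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(N, columns)={max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.ones(n_components)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            flip[j] = -1.0
    scores = scores * flip
    pca.components_ = pca.components_ * flip[:, None]
    return (scores, pca) if return_model else scores


# ---------------------------------------------------------------------------
# embedding + community detection
# ---------------------------------------------------------------------------

def _knn_graph(scores: np.ndarray, n_neighbors: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = {tuple(sorted((i, int(j)))) for i, row in enumerate(idx) for j in row[1:]}
    return igraph.Graph(n=scores.shape[0], edges=sorted(edges))


def embed_and_cluster(scores: np.ndarray, n_neighbors: int = DEFAULT_N_NEIGHBORS,
                      resolution: float = DEFAULT_RESOLUTION, seed: int = 0,
                      selected_token_idx: np.ndarray | None = None,
                      pca: PCA | None = None) -> ClusterModel:
    """UMAP 2-D embedding of the PCA scores plus Louvain-style community
    labels from a k-nearest-neighbor graph built in PC space.  Deterministic
    for a fixed seed."""
    import umap

    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 rows")

    if np.allclose(scores, scores[0]):
        warnings.warn("all rows identical: single trivial cluster")
        labels = np.zeros(n, dtype=int)
        coords = np.zeros((n, 2))
    else:
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed, n_jobs=1)
        coords = np.asarray(reducer.fit_transform(scores), dtype=np.float64)
        graph = _knn_graph(scores, n_neighbors)
        random.seed(seed)            # python-igraph draws from Python's RNG
        communities = graph.community_multilevel(resolution=resolution)
        labels = np.asarray(communities.membership, dtype=int)

    centroids = {int(c): coords[labels == c].mean(axis=0) for c in np.unique(labels)}
    return ClusterModel(coords2d=coords, labels=labels, centroids=centroids,
                        selected_token_idx=(selected_token_idx
                                            if selected_token_idx is not None
                                            else np.arange(0)),
                        pca=pca if pca is not None else PCA(),
                        params={"n_neighbors": n_neighbors, "resolution": resolution,
                                "seed": seed})


def cluster_pipeline(matrix: LogitMatrix, n_keep: int | None = None,
                     n_components: int | None = None,
                     n_neighbors: int = DEFAULT_N_NEIGHBORS,
                     resolution: float = DEFAULT_RESOLUTION,
                     seed: int = 0) -> tuple[ClusterModel, LogitMatrix]:
    """Convenience wrapper: variance selection -> PCA -> embed/cluster."""
    selected, keep = select_high_variance_tokens(matrix, n_keep, return_index=True)
    n_comp = n_components or min(DEFAULT_N_COMPONENTS, selected.n - 1,
                                 selected.values.shape[1])
    scores, pca = reduce_pca(selected, n_components=n_comp, return_model=True)
    cm = embed_and_cluster(scores, n_neighbors=n_neighbors, resolution=resolution,
                           seed=seed, selected_token_idx=keep, pca=pca)
    return cm, selected


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def cluster_markers(matrix: LogitMatrix, labels: np.ndarray) -> pd.DataFrame:
    """One-vs-rest rank-sum test per token per cluster; Benjamini-Hochberg
    adjustment across tokens within each cluster; rows sorted by q (ascending)
    within cluster.  Singleton clusters are skipped with a log entry."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("marker testing needs at least two clusters")
    X = matrix.values
    frames = []
    for c in clusters:
        in_c = labels == c
        if in_c.sum() < 2 or (~in_c).sum() < 2:
            logger.warning("cluster %s too small for marker tests; skipped", c)
            continue
        stat, p = ranksums(X[in_c], X[~in_c], axis=0)
        direction = np.sign(X[in_c].mean(axis=0) - X[~in_c].mean(axis=0)).astype(int)
        q = false_discovery_control(p, method="bh")
        df = pd.DataFrame({
            "cluster": c, "token_id": np.arange(X.shape[1]),
            "token": matrix.tokens, "direction": direction, "p": p, "q": q,
        }).sort_values(["q", "p", "token_id"], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# hierarchical grouping of clusters
# ---------------------------------------------------------------------------

def group_clusters_hierarchically(matrix: LogitMatrix, labels: np.ndarray,
                                  n_groups: int) -> tuple[dict[int, int], list[int]]:
    """Average-linkage hierarchy (Euclidean) over per-cluster mean vectors,
    cut into ``n_groups``.  Returns (cluster -> group map, dendrogram leaf
    order of the clusters)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if n_groups > clusters.size:
        raise ValueError("n_groups exceeds the number of clusters")
    means = np.stack([matrix.values[labels == c].mean(axis=0) for c in clusters])
    if clusters.size == 1:
        return {int(clusters[0]): 1}, [int(clusters[0])]
    Z = linkage(means, method="average", metric="euclidean")
    cut = fcluster(Z, t=n_groups, criterion="maxclust")
    order = [int(clusters[i]) for i in leaves_list(Z)]
    return {int(c): int(g) for c, g in zip(clusters, cut)}, order


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich_terms(cluster_genes, annotation: dict[str, set], background: set,
                 n_clusters_with_term: dict[str, int] | None = None,
                 max_term_clusters: int = DEFAULT_MAX_TERM_CLUSTERS) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a cluster's
    gene set, BH-adjusted; terms observed in more than ``max_term_clusters``
    clusters are filtered out before ranking.  The lowest-q surviving term
    (first row) represents the cluster."""
    if not annotation or not background:
        raise ValueError("annotation and background must be non-empty")
    genes = set(cluster_genes) & set(background)
    if not genes:
        raise ValueError("no cluster gene overlaps the background universe")
    M, n_draw = len(background), len(genes)
    records = []
    for term, term_genes in annotation.items():
        if n_clusters_with_term and n_clusters_with_term.get(term, 0) > max_term_clusters:
            continue
        K = len(set(term_genes) & set(background))
        if K == 0:
            continue
        k = len(genes & set(term_genes))
        p = float(hypergeom.sf(k - 1, M, K, n_draw))
        records.append({"term": term, "overlap": k, "term_size": K, "p": p})
    if not records:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    df = pd.DataFrame(records)
    df["q"] = false_discovery_control(df["p"].to_numpy(), method="bh")
    return df.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# projection of new samples
# ---------------------------------------------------------------------------

def project_new_sample(new_logits: np.ndarray, reference: LogitMatrix,
                       cluster_model: ClusterModel, seed: int | None = None
                       ) -> tuple[np.ndarray, int, ClusterModel]:
    """Joint re-embedding of the reference matrix plus one new vector.

    The selection/PCA/UMAP/Louvain pipeline is re-run on the combined data
    with the reference run's parameters and seed; the new row's coordinate
    and the reference-label centroid nearest to it (in the new embedding) are
    returned, together with the joint cluster model."""
    new_logits = np.asarray(new_logits, dtype=np.float64).ravel()
    if new_logits.size != len(reference.tokens):
        raise ValueError("new vector length does not match reference vocabulary")
    params = cluster_model.params
    seed = params.get("seed", 0) if seed is None else seed
    combined = LogitMatrix(
        values=np.vstack([reference.values, new_logits[None, :]]),
        row_meta=pd.concat([reference.row_meta,
                            pd.DataFrame([{"target": "?", "ligand_id": "?", "pose_id": "new"}])],
                           ignore_index=True),
        tokens=list(reference.tokens))
    n_keep = (cluster_model.selected_token_idx.size
              if cluster_model.selected_token_idx.size else None)
    n_comp = getattr(cluster_model.pca, "n_components_", None)
    cm, _ = cluster_pipeline(combined, n_keep=n_keep, n_components=n_comp,
                             n_neighbors=params.get("n_neighbors", DEFAULT_N_NEIGHBORS),
                             resolution=params.get("resolution", DEFAULT_RESOLUTION),
                             seed=seed)
    new_coord = cm.coords2d[-1]
    # centroids of the *reference* labels at their re-embedded coordinates
    ref_coords = cm.coords2d[:-1]
    centroids = {int(c): ref_coords[cluster_model.labels == c].mean(axis=0)
                 for c in np.unique(cluster_model.labels)}
    assigned = min(centroids, key=lambda c: (float(np.linalg.norm(new_coord - centroids[c])), c))
    return new_coord, int(assigned), cm


def radar_weights(new_coord: np.ndarray, group_centroids: dict) -> dict:
    """Min-max-inverted centroid distances: the nearest group gets weight 1,
    the farthest 0."""
    if len(group_centroids) < 2:
        raise ValueError("radar weights need at least two groups")
    new_coord = np.asarray(new_coord, dtype=float)
    d = {g: float(np.linalg.norm(new_coord - np.asarray(c, float)))
         for g, c in group_centroids.items()}
    dmin, dmax = min(d.values()), max(d.values())
    if dmax == dmin:
        warnings.warn("all centroid distances equal; weights degenerate to 1")
        return {g: 1.0 for g in d}
    return {g: (dmax - dist) / (dmax - dmin) for g, dist in d.items()}
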