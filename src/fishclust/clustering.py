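"""Behavioral clustering: similarity-weighted k-NN graph + Louvain communities.

The reference workflow: standardize the four exploratory features over a
reference cohort, convert pairwise 4-D Euclidean distances D to similarity
scores S = 1/(1+D), connect each fish to its k most-similar neighbors in a
weighted undirected graph, and partition with the Louvain modularity
algorithm. k is chosen from the middle of a plateau of k values that
optimize internal clustering indices (Calinski–Harabasz, Silhouette,
Davies–Bouldin) computed on the standardized feature cloud.

New sessions are assigned to the reference communities by majority vote of
each new fish's m most-similar reference fish, where m is half the size of
the smallest reference community (the reference analysis used m = 41 with a
smallest community of 82).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .features import FEATURE_NAMES

__all__ = [
    "StandardizationParams",
    "ClusterModel",
    "standardize",
    "similarity",
    "build_knn_graph",
    "louvain_partition",
    "scan_k",
    "select_k",
    "fit",
    "assign",
    "name_clusters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and standard deviation from a reference cohort."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any() or not np.isfinite(self.sd).all():
            raise ValueError("standard deviations must be positive and finite")


def _feature_matrix(features: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    if len(cols) != len(FEATURE_NAMES):
        missing = set(FEATURE_NAMES) - set(features.columns)
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return features[FEATURE_NAMES]


def standardize(
    features: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the four features; reference-anchored when ``params`` is given.

    With ``params`` supplied (e.g. from the reference cohort) the new data are
    scaled with the reference mean/sd unchanged, so new sessions live in the
    same standardized space as the fitted model.
    """
    X = _feature_matrix(features)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("features must be finite")
    if params is None:
        if len(X) < 2:
            raise ValueError("need >= 2 rows to estimate standardization parameters")
        mean, sd = X.mean(), X.std(ddof=1)
        if (sd <= 0).any():
            bad = sd.index[sd <= 0].tolist()
            raise ValueError(f"zero variance in features {bad}; supply params")
        params = StandardizationParams(mean=mean, sd=sd)
    Z = (X - params.mean) / params.sd
    return Z, params


def similarity(standardized: pd.DataFrame | np.ndarray, form: str = "inverse") -> np.ndarray:
    """Pairwise similarity from Euclidean distance in standardized feature space.

    ``inverse`` (default): S = 1/(1+D); ``exp``: S = exp(-D). Both are
    strictly decreasing in D with S(0) = 1, giving weights in (0, 1].
    """
    X = np.asarray(standardized, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("standardized features must be finite")
    D = squareform(pdist(X, metric="euclidean"))
    return _sim_from_dist(D, form)


def _sim_from_dist(D: np.ndarray, form: str) -> np.ndarray:
    if form == "inverse":
        return 1.0 / (1.0 + D)
    if form == "exp":
        return np.exp(-D)
    raise ValueError(f"unknown similarity form {form!r}")


def _neighbor_order(sim_row: np.ndarray, self_idx: int | None) -> np.ndarray:
    """Indices sorted by decreasing similarity, ties broken by lower index."""
    n = sim_row.size
    idx = np.arange(n)
    order = np.lexsort((idx, -sim_row))
    if self_idx is not None:
        order = order[order != self_idx]
    return order


def build_knn_graph(similarities: np.ndarray, k: int) -> nx.Graph:
    """Weighted undirected k-nearest-neighbor graph (union symmetrization).

    Edge (i, j) is present iff j is among i's k most similar neighbors or
    vice versa, weighted by S_ij. Similarity ties are broken toward the lower
    node index, making the edge set deterministic.
    """
    S = np.asarray(similarities, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not (1 <= k < n):
        raise ValueError(f"k={k} out of range for n={n}")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in _neighbor_order(S[i], i)[:k]:
            G.add_edge(i, int(j), weight=float(S[i, j]))
    return G


def louvain_partition(graph: nx.Graph, seed: int = 0) -> np.ndarray:
    """Louvain community labels, 1-based, numbered by descending community size.

    The greedy node-visit order is randomized by ``seed``, so a fixed seed
    gives a fixed partition. Size ties are broken toward the community
    containing the smallest node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=1.0, seed=int(seed)
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    nodes = sorted(graph.nodes())
    node_pos = {v: i for i, v in enumerate(nodes)}
    for cid, comm in enumerate(communities, start=1):
        for v in comm:
            labels[node_pos[v]] = cid
    return labels


def scan_k(
    features: pd.DataFrame,
    k_values,
    seed: int = 0,
    params: StandardizationParams | None = None,
    form: str = "inverse",
) -> pd.DataFrame:
    """Internal clustering indices over a range of k.

    For each k: build the similarity k-NN graph, run Louvain, then score the
    partition on the standardized feature cloud with the Calinski–Harabasz
    (higher better), Silhouette (higher better) and Davies–Bouldin (lower
    better) indices. A k yielding a single community gets NaN indices.
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    Z, _ = standardize(features, params)
    S = similarity(Z, form=form)
    X = Z.to_numpy()
    rows = []
    for k in k_values:
        G = build_knn_graph(S, int(k))
        labels = louvain_partition(G, seed=seed)
        n_comm = int(labels.max())
        if n_comm >= 2:
            ch = calinski_harabasz_score(X, labels)
            sil = silhouette_score(X, labels)
            db = davies_bouldin_score(X, labels)
        else:
            ch = sil = db = np.nan
        rows.append(
            {
                "k": int(k),
                "n_communities": n_comm,
                "calinski_harabasz": ch,
                "silhouette": sil,
                "davies_bouldin": db,
            }
        )
    return pd.DataFrame(rows)


def select_k(scan: pd.DataFrame, window: int = 5) -> int:
    """Pick k from the middle of the best plateau of a k-scan.

    A k is a candidate when its combined index rank — the mean of its ranks
    by Calinski–Harabasz (descending), Silhouette (descending) and
    Davies–Bouldin (ascending) — falls in the top ``1/window`` quantile of
    scanned ks. The selected k is the middle element of the longest
    contiguous candidate run with a constant community count, which
    operationalizes "the middle of a regime that optimizes internal
    clustering and is robust to small changes in k". With no run of length
    >= 2, the single best-ranked k is returned with a warning.
    """
    if scan.empty:
        raise ValueError("empty k-scan")
    df = scan.reset_index(drop=True)
    valid = df["n_communities"] >= 2
    if not valid.any():
        raise ValueError("no scanned k produced >= 2 communities")
    ranks = pd.DataFrame(
        {
            "ch": (-df["calinski_harabasz"]).rank(),
            "sil": (-df["silhouette"]).rank(),
            "db": df["davies_bouldin"].rank(),
        }
    )
    combined = ranks.mean(axis=1)
    combined[~valid] = np.inf
    threshold = np.nanquantile(combined[valid], 1.0 / window)
    good = (combined <= threshold) & valid

    best_run: tuple[int, int] | None = None  # (start, stop) inclusive
    start = None
    for i in range(len(df) + 1):
        ok = (
            i < len(df)
            and bool(good[i])
            and (start is None or df["n_communities"][i] == df["n_communities"][start])
        )
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if best_run is None or (i - 1 - start) > (best_run[1] - best_run[0]):
                best_run = (start, i - 1)
            # the current k may begin a new run
            start = i if (i < len(df) and bool(good[i])) else None
    if best_run is None or best_run[1] == best_run[0]:
        best = int(combined.idxmin())
        warnings.warn("no index-optimal plateau of length >= 2; returning the best single k")
        return int(df["k"][best])
    lo, hi = best_run
    mid = lo + (hi - lo) // 2 if (hi - lo) % 2 == 0 else lo + (hi - lo + 1) // 2
    return int(df["k"][mid])


@dataclass
class ClusterModel:
    """A fitted reference clustering.

    Holds the standardized reference features, the standardization
    parameters, the k-NN similarity graph, 1-based community labels ordered
    by descending size, and the assignment neighbor count
    ``m_assign = floor(n_min / 2)`` where ``n_min`` is the smallest
    community's size.
    """

    reference: pd.DataFrame  # standardized features, FEATURE_NAMES columns
    fish_ids: pd.Series
    params: StandardizationParams
    graph: nx.Graph
    labels: np.ndarray
    k: int
    seed: int
    form: str = "inverse"

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    @property
    def n_min(self) -> int:
        return int(np.bincount(self.labels)[1:].min())

    @property
    def m_assign(self) -> int:
        return max(self.n_min // 2, 1)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fish_id": self.fish_ids.to_numpy(), "cluster": self.labels})


def fit(
    features: pd.DataFrame,
    k: int | None = None,
    k_values=None,
    seed: int = 0,
    form: str = "inverse",
    window: int = 5,
) -> ClusterModel:
    """Fit the reference clustering on a cohort's feature table.

    Standardizes, computes similarities, builds the k-NN graph (running the
    index scan and plateau selection when ``k`` is not given), and partitions
    with seeded Louvain. ``features`` needs the four feature columns plus,
    optionally, ``fish_id``.
    """
    Z, params = standardize(features)
    n = len(Z)
    if k is None:
        if k_values is None:
            hi = min(max(n // 2, 12), n - 1)
            k_values = range(10, hi + 1, max((hi - 10) // 24, 1))
        scan = scan_k(features, k_values, seed=seed, form=form)
        k = select_k(scan, window=window)
    if not (1 <= k < n):
        raise ValueError(f"k={k} out of range for n={n}")
    S = similarity(Z, form=form)
    G = build_knn_graph(S, k)
    labels = louvain_partition(G, seed=seed)
    fish_ids = (
        features["fish_id"].reset_index(drop=True)
        if "fish_id" in features.columns
        else pd.Series([str(i) for i in range(n)])
    )
    return ClusterModel(
        reference=Z.reset_index(drop=True),
        fish_ids=fish_ids,
        params=params,
        graph=G,
        labels=labels,
        k=int(k),
        seed=int(seed),
        form=form,
    )


def assign(model: ClusterModel, new_features: pd.DataFrame) -> np.ndarray:
    """Assign new fish-sessions to the reference communities.

    Each new row is standardized with the reference parameters; its
    ``m_assign`` most-similar reference fish are found, and the label is the
    community holding the largest share of those neighbors. Ties go to the
    community with the larger total similarity among the tied neighbors,
    then to the lower community id.
    """
    m = model.m_assign
    if m > len(model.reference):
        raise ValueError("m_assign exceeds the reference cohort size")
    Z_new, _ = standardize(new_features, model.params)
    D = cdist(Z_new.to_numpy(), model.reference.to_numpy())
    S = _sim_from_dist(D, model.form)
    n_comm = model.n_communities
    out = np.empty(len(Z_new), dtype=int)
    for i in range(len(Z_new)):
        nbrs = _neighbor_order(S[i], None)[:m]
        nbr_labels = model.labels[nbrs]
        counts = np.bincount(nbr_labels, minlength=n_comm + 1)[1:]
        sims = np.bincount(nbr_labels, weights=S[i, nbrs], minlength=n_comm + 1)[1:]
        best = np.flatnonzero(counts == counts.max())
        if best.size > 1:
            best = best[sims[best] == sims[best].max()]
        out[i] = int(best[0]) + 1
    return out


def name_clusters(model: ClusterModel) -> dict[int, str]:
    """Attach semantic archetype names to numeric communities.

    Matches each community's mean standardized feature signature to the
    canonical profiles: lowest bottom distance + percent explored -> shy;
    highest center distance -> wall_hugger; highest distance travelled +
    percent explored -> active_explorer; highest bottom distance with lowest
    center distance -> bold. Assignment is greedy on the strength of each
    signature so every community gets a distinct name (when there are at
    most four communities).
    """
    prof = model.reference.groupby(model.labels).mean()
    scores = pd.DataFrame(
        {
            "shy": -(prof["bottom_cm"] + prof["percent_explored"]),
            "wall_hugger": prof["center_cm"],
            "active_explorer": prof["distance_cm"] + prof["percent_explored"],
            "bold": prof["bottom_cm"] - prof["center_cm"],
        }
    )
    names: dict[int, str] = {}
    taken_names: set[str] = set()
    flat = scores.stack().sort_values(ascending=False)
    for (cid, name), _ in flat.items():
        if cid in names or name in taken_names:
            continue
        names[int(cid)] = name
        taken_names.add(name)
    for cid in prof.index:
        names.setdefault(int(cid), f"cluster_{cid}")
    return names


def save_model(model: ClusterModel, path) -> None:
    """Serialize a ClusterModel to a directory (params.json, edges.csv, labels.csv, reference.csv)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    params = {
        "mean": model.params.mean.to_dict(),
        "sd": model.params.sd.to_dict(),
        "k": model.k,
        "seed": model.seed,
        "form": model.form,
        "m_assign": model.m_assign,
    }
    (p / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True))
    edges = nx.to_pandas_edgelist(model.graph)
    edges = edges.rename(columns={"source": "i", "target": "j"})[["i", "j", "weight"]]
    # %.17g round-trips doubles exactly, so save -> load -> save is byte-stable
    edges.sort_values(["i", "j"]).to_csv(p / "edges.csv", index=False, float_format="%.17g")
    model.labels_frame().to_csv(p / "labels.csv", index=False)
    ref = model.reference.copy()
    ref.insert(0, "fish_id", model.fish_ids.to_numpy())
    ref.to_csv(p / "reference.csv", index=False, float_format="%.17g")


def load_model(path) -> ClusterModel:
    p = Path(path)
    params = json.loads((p / "params.json").read_text())
    # round_trip parsing pairs with the %.17g writer for exact byte stability
    ref = pd.read_csv(p / "reference.csv", float_precision="round_trip")
    labels = pd.read_csv(p / "labels.csv")["cluster"].to_numpy(dtype=int)
    edges = pd.read_csv(p / "edges.csv", float_precision="round_trip")
    G = nx.Graph()
    G.add_nodes_from(range(len(ref)))
    G.add_weighted_edges_from(edges.itertuples(index=False, name=None))
    return ClusterModel(
        reference=ref[FEATURE_NAMES],
        fish_ids=ref["fish_id"],
        params=StandardizationParams(
            mean=pd.Series(params["mean"])[FEATURE_NAMES],
            sd=pd.Series(params["sd"])[FEATURE_NAMES],
        ),
        graph=G,
        labels=labels,
        k=int(params["k"]),
        seed=int(params["seed"]),
        form=params["form"],
    )
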