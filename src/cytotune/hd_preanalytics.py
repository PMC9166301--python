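"""Pre-analytical steps for high-dimensional analysis and capture metrics.

The HD pipeline applied to a multicolor acquisition is: arcsinh scaling,
density-based censoring of multidimensional scattered outliers (a fixed
percentage of the lowest-density events, 3% by default), optional balanced
down-sampling, delegated embedding/clustering, and evaluation of whether
truth-defined rare subsets are captured by single clusters (recall/purity)
or fragmented across several.

The density estimate is the inverse distance to the k-th nearest neighbour
(k = 30 by default) in the transformed channel space — a desk-scale stand-in
for spanning-tree density normalization with the same censoring behaviour:
isolated outliers have distant neighbours and are removed first, while dense
rare islands survive with their frequency intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from . import defaults
from .exceptions import ConfigError
from .fcs_io import EventTable

__all__ = [
    "TransformParams",
    "CensorParams",
    "SubsetCapture",
    "CaptureReport",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "density_censor",
    "downsample",
    "cluster_capture",
    "run_embedding_and_clustering",
    "cluster_median_table",
]


@dataclass(frozen=True)
class TransformParams:
    """Per-channel arcsinh cofactors (scalar broadcasts to all channels)."""

    cofactor: float | dict[str, float] = defaults.ARCSINH_COFACTOR

    def vector(self, detectors: list[str]) -> np.ndarray:
        if isinstance(self.cofactor, dict):
            try:
                arr = np.array([self.cofactor[d] for d in detectors],
                               dtype=float)
            except KeyError as exc:
                raise ConfigError(f"no cofactor for channel {exc}") from None
        else:
            arr = np.full(len(detectors), float(self.cofactor))
        if np.any(arr <= 0):
            raise ConfigError("arcsinh cofactors must be positive")
        return arr


def arcsinh_transform(table: EventTable,
                      params: TransformParams = TransformParams()
                      ) -> EventTable:
    """value -> arcsinh(value / cofactor), per channel; invertible."""
    cof = params.vector(table.detector_names)
    out = table.with_data(np.arcsinh(table.data / cof),
                          transform="arcsinh",
                          transform_cofactors=None)
    out.meta["transform_cofactors"] = cof
    return out


def inverse_arcsinh_transform(table: EventTable,
                              params: TransformParams | None = None
                              ) -> EventTable:
    cof = (params.vector(table.detector_names) if params is not None
           else table.meta.get("transform_cofactors"))
    if cof is None:
        raise ConfigError("no cofactors recorded or supplied for inversion")
    out = table.with_data(np.sinh(table.data) * cof, transform="linear")
    out.meta.pop("transform_cofactors", None)
    return out


@dataclass(frozen=True)
class CensorParams:
    """Density-censoring settings: percentage cut, k, channels used."""

    fraction: float = defaults.CENSOR_FRACTION  # percent of events
    k: int = defaults.DENSITY_K
    channels: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0 < self.fraction < 50:
            raise ConfigError("censor fraction must be in (0, 50) percent")
        if self.k < 2:
            raise ConfigError("density k must be >= 2")


def density_censor(
    table: EventTable,
    params: CensorParams = CensorParams(),
) -> tuple[EventTable, EventTable, dict]:
    """Censor the lowest-density ``fraction`` percent of events.

    Density is the inverse distance to the k-th nearest neighbour (self
    excluded) in the selected channels; exactly
    ``floor(fraction/100 * N)`` events are removed, ties at the boundary
    broken by stable sort on (density, original index).  Expects an
    arcsinh-transformed table (warns otherwise).  Returns (kept, censored,
    report).
    """
    from sklearn.neighbors import NearestNeighbors

    if table.meta.get("transform") != "arcsinh":
        warnings.warn("density_censor expects arcsinh-transformed data",
                      stacklevel=2)
    n = table.n_events
    if params.k >= n:
        raise ConfigError(f"k={params.k} must be smaller than N={n}")
    cols = ([table.channel_index(c) for c in params.channels]
            if params.channels else slice(None))
    X = table.data[:, cols]
    nn = NearestNeighbors(n_neighbors=params.k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    kdist = dist[:, -1]
    with np.errstate(divide="ignore"):
        density = np.where(kdist > 0, 1.0 / kdist, np.inf)

    n_censor = int(np.floor(params.fraction / 100.0 * n))
    order = np.argsort(density, kind="stable")
    censored_idx = np.sort(order[:n_censor])
    kept_mask = np.ones(n, dtype=bool)
    kept_mask[censored_idx] = False

    def subset(mask: np.ndarray) -> EventTable:
        meta = {k: (v[mask] if isinstance(v, np.ndarray)
                    and v.shape[:1] == (n,) else v)
                for k, v in table.meta.items()}
        return EventTable(data=table.data[mask],
                          channels=list(table.channels), meta=meta)

    report = {
        "n_events": n,
        "n_censored": n_censor,
        "fraction": params.fraction,
        "k": params.k,
        "density_threshold": float(density[order[n_censor - 1]])
        if n_censor else None,
    }
    return subset(kept_mask), subset(~kept_mask), report


def downsample(tables: list[EventTable], target_n: int, seed: int
               ) -> list[EventTable]:
    """Uniform random subsample (without replacement) per table, seeded.

    Tables at or below ``target_n`` events pass through unchanged; row order
    of the survivors is preserved.
    """
    if target_n <= 0:
        raise ConfigError("target_n must be positive")
    seeds = np.random.SeedSequence(seed).generate_state(len(tables))
    out = []
    for t, s in zip(tables, seeds):
        n = t.n_events
        if n <= target_n:
            out.append(t)
            continue
        rng = np.random.default_rng(int(s))
        keep = np.sort(rng.choice(n, size=target_n, replace=False))
        meta = {k: (v[keep] if isinstance(v, np.ndarray)
                    and v.shape[:1] == (n,) else v)
                for k, v in t.meta.items()}
        out.append(EventTable(data=t.data[keep], channels=list(t.channels),
                              meta=meta))
    return out


@dataclass
class SubsetCapture:
    subset: str
    n_events: int
    best_cluster: int
    best_cluster_recall: float
    best_cluster_purity: float
    n_clusters_containing: int
    fragmented: bool


@dataclass
class CaptureReport:
    """Per-truth-subset capture metrics against a clustering."""

    subsets: dict[str, SubsetCapture]
    params: dict = field(default_factory=dict)

    def __getitem__(self, subset: str) -> SubsetCapture:
        return self.subsets[subset]


def cluster_capture(
    cluster_labels,
    truth_labels,
    subset_min_share: float = 0.05,
    subsets=None,
) -> CaptureReport:
    """Score how well each truth subset is captured by single clusters.

    For each subset: the best cluster is the one holding the largest share
    of the subset (recall); purity is that subset's share of the best
    cluster; a subset is fragmented when more than one cluster holds at
    least ``subset_min_share`` of it.
    """
    cl = np.asarray(cluster_labels)
    tr = np.asarray(truth_labels)
    if cl.shape != tr.shape:
        raise ConfigError("cluster and truth label vectors differ in length")
    names = [str(s) for s in (subsets if subsets is not None
                              else np.unique(tr))]
    tr = tr.astype(str)
    out = {}
    clusters, cl_idx = np.unique(cl, return_inverse=True)
    for name in names:
        mask = tr == name
        n_sub = int(mask.sum())
        if n_sub == 0:
            raise ConfigError(f"truth subset {name!r} has no events")
        counts = np.bincount(cl_idx[mask], minlength=clusters.size)
        best = int(np.argmax(counts))
        recall = counts[best] / n_sub
        cluster_size = int((cl_idx == best).sum())
        purity = counts[best] / cluster_size if cluster_size else 0.0
        containing = int(np.sum(counts >= subset_min_share * n_sub))
        out[name] = SubsetCapture(
            subset=name, n_events=n_sub, best_cluster=int(clusters[best])
            if np.issubdtype(clusters.dtype, np.integer) else best,
            best_cluster_recall=float(recall),
            best_cluster_purity=float(purity),
            n_clusters_containing=containing,
            fragmented=containing > 1)
    return CaptureReport(subsets=out,
                         params={"subset_min_share": subset_min_share})


def run_embedding_and_clustering(
    table: EventTable,
    n_neighbors: int = 30,
    exclude_channels: tuple[str, ...] = (),
    embedding: str = "none",
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Delegated embedding + neighbour-graph community detection.

    Builds a k-nearest-neighbour graph on the selected (transformed)
    channels and partitions it with the Leiden algorithm (seeded, hence
    deterministic); optionally computes a 2-D UMAP embedding.  Excluded
    channels (viability dye, lineage pre-gates) are dropped before both
    steps.  Returns ``(embedding or None, cluster labels)`` and attaches
    both to ``table.meta``.
    """
    import igraph
    import leidenalg

    use = [d for d in table.detector_names if d not in exclude_channels]
    if not use:
        raise ConfigError("all channels excluded")
    X = table.data[:, [table.channel_index(d) for d in use]]
    n = X.shape[0]
    if n_neighbors >= n:
        raise ConfigError(f"n_neighbors={n_neighbors} must be < N={n}")

    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(i, j) if i < j else (j, i)
             for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    labels = np.asarray(part.membership)

    coords = None
    if embedding == "umap":
        import umap

        coords = umap.UMAP(n_neighbors=n_neighbors, random_state=int(seed)
                           ).fit_transform(X)
    elif embedding != "none":
        raise ConfigError(f"unknown embedding {embedding!r}")

    table.meta["cluster_labels"] = labels
    if coords is not None:
        table.meta["embedding"] = coords
    return coords, labels


def cluster_median_table(table: EventTable, cluster_labels=None):
    """Per-cluster per-channel median intensities (phenotype heat-map table)."""
    labels = np.asarray(cluster_labels if cluster_labels is not None
                        else table.meta.get("cluster_labels"))
    if labels is None or labels.shape[:1] != (table.n_events,):
        raise ConfigError("cluster labels missing or wrong length")
    df = table.to_dataframe()
    df["cluster"] = labels
    return df.groupby("cluster").median()
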