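"""Synthetic study systems for end-to-end testing of the pipeline.

The generators emulate the statistical structure the analysis assumes:
an ultrametric dated phylogeny (pure-birth), a continuous trait with
phylogenetic signal (Brownian motion), landform-structured assemblages
whose composition is neutral, environmentally filtered (clustered) or
competitively thinned (overdispersed), and spatially autocorrelated
covariates and responses on k-nearest-neighbour weights.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .spatial import SpatialWeights
from .trees import DatedTree

#: landform labels mirroring the five bedrock categories of the study design
DEFAULT_LANDFORMS = ("karst", "karst-granitic", "granitic", "Danxia", "desert")


@dataclass(frozen=True)
class AssemblyConfig:
    """Design of a synthetic multi-landform assemblage experiment."""

    n_species: int
    n_sites_per_landform: int = 4
    n_landforms: int = 5
    mode: str = "neutral"
    filter_strength: float = 5.0
    richness_range: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.mode not in ("neutral", "clustered", "overdispersed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be nonnegative")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid richness_range")
        if hi > self.n_species:
            raise ValueError("richness_range exceeds n_species")
        if not (1 <= self.n_landforms <= len(DEFAULT_LANDFORMS)):
            raise ValueError("n_landforms out of range")

    @property
    def landforms(self) -> tuple[str, ...]:
        return DEFAULT_LANDFORMS[: self.n_landforms]


# ----------------------------------------------------------------------
# trees and traits
# ----------------------------------------------------------------------


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | None = None) -> DatedTree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` extant tips.

    Lineages split at rate ``birth_rate`` each; after the last split an
    additional exponential waiting time separates the final split from
    the present, so all tips are extant and the tree is ultrametric by
    construction.  Tip labels are ``t0001 ...`` in birth order.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = max(4, len(str(n_tips)))
    root = tree.seed_node
    active = [root]
    birth_time = {id(root): 0.0}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for j, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"t{j:0{width}d}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        end = t if node.is_leaf() else min(
            birth_time[id(c)] for c in node.child_nodes())
        # internal node's own split time is its children's birth time
        start = birth_time[id(node)]
        node.edge.length = (t - start) if node.is_leaf() else (
            birth_time[id(node.child_nodes()[0])] - start)
    return DatedTree(tree)


def simulate_bm_trait(tree: DatedTree, sigma2: float, root_state: float = 0.0,
                      seed: int | None = None) -> dict[str, float]:
    """Brownian trait: Gaussian increments with variance sigma2 x branch."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = root_state
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, math.sqrt(sigma2 * bl)) if sigma2 > 0 and bl > 0 else 0.0
            values[id(node)] = values[id(parent)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


# ----------------------------------------------------------------------
# assemblages
# ----------------------------------------------------------------------


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int
                                         ) -> np.ndarray:
    """Successive draws, weights renormalized after each removal."""
    w = weights.astype(float).copy()
    chosen = []
    for _ in range(k):
        p = w / w.sum()
        i = int(rng.choice(len(w), p=p))
        chosen.append(i)
        w[i] = 0.0
    return np.asarray(chosen)


def _overdispersed_community(labels: list[str], D: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximin selection: seed with the two most distant species,
    then add the species with the largest minimum distance to the chosen
    set; ties broken by lexicographic tip label."""
    n = len(labels)
    order = np.argsort(labels)  # lexicographic tie-break helper
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            key = (-D[i, j], min(rank[i], rank[j]), max(rank[i], rank[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
    chosen = [best[1], best[2]]
    chosen.sort(key=lambda i: rank[i])
    while len(chosen) < k:
        mind = D[:, chosen].min(axis=1)
        mind[chosen] = -np.inf
        cand = np.flatnonzero(mind == mind.max())
        nxt = cand[np.argmin(rank[cand])]
        chosen.append(int(nxt))
    return np.asarray(chosen[:k])


def simulate_assemblages(
    tree: DatedTree, trait: dict[str, float], config: AssemblyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-by-species 0/1 matrix plus a site/landform predictor skeleton.

    neutral: uniform sampling without replacement from the pool.
    clustered: each landform has an optimum trait (equally spaced
    quantiles of the trait distribution); species are drawn without
    replacement with weight exp(-filter_strength * (trait - optimum)^2).
    overdispersed: deterministic greedy maximin of patristic distance.
    """
    labels, D = tree.patristic_matrix()
    if set(trait) != set(labels):
        raise ValueError("trait keys must equal tree tips")
    tvals = np.asarray([trait[l] for l in labels])
    rng = np.random.default_rng(config.seed)
    lo, hi = config.richness_range
    quantiles = [(i + 1) / (config.n_landforms + 1)
                 for i in range(config.n_landforms)]
    optima = np.quantile(tvals, quantiles)
    rows, meta = [], []
    for li, landform in enumerate(config.landforms):
        for s in range(config.n_sites_per_landform):
            k = int(rng.integers(lo, hi + 1))
            if config.mode == "neutral":
                idx = rng.choice(len(labels), size=k, replace=False)
            elif config.mode == "clustered":
                w = np.exp(-config.filter_strength * (tvals - optima[li]) ** 2)
                w = np.maximum(w, 1e-300)
                idx = _weighted_sample_without_replacement(rng, w, k)
            else:
                idx = _overdispersed_community(labels, D, k)
            row = np.zeros(len(labels), dtype=int)
            row[idx] = 1
            rows.append(row)
            meta.append({"site_id": f"{landform}_{s + 1:02d}",
                         "landform": landform})
    matrix = pd.DataFrame(rows, columns=labels,
                          index=[m["site_id"] for m in meta])
    predictors = pd.DataFrame(meta).set_index("site_id")
    return matrix, predictors


# ----------------------------------------------------------------------
# spatial covariates and responses
# ----------------------------------------------------------------------


def random_coords(n: int, seed: int | None = None,
                  bbox: tuple[float, float, float, float] = (80.0, 130.0, 20.0, 50.0)
                  ) -> pd.DataFrame:
    """Uniform site coordinates (lon, lat) on a rectangle."""
    rng = np.random.default_rng(seed)
    lon0, lon1, lat0, lat1 = bbox
    return pd.DataFrame({
        "lon": rng.uniform(lon0, lon1, n),
        "lat": rng.uniform(lat0, lat1, n),
    })


def _sar_draw(rng, weights: SpatialWeights, lam: float, size: int) -> np.ndarray:
    n = weights.n
    A = np.eye(n) - lam * weights.matrix
    eps = rng.standard_normal((n, size))
    try:
        return np.linalg.solve(A, eps)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"I - lambda*W is singular at lambda={lam}") from exc


def simulate_predictors(weights: SpatialWeights, lambda_x: float,
                        n_columns: int = 1, seed: int | None = None,
                        names: list[str] | None = None) -> pd.DataFrame:
    """Spatially autocorrelated covariates x = (I - lambda W)^-1 eps."""
    if not (abs(lambda_x) < 1):
        raise ValueError("|lambda_x| must be < 1")
    rng = np.random.default_rng(seed)
    X = _sar_draw(rng, weights, lambda_x, n_columns)
    names = names or [f"x{j + 1}" for j in range(n_columns)]
    return pd.DataFrame(X, columns=names, index=weights.ids)


def simulate_sem_response(X, beta, weights: SpatialWeights, lambda_err: float,
                          sigma: float = 1.0, seed: int | None = None
                          ) -> np.ndarray:
    """Response y = X beta + u with spatially autoregressive errors."""
    if not (abs(lambda_err) < 1):
        raise ValueError("|lambda_err| must be < 1")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.shape[1] != beta.shape[0] or X.shape[0] != weights.n:
        raise ValueError("nonconformable shapes for X, beta and weights")
    rng = np.random.default_rng(seed)
    u = sigma * _sar_draw(rng, weights, lambda_err, 1)[:, 0] if sigma > 0 else 0.0
    return X @ beta + u
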