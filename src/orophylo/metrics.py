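"""Community phylogenetic diversity and structure under the uniform null.

Observed metrics per flora (community): species richness SR, Faith's PD
(sum of branch lengths of the minimal subtree spanning the community),
mean pairwise patristic distance MPD, and mean nearest-taxon distance
MNTD.  Each is standardized against the *uniform* null model, in which
every subset of size k drawn from the tips of the supplied tree is
equally likely:

    PDI =  (PD_obs  - mean PD_null)  / sd PD_null
    NRI = -(MPD_obs - mean MPD_null) / sd MPD_null
    NTI = -(MNTD_obs- mean MNTD_null)/ sd MNTD_null

so positive NRI/NTI indicates phylogenetic clustering and negative values
overdispersion, while PDI keeps the sign of the PD deviation.

Three engines provide the null moments: exhaustive enumeration over all
C(n, k) subsets (exact, population sd), seeded Monte-Carlo subsampling
(sample sd), and analytic means (per-edge inclusion probabilities for PD;
the k-free mean pairwise distance for MPD) with the sd delegated to
Monte-Carlo.  The engines must agree on small pools, which the test suite
exploits as an internal oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .trees import DatedTree, MissingTaxonError

ENUMERATE_CAP = 100_000
_ENGINES = ("enumerate", "montecarlo", "analytic", "auto")


@dataclass(frozen=True)
class NullMoments:
    """Mean and sd of a metric over uniform draws of k tips from n."""

    metric: str
    k: int
    mean: float
    sd: float
    engine: str
    n_rand: int | None = None
    seed: int | None = None


class _TreeCache:
    """Per-tree precomputation: tip order, distances, edge incidence."""

    def __init__(self, tree: DatedTree):
        self.labels, self.D = tree.patristic_matrix()
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.n = len(self.labels)
        # edge table: for every non-root edge, its length and the tip set below
        lengths: list[float] = []
        below: list[np.ndarray] = []
        dtree = tree.dendropy_tree
        tipsets: dict[int, np.ndarray] = {}
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                vec = np.zeros(self.n, dtype=bool)
                vec[self.index[node.taxon.label]] = True
            else:
                vec = np.zeros(self.n, dtype=bool)
                for c in node.child_nodes():
                    vec |= tipsets[id(c)]
            tipsets[id(node)] = vec
            if node.parent_node is not None:
                lengths.append(node.edge.length or 0.0)
                below.append(vec)
        self.edge_lengths = np.asarray(lengths)
        self.edge_below = np.asarray(below).T  # (n_tips, n_edges) 0/1
        self.root_depths = None  # filled lazily for pd_include_root

    def indices(self, community) -> np.ndarray:
        try:
            return np.asarray([self.index[s] for s in community])
        except KeyError as exc:
            raise MissingTaxonError(f"species {exc.args[0]!r} not in tree") from exc


def _pd_from_membership(cache: _TreeCache, member: np.ndarray, include_root: bool
                        ) -> np.ndarray:
    """PD for each row of a boolean membership matrix (rows are draws)."""
    counts = member.astype(np.int64) @ cache.edge_below
    k = member.sum(axis=1, keepdims=True)
    if include_root:
        used = counts > 0
    else:
        used = (counts > 0) & (counts < k)
    return used @ cache.edge_lengths


def _pairwise_stats(cache: _TreeCache, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(MPD, MNTD) for each row of an index matrix (rows are communities)."""
    sub = cache.D[idx[:, :, None], idx[:, None, :]]
    k = idx.shape[1]
    mpd = sub.sum(axis=(1, 2)) / (k * (k - 1))
    np.einsum("ijj->ij", sub)[:] = np.inf
    mntd = sub.min(axis=2).mean(axis=1)
    return mpd, mntd


# ----------------------------------------------------------------------
# observed metrics
# ----------------------------------------------------------------------


def faith_pd(tree: DatedTree, community, include_root: bool = False) -> float:
    """Sum of branch lengths of the minimal subtree spanning the community.

    By default the subtree is not forced to include the root, so a
    singleton community has PD 0; ``include_root=True`` adds the path to
    the root (Faith's original convention).
    """
    community = list(community)
    if not community:
        raise ValueError("empty community")
    cache = _cache_for(tree)
    member = np.zeros((1, cache.n), dtype=bool)
    member[0, cache.indices(community)] = True
    return float(_pd_from_membership(cache, member, include_root)[0])


def mpd(tree: DatedTree, community) -> float:
    """Mean patristic distance over all unordered pairs in the community."""
    idx = _pair_indices(tree, community)
    return float(_pairwise_stats(_cache_for(tree), idx)[0][0])


def mntd(tree: DatedTree, community) -> float:
    """Mean distance from each member to its nearest other member."""
    idx = _pair_indices(tree, community)
    return float(_pairwise_stats(_cache_for(tree), idx)[1][0])


def _pair_indices(tree: DatedTree, community) -> np.ndarray:
    community = list(community)
    if len(community) < 2:
        raise ValueError("community must contain at least 2 species")
    cache = _cache_for(tree)
    return cache.indices(community)[None, :]


def _cache_for(tree: DatedTree) -> _TreeCache:
    # stored on the tree; DatedTree._refresh clears it on any mutation
    cache = getattr(tree, "_metrics_cache", None)
    if cache is None:
        cache = _TreeCache(tree)
        tree._metrics_cache = cache
    return cache


# ----------------------------------------------------------------------
# null moments
# ----------------------------------------------------------------------


def null_moments(
    tree: DatedTree,
    metric: str,
    k: int,
    engine: str = "auto",
    n_rand: int = 999,
    seed: int | None = None,
    include_root: bool = False,
    enumerate_cap: int = ENUMERATE_CAP,
) -> NullMoments:
    """Moments of PD/MPD/MNTD over uniform size-k subsets of the tree tips."""
    metric = metric.upper()
    if metric not in ("PD", "MPD", "MNTD"):
        raise ValueError(f"unknown metric {metric!r}")
    cache = _cache_for(tree)
    n = cache.n
    kmin = 1 if metric == "PD" else 2
    if not (kmin <= k <= n):
        raise ValueError(f"k={k} outside [{kmin}, {n}] for {metric}")
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "auto":
        engine = "enumerate" if math.comb(n, k) <= enumerate_cap else "montecarlo"

    if engine == "enumerate":
        if math.comb(n, k) > enumerate_cap:
            raise ValueError(
                f"C({n},{k}) = {math.comb(n, k)} exceeds enumeration cap {enumerate_cap}"
            )
        vals = _enumerate_values(cache, metric, k, include_root)
        return NullMoments(metric, k, float(vals.mean()),
                           float(vals.std(ddof=0)), "enumerate")

    if engine == "montecarlo":
        vals = _montecarlo_values(cache, metric, k, n_rand, seed, include_root)
        return NullMoments(metric, k, float(vals.mean()),
                           float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                           "montecarlo", n_rand=n_rand, seed=seed)

    # analytic means; sd (where needed) from Monte-Carlo
    if metric == "PD":
        mean = _analytic_pd_mean(cache, k, include_root)
    elif metric == "MPD":
        iu = np.triu_indices(n, 1)
        mean = float(cache.D[iu].mean())  # independent of k under the uniform null
    else:
        raise ValueError("no analytic moments for MNTD; use enumerate or montecarlo")
    if k == n:
        sd = 0.0
    else:
        vals = _montecarlo_values(cache, metric, k, n_rand, seed, include_root)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return NullMoments(metric, k, mean, sd, "analytic", n_rand=n_rand, seed=seed)


def _enumerate_values(cache: _TreeCache, metric: str, k: int,
                      include_root: bool) -> np.ndarray:
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(cache.n), k)),
        dtype=np.intp,
    ).reshape(-1, k)
    return _values_for_indices(cache, metric, combos, include_root)


def _montecarlo_values(cache: _TreeCache, metric: str, k: int, n_rand: int,
                       seed: int | None, include_root: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    # uniform k-subsets without replacement: k smallest of n iid uniforms
    u = rng.random((n_rand, cache.n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    return _values_for_indices(cache, metric, idx, include_root)


def _values_for_indices(cache: _TreeCache, metric: str, idx: np.ndarray,
                        include_root: bool) -> np.ndarray:
    if metric == "PD":
        member = np.zeros((idx.shape[0], cache.n), dtype=bool)
        np.put_along_axis(member, idx, True, axis=1)
        return _pd_from_membership(cache, member, include_root)
    mpd_vals, mntd_vals = _pairwise_stats(cache, idx)
    return mpd_vals if metric == "MPD" else mntd_vals


def _analytic_pd_mean(cache: _TreeCache, k: int, include_root: bool) -> float:
    n = cache.n
    total = math.comb(n, k)
    m = cache.edge_below.sum(axis=0)  # tips below each edge
    inside = np.array([math.comb(int(mi), k) if mi >= k else 0 for mi in m])
    outside = np.array([math.comb(int(n - mi), k) if n - mi >= k else 0 for mi in m])
    if include_root:
        p = 1.0 - outside / total
    else:
        p = 1.0 - (outside + inside) / total
    return float(p @ cache.edge_lengths)


# ----------------------------------------------------------------------
# per-site SES metrics
# ----------------------------------------------------------------------


class PhyloDiversityMetrics(BaseEstimator, TransformerMixin):
    """Transformer: site-by-species presences -> per-site diversity table.

    Parameters
    ----------
    tree : DatedTree
        Dated phylogeny whose tips define the species pool of the uniform
        null.  Sites may use any subset of the tips.
    engine : {"auto", "enumerate", "montecarlo", "analytic"}
        Null-moment engine; "auto" enumerates while C(n, k) stays below
        ``enumerate_cap`` and otherwise falls back to Monte-Carlo.
    n_rand : int
        Number of Monte-Carlo randomizations per community size.
    seed : int or None
        Seed for the Monte-Carlo engine.
    pd_include_root : bool
        Whether PD includes the path from the community subtree to the root.

    After :meth:`fit`, ``null_moments_`` caches moments per distinct
    community size.  :meth:`transform` returns a DataFrame with columns
    SR, PD, MPD, MNTD, PDI, NRI, NTI indexed by site.  Sites whose null
    sd is 0 (e.g. the full pool) get NaN for the affected SES columns.
    """

    def __init__(self, tree: DatedTree | None = None, engine: str = "auto",
                 n_rand: int = 999, seed: int | None = None,
                 pd_include_root: bool = False,
                 enumerate_cap: int = ENUMERATE_CAP):
        self.tree = tree
        self.engine = engine
        self.n_rand = n_rand
        self.seed = seed
        self.pd_include_root = pd_include_root
        self.enumerate_cap = enumerate_cap

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.tree is None:
            raise ValueError("a tree is required")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a sites-by-species DataFrame")
        if X.empty:
            raise ValueError("empty site-by-species matrix")
        vals = X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        cache = _cache_for(self.tree)
        unknown = set(X.columns) - set(cache.labels)
        if unknown:
            raise MissingTaxonError(f"species not in tree: {sorted(unknown)[:5]}")
        if (vals.sum(axis=1) < 1).any():
            raise ValueError("every site must contain at least one species")
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "PhyloDiversityMetrics":
        X = self._validate(X)
        cache = _cache_for(self.tree)
        self.n_pool_ = cache.n
        self.null_moments_: dict[tuple[str, int], NullMoments] = {}
        for k in sorted(set(int(s) for s in X.sum(axis=1))):
            for metric in ("PD", "MPD", "MNTD"):
                if k < 2 and metric != "PD":
                    continue
                engine = self.engine
                if engine == "analytic" and metric == "MNTD":
                    engine = "auto"
                self.null_moments_[(metric, k)] = null_moments(
                    self.tree, metric, k, engine=engine, n_rand=self.n_rand,
                    seed=self.seed, include_root=self.pd_include_root,
                    enumerate_cap=self.enumerate_cap,
                )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "null_moments_"):
            raise ValueError("fit before transform")
        X = self._validate(X)
        cache = _cache_for(self.tree)
        cols = cache.indices(X.columns)
        rows = []
        for site, row in zip(X.index, X.to_numpy().astype(bool)):
            idx = cols[row]
            k = len(idx)
            member = np.zeros((1, cache.n), dtype=bool)
            member[0, idx] = True
            pd_obs = float(_pd_from_membership(cache, member,
                                               self.pd_include_root)[0])
            if k >= 2:
                mpd_obs, mntd_obs = (float(v[0]) for v in
                                     _pairwise_stats(cache, idx[None, :]))
            else:
                mpd_obs = mntd_obs = np.nan
            rec = {"SR": k, "PD": pd_obs, "MPD": mpd_obs, "MNTD": mntd_obs}
            rec["PDI"] = self._ses(("PD", k), pd_obs, flip=False)
            rec["NRI"] = self._ses(("MPD", k), mpd_obs, flip=True)
            rec["NTI"] = self._ses(("MNTD", k), mntd_obs, flip=True)
            rows.append(rec)
        return pd.DataFrame(rows, index=X.index)

    def _ses(self, key: tuple[str, int], obs: float, flip: bool) -> float:
        mom = self.null_moments_.get(key)
        if mom is None or not np.isfinite(obs) or mom.sd == 0:
            return np.nan
        z = (obs - mom.mean) / mom.sd
        return -z if flip else z


def ses_metrics(
    tree: DatedTree,
    matrix: pd.DataFrame,
    engine: str = "auto",
    n_rand: int = 999,
    seed: int | None = None,
    pd_include_root: bool = False,
) -> pd.DataFrame:
    """Per-site SR/PD/MPD/MNTD plus PDI/NRI/NTI against the uniform null."""
    est = PhyloDiversityMetrics(tree=tree, engine=engine, n_rand=n_rand,
                                seed=seed, pd_include_root=pd_include_root)
    return est.fit(matrix).transform(matrix)
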