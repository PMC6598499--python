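"""Phylogenetic comparative methods for the thermal-optimum trait.

Provides penalized-likelihood rate smoothing (substitutions tree -> relative
time tree), the Brownian-motion variance-covariance matrix, Pagel's lambda
and Blomberg's K with their hypothesis tests, nucleotide p-distances under
pairwise deletion, great-circle geographic distances, and the Mantel
permutation test.

Trees are ``dendropy.Tree`` objects throughout; traits are plain
``{tip_label: value}`` mappings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import AlignmentError, ConsistencyError, DataError, TreeError

__all__ = [
    "PhyloCovariance",
    "SignalEstimate",
    "DistanceMatrix",
    "read_tree",
    "write_tree",
    "tip_labels",
    "root_to_tip_depths",
    "is_ultrametric",
    "ultrametricize_pl",
    "phylo_vcv",
    "lambda_transform",
    "fit_pagels_lambda",
    "blombergs_k",
    "k_permutation_test",
    "p_distance_matrix",
    "geographic_distance_matrix",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Tree I/O and basic queries

def read_tree(source: str, from_path: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree, preserving tip labels verbatim."""
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )
    if from_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def root_to_tip_depths(tree: dendropy.Tree) -> dict:
    """Map tip label -> path length from root."""
    depths = {}
    dist = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = dist[node]
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    d = np.array(list(root_to_tip_depths(tree).values()))
    return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))


# ---------------------------------------------------------------------------
# Phylogenetic covariance

@dataclass(frozen=True)
class PhyloCovariance:
    """Shared root-to-MRCA path-length matrix (BM trait covariance shape)."""

    labels: tuple
    matrix: np.ndarray


def phylo_vcv(tree: dendropy.Tree, warn_non_ultrametric: bool = True) -> PhyloCovariance:
    """Entry (i, j) = shared path length from root to MRCA of tips i and j.

    The diagonal holds each tip's root-to-tip depth.  A non-ultrametric
    input is allowed (with a warning): the diagonal then varies.
    """
    leaves = list(tree.leaf_node_iter())
    labels = tuple(leaf.taxon.label for leaf in leaves)
    if len(set(labels)) != len(labels):
        raise TreeError("tip labels must be unique")
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    C = np.zeros((n, n))
    # postorder: leaf-index sets per clade; pairs split at a node share its depth
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node]
            C[i, i] = depth[node]
            below[node] = [i]
        else:
            child_sets = [below.pop(ch) for ch in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.array(child_sets[a])
                    ib = np.array(child_sets[b])
                    C[np.ix_(ia, ib)] = depth[node]
                    C[np.ix_(ib, ia)] = depth[node]
            below[node] = [i for s in child_sets for i in s]
    diag = np.diag(C)
    if warn_non_ultrametric and np.ptp(diag) > 1e-6 * max(diag.max(), 1e-300):
        warnings.warn("tree is not ultrametric; VCV diagonal varies", stacklevel=2)
    return PhyloCovariance(labels=labels, matrix=C)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keeping the diagonal."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _trait_vector(trait: dict, labels) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    extra = [l for l in trait if l not in set(labels)]
    if missing or extra:
        raise ConsistencyError(
            f"trait/tip label mismatch: missing={missing}, extra={extra}"
        )
    y = np.array([float(trait[l]) for l in labels])
    if not np.all(np.isfinite(y)):
        raise DataError("trait values must be finite")
    return y


# ---------------------------------------------------------------------------
# Penalized-likelihood rate smoothing

@dataclass
class _PLProblem:
    """Index arrays describing the smoothing optimization for one tree."""

    n_nodes: int
    root_index: int
    preorder_free: list      # (node_index, parent_index) for free internal nodes
    leaf_indices: np.ndarray
    edge_child: np.ndarray   # node index of each edge's child
    edge_parent: np.ndarray  # node index of each edge's parent
    b: np.ndarray            # observed branch lengths (substitutions)
    pair_child: np.ndarray   # edge indices for ancestor-descendant rate pairs
    pair_parent: np.ndarray
    root_edges: np.ndarray   # edge indices of the root's child edges


def _build_pl_problem(tree: dendropy.Tree, eps: float) -> _PLProblem:
    nodes = list(tree.preorder_node_iter())
    node_idx = {nd: i for i, nd in enumerate(nodes)}
    root = tree.seed_node
    edge_child, edge_parent, b = [], [], []
    edge_of_node = {}
    for nd in nodes:
        if nd is root:
            continue
        edge_of_node[nd] = len(edge_child)
        edge_child.append(node_idx[nd])
        edge_parent.append(node_idx[nd.parent_node])
        length = nd.edge.length if nd.edge.length is not None else 0.0
        if length <= 0:
            warnings.warn(
                f"zero-length branch floored at {eps}", stacklevel=3
            )
            length = eps
        b.append(length)
    pair_child, pair_parent = [], []
    for nd in nodes:
        if nd is root or nd.parent_node is root:
            continue
        pair_child.append(edge_of_node[nd])
        pair_parent.append(edge_of_node[nd.parent_node])
    root_edges = [edge_of_node[ch] for ch in root.child_nodes()]
    free = [
        (node_idx[nd], node_idx[nd.parent_node])
        for nd in nodes
        if nd is not root and not nd.is_leaf()
    ]
    leaf_indices = np.array([node_idx[nd] for nd in nodes if nd.is_leaf()])
    return _PLProblem(
        n_nodes=len(nodes),
        root_index=node_idx[root],
        preorder_free=free,
        leaf_indices=leaf_indices,
        edge_child=np.array(edge_child),
        edge_parent=np.array(edge_parent),
        b=np.array(b),
        pair_child=np.array(pair_child, dtype=int),
        pair_parent=np.array(pair_parent, dtype=int),
        root_edges=np.array(root_edges, dtype=int),
    )


def _pl_ages(prob: _PLProblem, u: np.ndarray) -> np.ndarray:
    age = np.zeros(prob.n_nodes)
    age[prob.root_index] = 1.0
    for k, (ni, pi) in enumerate(prob.preorder_free):
        age[ni] = age[pi] * expit(u[k])
    return age


def _pl_objective_value(prob: _PLProblem, age, log_r, smoothing):
    """Penalized log-likelihood (to be maximized)."""
    r = np.exp(log_r)
    t = np.maximum(age[prob.edge_parent] - age[prob.edge_child], 1e-12)
    loglik = float(np.sum(prob.b * np.log(r * t) - r * t))
    pen = float(np.sum((r[prob.pair_child] - r[prob.pair_parent]) ** 2))
    if prob.root_edges.size:
        pen += float(np.var(r[prob.root_edges]))
    return loglik - smoothing * pen


def ultrametricize_pl(
    tree: dendropy.Tree,
    smoothing: float = 0.1,
    eps: float = 1e-8,
) -> dendropy.Tree:
    """Convert a substitutions tree into a relative time tree.

    Node ages and per-edge rates maximize a Poisson branch-length
    log-likelihood minus ``smoothing`` times a roughness penalty (squared
    ancestor-descendant rate differences plus the variance of the rates on
    the root's edges).  The root age is fixed at 1 and tip ages at 0, so
    the output is ultrametric by construction and shares the input
    topology.

    The returned tree carries ``pl_objective`` (the achieved penalized
    log-likelihood) and ``pl_rates`` attributes for diagnostics.
    """
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise TreeError(
            "root has more than two children: tree appears unrooted; "
            "root it before rate smoothing"
        )
    work = tree.clone(depth=1)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_node_iter()):
        warnings.warn("polytomies resolved arbitrarily with zero-length branches")
        work.resolve_polytomies()
    prob = _build_pl_problem(work, eps)
    n_free = len(prob.preorder_free)
    n_edges = prob.b.size

    # init: node ages from relative leaf distances; one shared rate
    init_depth = {work.seed_node: 0.0}
    for nd in work.preorder_node_iter():
        if nd is not work.seed_node:
            init_depth[nd] = init_depth[nd.parent_node] + max(nd.edge.length or eps, eps)
    max_depth = max(init_depth[nd] for nd in work.leaf_node_iter())
    nodes = list(work.preorder_node_iter())
    age0 = {}
    for nd in reversed(nodes):  # postorder-ish: leaves first
        if nd.is_leaf():
            age0[nd] = 0.0
        else:
            # height above the deepest descendant leaf, in relative time
            h = max(age0[ch] + max(ch.edge.length or eps, eps) / max_depth
                    for ch in nd.child_nodes())
            age0[nd] = min(h, 0.999)
    age0[work.seed_node] = 1.0
    u0 = np.zeros(n_free)
    for k, (ni, pi) in enumerate(prob.preorder_free):
        ratio = age0[nodes[ni]] / max(age0[nodes[pi]], 1e-9)
        u0[k] = logit(np.clip(ratio, 0.05, 0.95))
    total_b = prob.b.sum()
    age_init = _pl_ages(prob, u0)
    total_t = np.maximum(age_init[prob.edge_parent] - age_init[prob.edge_child], 1e-12).sum()
    log_r0 = np.full(n_edges, math.log(max(total_b / total_t, 1e-9)))

    def neg_obj(x):
        u, log_r = x[:n_free], x[n_free:]
        age = _pl_ages(prob, u)
        return -_pl_objective_value(prob, age, log_r, smoothing)

    x0 = np.concatenate([u0, log_r0])
    res = optimize.minimize(
        neg_obj, x0, method="L-BFGS-B",
        options=dict(maxiter=2000, maxfun=200000, ftol=1e-14, gtol=1e-10),
    )
    # a second polish from the solution guards against early L-BFGS exits
    res2 = optimize.minimize(
        neg_obj, res.x, method="L-BFGS-B",
        options=dict(maxiter=2000, maxfun=200000, ftol=1e-15, gtol=1e-12),
    )
    if res2.fun < res.fun:
        res = res2
    u, log_r = res.x[:n_free], res.x[n_free:]
    age = _pl_ages(prob, u)
    for e in range(n_edges):
        child_node = nodes[prob.edge_child[e]]
        child_node.edge.length = float(age[prob.edge_parent[e]] - age[prob.edge_child[e]])
    work.pl_objective = float(-res.fun)
    work.pl_rates = np.exp(log_r)
    return work


# ---------------------------------------------------------------------------
# Phylogenetic signal

@dataclass(frozen=True)
class SignalEstimate:
    """Phylogenetic signal statistic (Pagel's lambda or Blomberg's K)."""

    statistic: float
    kind: str                 # "lambda" or "K"
    sigma2: float
    root_state: float
    log_likelihood: float
    p_value: float


def _lambda_profile_loglik_factory(C: np.ndarray, y: np.ndarray):
    """Return f(lam) -> (logL, sigma2_ML, root_state) profiled analytically.

    Uses a shared eigendecomposition when the diagonal of C is constant
    (ultrametric tree), which makes each evaluation O(n); otherwise falls
    back to a Cholesky factorization per lambda.
    """
    n = y.size
    diag = np.diag(C)
    ones = np.ones(n)
    if np.ptp(diag) <= 1e-9 * max(diag.max(), 1e-300):
        d = float(diag.mean())
        w, Q = np.linalg.eigh(C)
        yt = Q.T @ y
        ot = Q.T @ ones

        def f(lam):
            v = lam * w + (1.0 - lam) * d
            v = np.maximum(v, 1e-12)
            a = float(np.sum(ot * yt / v) / np.sum(ot * ot / v))
            resid = yt - a * ot
            s2 = float(np.sum(resid * resid / v) / n)
            s2 = max(s2, 1e-300)
            logl = -0.5 * (n * math.log(2 * math.pi * s2) + float(np.sum(np.log(v))) + n)
            return logl, s2, a

        return f

    def f(lam):
        V = lambda_transform(C, lam)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        z = np.linalg.solve(L, y)
        o = np.linalg.solve(L, ones)
        a = float(o @ z / (o @ o))
        resid = z - a * o
        s2 = max(float(resid @ resid) / n, 1e-300)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        logl = -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)
        return logl, s2, a

    return f


def fit_pagels_lambda(tree: dendropy.Tree, trait: dict, grid_size: int = 50) -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda on [0, 1] with an LR test vs 0.

    The trait is modeled as multivariate normal with covariance
    sigma2 * C(lambda); root state and sigma2 are profiled analytically.
    The p-value is a likelihood-ratio test of the ML lambda against
    lambda = 0 using a chi-square reference with 1 df (conservative at the
    boundary).
    """
    cov = phylo_vcv(tree, warn_non_ultrametric=False)
    y = _trait_vector(trait, cov.labels)
    if np.ptp(y) == 0:
        raise DataError("constant trait: lambda undefined")
    f = _lambda_profile_loglik_factory(cov.matrix, y)

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([f(l)[0] for l in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -f(l)[0], bounds=(lo, hi), method="bounded",
            options=dict(xatol=1e-8),
        )
        lam_hat = float(res.x)
        if f(lam_hat)[0] < vals[k]:
            lam_hat = float(grid[k])
    else:
        lam_hat = float(grid[k])
    logl_hat, s2, a = f(lam_hat)
    logl0 = f(0.0)[0]
    lr = max(2.0 * (logl_hat - logl0), 0.0)
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SignalEstimate(
        statistic=lam_hat, kind="lambda", sigma2=s2, root_state=a,
        log_likelihood=logl_hat, p_value=max(p, np.finfo(float).tiny),
    )


def _k_machinery(C: np.ndarray):
    n = C.shape[0]
    Ci = np.linalg.inv(C)
    w = Ci.sum(axis=0)            # 1' C^-1
    W = float(w.sum())            # 1' C^-1 1
    expected = (float(np.trace(C)) - n / W) / (n - 1)
    return Ci, w, W, expected


def _k_value(y: np.ndarray, Ci, w, W, expected) -> float:
    n = y.size
    a0 = float(w @ y) / W
    d = y - a0
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Ci @ d) / (n - 1)
    return (mse0 / mse) / expected


def blombergs_k(tree: dendropy.Tree, trait: dict) -> SignalEstimate:
    """Blomberg's K: observed MSE0/MSE ratio over its Brownian expectation.

    MSE0 is the mean squared deviation from the phylogenetically corrected
    mean; MSE is the covariance-whitened generalized mean square.  K has
    expectation ~1 under Brownian motion.  The p-value field is NaN here;
    use :func:`k_permutation_test` for the hypothesis test.
    """
    cov = phylo_vcv(tree, warn_non_ultrametric=False)
    y = _trait_vector(trait, cov.labels)
    if np.ptp(y) == 0:
        raise DataError("constant trait: K undefined")
    n = y.size
    Ci, w, W, expected = _k_machinery(cov.matrix)
    k = _k_value(y, Ci, w, W, expected)
    a0 = float(w @ y) / W
    d = y - a0
    s2 = float(d @ Ci @ d) / n
    sign, logdet = np.linalg.slogdet(cov.matrix)
    logl = -0.5 * (n * math.log(2 * math.pi * max(s2, 1e-300)) + logdet + n)
    return SignalEstimate(
        statistic=k, kind="K", sigma2=s2, root_state=a0,
        log_likelihood=logl, p_value=float("nan"),
    )


def k_permutation_test(
    tree: dendropy.Tree, trait: dict, n_perm: int = 999, seed=None
) -> float:
    """One-sided permutation p-value for Blomberg's K.

    Trait values are shuffled across tips; p = (1 + #{K_perm >= K_obs}) /
    (n_perm + 1).  Deterministic for a given seed.
    """
    if n_perm < 99:
        raise DataError(f"n_perm must be >= 99, got {n_perm}")
    cov = phylo_vcv(tree, warn_non_ultrametric=False)
    y = _trait_vector(trait, cov.labels)
    if np.ptp(y) == 0:
        raise DataError("constant trait: K undefined")
    Ci, w, W, expected = _k_machinery(cov.matrix)
    k_obs = _k_value(y, Ci, w, W, expected)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y.size) for _ in range(n_perm)])
    Y = y[perms]                                   # (n_perm, n)
    a0 = (Y @ w) / W
    D = Y - a0[:, None]
    mse0 = np.einsum("pi,pi->p", D, D)
    mse = np.einsum("pi,pi->p", D @ Ci, D)
    k_perm = (mse0 / mse) / expected
    return float((1 + int(np.sum(k_perm >= k_obs - 1e-12))) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Distance matrices and the Mantel test

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled distance matrix with zero diagonal."""

    labels: tuple
    matrix: np.ndarray
    units: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))
        if m.shape != (len(self.labels), len(self.labels)):
            raise DataError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(m < -1e-12):
            raise DataError("distances must be nonnegative")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))


_UNAMBIGUOUS = frozenset(b"ACGT")


def p_distance_matrix(sequences: dict) -> DistanceMatrix:
    """Pairwise proportion of differing nucleotide sites.

    Only positions where both sequences carry an unambiguous base
    (A, C, G, T; case-insensitive) are compared — gaps and ambiguity codes
    are treated as missing (pairwise deletion).

    Raises
    ------
    AlignmentError
        Unequal sequence lengths, or a pair with no comparable site.
    """
    labels = tuple(sequences)
    seqs = [str(sequences[l]).upper() for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"aligned sequences must have equal lengths, got {sorted(lengths)}")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(len(seqs), -1)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise AlignmentError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            diffs = int(np.sum(arr[i, both] != arr[j, both]))
            m[i, j] = m[j, i] = diffs / comparable
    return DistanceMatrix(labels=labels, matrix=m, units="substitution proportion")


def geographic_distance_matrix(coords: dict) -> DistanceMatrix:
    """Great-circle (haversine) distances in km, Earth radius 6371 km.

    ``coords`` maps label -> (latitude, longitude) in decimal degrees.
    """
    labels = tuple(coords)
    lat = np.radians([float(coords[l][0]) for l in labels])
    lon = np.radians([float(coords[l][1]) for l in labels])
    lat_deg = np.degrees(lat)
    lon_deg = np.degrees(lon)
    if np.any(np.abs(lat_deg) > 90 + 1e-9) or np.any(np.abs(lon_deg) > 180 + 1e-9):
        raise DataError("coordinates out of range: lat in [-90,90], lon in [-180,180]")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    m = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2
    return DistanceMatrix(labels=labels, matrix=m, units="km")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed=None,
) -> dict:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the
    one-sided (greater) p-value comes from simultaneous row/column
    permutations of the second matrix with the add-one correction.
    """
    if d1.labels != d2.labels:
        raise ConsistencyError(
            f"distance matrices must share labels in order: {d1.labels} vs {d2.labels}"
        )
    if n_perm < 99:
        raise DataError(f"n_perm must be >= 99, got {n_perm}")
    n = len(d1.labels)
    iu = np.triu_indices(n, k=1)
    a = d1.matrix[iu]
    b = d2.matrix[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("constant distance matrix: Mantel r undefined")
    r_obs = float(stats.pearsonr(a, b)[0])
    az = (a - a.mean()) / a.std()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = d2.matrix[np.ix_(perm, perm)][iu]
        r_perm = float(np.mean(az * (bp - bp.mean()) / bp.std()))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"r": r_obs, "p": float(p), "n_perm": n_perm}
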