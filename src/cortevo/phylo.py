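"""Phylogenetic comparative machinery for continuous traits.

Trait evolution along a calibrated ultrametric phylogeny is modelled as a
Gaussian process: Brownian motion (BM), Ornstein–Uhlenbeck (OU, selection
strength alpha toward an optimum theta), early burst (EB, exponent r), and a
scalar-OU model with optimum shifts on selected edges (scOU). All models are
fitted by maximum likelihood through phylogenetic GLS with the family's tip
covariance kernel; model selection uses a Generalized Information Criterion
(GIC) whose effective-parameter term stays valid for ridge-penalized
covariance estimates (the formula is documented at :func:`gic`).

Ancestral states are best linear unbiased predictions under the fitted
covariance, computed by joint Gaussian conditioning over tips and internal
nodes, so missing tip values are imputed in the same pass.

Trees are held as parent-pointer arrays with branch lengths in Myr; Newick
serialisation goes through dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

__all__ = [
    "PhyloTree", "TraitMatrix", "EvoModelFit",
    "simulate_traits", "fit_model", "fit_scou_shifts", "gic", "select_model",
    "make_ultrametric", "ancestral_states", "phylo_pca", "lineage_divergence",
]


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree as parent pointers; tips are nodes ``0..n_tips-1``.

    ``blen[i]`` is the length (Myr) of the edge above node i (0 at the root).
    """

    parent: np.ndarray
    blen: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        self._mrca_cache: dict = {}

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(ch[n])
        return out[::-1]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children())

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for n in self.postorder()[::-1]:  # preorder
            p = self.parent[n]
            if p >= 0:
                depth[n] = depth[p] + self.blen[n]
        return depth

    def tip_depth(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    def node_ages(self) -> np.ndarray:
        """Time before present (Myr), assuming contemporaneous tips."""
        d = self.node_depths()
        return self.tip_depth() - d

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.node_depths()[: self.n_tips]
        return bool(d.max() - d.min() <= tol * max(d.max(), 1e-12))

    def _ancestor_paths(self) -> list[list[int]]:
        paths = []
        for n in range(self.n_nodes):
            path = [n]
            while self.parent[path[-1]] >= 0:
                path.append(int(self.parent[path[-1]]))
            paths.append(path)
        return paths

    def mrca_depth_matrix(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Depth (from the root) of the MRCA of each node pair."""
        if nodes is None:
            nodes = np.arange(self.n_nodes)
        key = tuple(np.asarray(nodes).tolist())
        cached = self._mrca_cache.get(key)
        if cached is not None:
            return cached.copy()
        depth = self.node_depths()
        paths = self._ancestor_paths()
        sets = [set(paths[n]) for n in nodes]
        m = len(nodes)
        out = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                common = sets[i] & sets[j]
                t = max(depth[list(common)])
                out[i, j] = out[j, i] = t
        np.fill_diagonal(out, depth[nodes])
        self._mrca_cache[key] = out.copy()
        return out

    def edges(self) -> np.ndarray:
        """Child node ids of every edge (all non-root nodes)."""
        return np.flatnonzero(self.parent >= 0)

    def descendant_tips(self, node: int) -> np.ndarray:
        ch = self.children()
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n < self.n_tips:
                out.append(n)
            stack.extend(ch[n])
        return np.asarray(sorted(out), dtype=np.int64)

    # -- newick ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        nodes = list(dt.preorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        order = tips + internals
        index = {id(n): i for i, n in enumerate(order)}
        parent = np.full(len(order), -1, dtype=np.int64)
        blen = np.zeros(len(order))
        for n in order:
            i = index[id(n)]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                blen[i] = float(n.edge.length or 0.0)
        labels = [str(n.taxon.label) if n.taxon else f"tip{i}" for i, n in enumerate(tips)]
        return cls(parent, blen, labels)

    def to_newick(self) -> str:
        ch = self.children()

        def rec(n: int) -> str:
            if not ch[n]:
                name = self.tip_labels[n].replace(" ", "_")
                return f"{name}:{self.blen[n]:.10g}"
            inner = ",".join(rec(c) for c in ch[n])
            if self.parent[n] < 0:
                return f"({inner});"
            return f"({inner}):{self.blen[n]:.10g}"

        return rec(self.root)


@dataclass
class TraitMatrix:
    """Tips × traits with an optional missing-value mask (NaN = missing)."""

    values: np.ndarray
    tip_labels: list[str]
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.tip_labels):
            raise ValueError("one row per tip required")
        if self.trait_names is None:
            self.trait_names = [f"trait{i}" for i in range(self.values.shape[1])]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def aligned_to(self, tree: PhyloTree) -> np.ndarray:
        """Rows reordered to the tree's tip order."""
        pos = {l: i for i, l in enumerate(self.tip_labels)}
        missing = [l for l in tree.tip_labels if l not in pos]
        if missing:
            raise ValueError(f"tips without trait rows: {missing}")
        return self.values[[pos[l] for l in tree.tip_labels]]


@dataclass
class EvoModelFit:
    """A fitted trait-evolution model."""

    family: str                     # "BM" | "OU" | "EB" | "scOU_shift"
    sigma2: float                   # unit-kernel rate scale
    loglik: float
    n_tips: int
    n_traits: int
    alpha: float = 0.0
    eb_rate: float = 0.0
    root_state: np.ndarray | None = None
    trait_cov: np.ndarray | None = None   # R (p x p), rate-scaled
    shift_edges: list[int] = field(default_factory=list)
    shift_values: np.ndarray | None = None
    ridge: float = 0.0
    n_kernel_params: int = 0
    n_candidate_edges: int = 0

    @property
    def gic_value(self) -> float:
        return gic(self)


# ---------------------------------------------------------------------------
# Covariance kernels (unit rate)
# ---------------------------------------------------------------------------

def _kernel(tree: PhyloTree, family: str, alpha: float = 0.0, eb_rate: float = 0.0,
            nodes: np.ndarray | None = None) -> np.ndarray:
    """Unit-rate covariance kernel between the requested nodes.

    BM: shared path length t_ij. OU (root fixed at the optimum):
    ``exp(-a d_ij) (1 - exp(-2 a t_ij)) / (2a)`` with d_ij the patristic
    distance. EB: ``(exp(r t_ij) - 1) / r``.
    """
    if nodes is None:
        nodes = np.arange(tree.n_tips)
    t = tree.mrca_depth_matrix(nodes)
    depth = tree.node_depths()[nodes]
    if family == "BM" or (family == "OU" and alpha < 1e-10) or \
       (family == "EB" and abs(eb_rate) < 1e-12):
        return t.copy()
    if family == "OU":
        d = depth[:, None] + depth[None, :] - 2 * t
        return np.exp(-alpha * d) * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
    if family == "EB":
        return (np.exp(eb_rate * t) - 1.0) / eb_rate
    raise ValueError(f"unknown family {family!r}")


def _profile_loglik(K: np.ndarray, Y: np.ndarray, X: np.ndarray | None = None,
                    ridge: float = 0.0) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Matrix-normal profile log-likelihood with GLS mean and profiled R.

    Y is (n, p); X the (n, q) mean design (default a column of ones). The
    trait covariance R is profiled as ``Z' K^{-1} Z / n`` (optionally ridged
    toward a scaled identity); the kernel rate is absorbed into R.

    Returns (loglik, beta, R, logdetK).
    """
    n, p = Y.shape
    if X is None:
        X = np.ones((n, 1))
    jitter = 1e-10 * np.trace(K) / n
    Kc = K + jitter * np.eye(n)
    cho = np.linalg.cholesky(Kc)
    logdetK = 2 * np.sum(np.log(np.diag(cho)))
    Ki_Y = np.linalg.solve(Kc, Y)
    Ki_X = np.linalg.solve(Kc, X)
    XtKiX = X.T @ Ki_X
    # lstsq: collinear mean designs (e.g. sibling shift edges + intercept)
    # get the minimum-norm solution instead of raising
    beta, *_ = np.linalg.lstsq(XtKiX, X.T @ Ki_Y, rcond=None)
    Z = Y - X @ beta
    Ki_Z = np.linalg.solve(Kc, Z)
    S = Z.T @ Ki_Z / n
    if ridge > 0:
        target = (np.trace(S) / p) * np.eye(p)
        R = (n * S + ridge * target) / (n + ridge)
    else:
        R = S
    # floor keeps degenerate fits (zero residuals) finite and invertible
    jitter = max(float(np.trace(R)) / p, 0.0) * 1e-10 + 1e-30
    R = R + jitter * np.eye(p)
    sgn, logdetR = np.linalg.slogdet(R)
    if sgn <= 0:
        return -np.inf, beta, R, logdetK
    Ri = np.linalg.inv(R)
    quad = float(np.einsum("ip,pq,iq->", Ki_Z, Ri, Z))
    ll = -0.5 * (p * logdetK + n * logdetR + quad + n * p * np.log(2 * np.pi))
    return ll, beta, R, logdetK


def fit_model(tree: PhyloTree, traits: TraitMatrix, family: str,
              ridge: float = 0.0) -> EvoModelFit:
    """Maximum-likelihood fit of BM, OU, or EB to tip traits.

    The root state and rate are profiled out; OU's alpha (or EB's r) is found
    by bounded scalar search on the profile likelihood. Multivariate traits
    share the kernel; their covariance R is profiled (ridged when requested).
    """
    Y = traits.aligned_to(tree)
    obs = ~np.isnan(Y).any(axis=1)
    min_tips = 2 if family == "BM" else 3
    if obs.sum() < min_tips:
        raise ValueError(f"need at least {min_tips} fully observed tips for {family}")
    Yo = Y[obs]
    nodes = np.flatnonzero(obs)
    n, p = Yo.shape
    T = tree.tip_depth()

    def fit_at(par: float) -> tuple[float, dict]:
        if family == "BM":
            K = _kernel(tree, "BM", nodes=nodes)
        elif family == "OU":
            K = _kernel(tree, "OU", alpha=par, nodes=nodes)
        elif family == "EB":
            K = _kernel(tree, "EB", eb_rate=par, nodes=nodes)
        else:
            raise ValueError(f"unknown family {family!r}")
        try:
            ll, beta, R, _ = _profile_loglik(K, Yo, ridge=ridge)
        except np.linalg.LinAlgError:
            warnings.warn("singular kernel; ridge fallback")
            ll, beta, R, _ = _profile_loglik(K + 1e-6 * T * np.eye(n), Yo, ridge=max(ridge, 1.0))
        return ll, {"beta": beta, "R": R}

    if family == "BM":
        ll, aux = fit_at(0.0)
        alpha, eb_rate, nk = 0.0, 0.0, 0
    elif family == "OU":
        res = minimize_scalar(lambda a: -fit_at(np.exp(a))[0],
                              bounds=(np.log(1e-6 / T), np.log(50.0 / T)), method="bounded")
        alpha = float(np.exp(res.x))
        ll, aux = fit_at(alpha)
        ll0, aux0 = fit_at(0.0)
        if ll0 >= ll:  # BM boundary
            alpha, ll, aux = 0.0, ll0, aux0
        eb_rate, nk = 0.0, 1
    elif family == "EB":
        res = minimize_scalar(lambda r: -fit_at(r)[0],
                              bounds=(-10.0 / T, -1e-8 / T), method="bounded")
        eb_rate = float(res.x)
        ll, aux = fit_at(eb_rate)
        ll0, aux0 = fit_at(0.0)
        if ll0 >= ll:
            eb_rate, ll, aux = 0.0, ll0, aux0
        alpha, nk = 0.0, 1
    else:
        raise ValueError(f"unknown family {family!r}")

    R = aux["R"]
    sigma2 = float(np.trace(R) / p)
    return EvoModelFit(family=family, sigma2=sigma2, loglik=float(ll),
                       n_tips=int(n), n_traits=p, alpha=alpha, eb_rate=eb_rate,
                       root_state=aux["beta"][0], trait_cov=R, ridge=ridge,
                       n_kernel_params=nk)


# ---------------------------------------------------------------------------
# scOU with optimum shifts
# ---------------------------------------------------------------------------

def _shift_design(tree: PhyloTree, alpha: float, shift_edges: list[int],
                  nodes: np.ndarray) -> np.ndarray:
    """Mean design for OU optimum shifts: column e weights each node by how
    much of edge e's optimum change has pulled it in, ``exp(-a (T_i - b_e))
    - exp(-a (T_i - a_e))`` along the root path (1 minus decay for BM)."""
    depth = tree.node_depths()
    paths = tree._ancestor_paths()
    X = np.zeros((len(nodes), 1 + len(shift_edges)))
    X[:, 0] = 1.0
    for j, e in enumerate(shift_edges):
        a_e = depth[tree.parent[e]]
        b_e = depth[e]
        for i, node in enumerate(nodes):
            path = paths[node]
            if e not in path:
                continue
            Ti = depth[node]
            if alpha < 1e-10:
                X[i, 1 + j] = 1.0
            else:
                lo = min(b_e, Ti)
                X[i, 1 + j] = np.exp(-alpha * (Ti - lo)) - np.exp(-alpha * (Ti - a_e))
    return X


def fit_scou_shifts(tree: PhyloTree, traits: TraitMatrix, max_shifts: int = 4,
                    exhaustive: bool = False, ridge: float = 0.0) -> EvoModelFit:
    """Scalar-OU fit with automatic detection of optimum shifts on edges.

    A single alpha is shared by all traits. Shift edges are selected greedily:
    starting from the no-shift scOU fit, the edge whose optimum shift most
    increases the profile likelihood is added, up to `max_shifts`; the number
    of shifts is then chosen by GIC. ``exhaustive=True`` replaces the greedy
    search by full enumeration of shift subsets (only sensible on small
    trees; used as the oracle in tests).

    Requires an ultrametric tree.
    """
    if not tree.is_ultrametric(1e-6):
        raise ValueError("scOU is defined for ultrametric trees; apply make_ultrametric first")
    Y = traits.aligned_to(tree)
    obs = ~np.isnan(Y).any(axis=1)
    nodes = np.flatnonzero(obs)
    Yo = Y[obs]
    n, p = Yo.shape
    T = tree.tip_depth()
    cand_edges = [int(e) for e in tree.edges() if tree.descendant_tips(e).size >= 1]

    def fit_set(shift_edges: list[int]) -> EvoModelFit:
        def nll(loga: float) -> float:
            a = np.exp(loga)
            K = _kernel(tree, "OU", alpha=a, nodes=nodes)
            X = _shift_design(tree, a, shift_edges, nodes)
            ll, *_ = _profile_loglik(K, Yo, X=X, ridge=ridge)
            return -ll
        res = minimize_scalar(nll, bounds=(np.log(1e-4 / T), np.log(50.0 / T)),
                              method="bounded")
        a = float(np.exp(res.x))
        K = _kernel(tree, "OU", alpha=a, nodes=nodes)
        X = _shift_design(tree, a, shift_edges, nodes)
        ll, beta, R, _ = _profile_loglik(K, Yo, X=X, ridge=ridge)
        return EvoModelFit(family="scOU_shift", sigma2=float(np.trace(R) / p),
                           loglik=float(ll), n_tips=n, n_traits=p, alpha=a,
                           root_state=beta[0], trait_cov=R,
                           shift_edges=list(shift_edges),
                           shift_values=beta[1:] if len(shift_edges) else None,
                           ridge=ridge, n_kernel_params=1,
                           n_candidate_edges=len(cand_edges))

    if exhaustive:
        from itertools import combinations
        if len(cand_edges) > 14:
            raise ValueError("exhaustive search limited to trees with <= 14 edges")
        best = None
        for m in range(max_shifts + 1):
            for combo in combinations(cand_edges, m):
                f = fit_set(list(combo))
                if best is None or f.gic_value < best.gic_value:
                    best = f
        return best

    fits = [fit_set([])]
    current: list[int] = []
    for _ in range(max_shifts):
        best_f, best_e = None, None
        for e in cand_edges:
            if e in current:
                continue
            f = fit_set(current + [e])
            if best_f is None or f.loglik > best_f.loglik:
                best_f, best_e = f, e
        if best_f is None:
            break
        current = current + [best_e]
        fits.append(best_f)
    return min(fits, key=lambda f: f.gic_value)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _effective_cov_params(fit: EvoModelFit) -> float:
    """Trace-form effective dof of the (possibly ridged) trait covariance.

    With eigenvalues d_i of R and ridge strength g = ridge/n toward the
    scaled identity, each eigen-direction contributes the shrinkage weight
    ``w_i = d_i / (d_i + g * mean(d))``; the dof of the covariance block is
    ``sum_{i<=j} w_i w_j``, reducing to p(p+1)/2 when the ridge vanishes.
    """
    R = fit.trait_cov
    if R is None:
        return 1.0
    p = R.shape[0]
    d = np.maximum(np.linalg.eigvalsh(R), 0.0)
    if fit.ridge <= 0:
        w = np.ones(p)
    else:
        g = fit.ridge / max(fit.n_tips, 1)
        w = d / (d + g * max(d.mean(), 1e-300))
    return float(np.sum(np.triu(np.outer(w, w))))


def gic(fit: EvoModelFit) -> float:
    """Generalized Information Criterion ``-2 loglik + 2 df``.

    ``df`` counts the kernel parameters (alpha or r), the mean parameters
    (root state plus any shift vectors, p per regime column), and the
    trace-form effective dof of the trait covariance — a bias-correction
    that remains meaningful for ridge-penalized high-dimensional fits. A
    kernel parameter (alpha or r) is shared by all p traits, and its
    finite-sample score bias accumulates over traits; its bias-correction
    term is therefore taken as ``max(1, p/2)`` per kernel parameter rather
    than 1 (with one trait this reduces to the usual count; with p >> n it
    is what keeps a boundary parameter from soaking up p small per-trait
    likelihood gains). Each selected shift additionally contributes
    ``ln(E)`` effective parameters
    for its placement among the E candidate edges (an extended-BIC-style
    multiplicity correction: the shift position is itself estimated by
    search, so a flat +1 would underpenalize).
    """
    p = fit.n_traits
    n_mean_cols = 1 + len(fit.shift_edges)
    df = fit.n_kernel_params * max(1.0, p / 2.0) + n_mean_cols * p \
        + _effective_cov_params(fit)
    if fit.family == "scOU_shift" and fit.shift_edges:
        df += len(fit.shift_edges) * max(np.log(max(fit.n_candidate_edges, 2)), 1.0)
    return -2.0 * fit.loglik + 2.0 * df


def select_model(fits: list[EvoModelFit]) -> EvoModelFit:
    """argmin-GIC among fits of the same data."""
    return min(fits, key=lambda f: f.gic_value)


# ---------------------------------------------------------------------------
# Simulation, ultrametrization, ancestral states
# ---------------------------------------------------------------------------

def simulate_traits(tree: PhyloTree, family: str, params: dict, p: int = 1,
                    seed: int | np.random.Generator = 0,
                    root_state: float | np.ndarray = 0.0
                    ) -> tuple[TraitMatrix, np.ndarray]:
    """Simulate traits at ALL nodes by exact covariance sampling.

    ``params``: ``sigma2`` plus ``alpha`` (OU) or ``r`` (EB). Returns the
    tip TraitMatrix and the (n_nodes, p) array of true node states
    (reproducible from the seed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = float(params.get("sigma2", 1.0))
    alpha = float(params.get("alpha", 0.0))
    r = float(params.get("r", 0.0))
    nodes = np.arange(tree.n_nodes)
    K = sigma2 * _kernel(tree, family, alpha=alpha, eb_rate=r, nodes=nodes)
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("covariance kernel not positive semi-definite")
    A = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
    mu = np.broadcast_to(np.atleast_1d(root_state), (p,)).astype(float)
    states = mu[None, :] + A @ rng.standard_normal((tree.n_nodes, p))
    tips = states[: tree.n_tips]
    return TraitMatrix(tips.copy(), list(tree.tip_labels)), states


def make_ultrametric(tree: PhyloTree, fossil_tips: list[str] | None = None) -> PhyloTree:
    """Shift tip ages to the present by lengthening terminal branches.

    Tips listed in `fossil_tips` (default: every tip) are extended so all
    tips end at the maximum tip depth.
    """
    depths = tree.node_depths()
    T = depths[: tree.n_tips].max()
    blen = tree.blen.copy()
    which = range(tree.n_tips) if fossil_tips is None else \
        [tree.tip_labels.index(l) for l in fossil_tips]
    for i in which:
        blen[i] += T - depths[i]
    return PhyloTree(tree.parent.copy(), blen, list(tree.tip_labels))


def ancestral_states(tree: PhyloTree, traits: TraitMatrix, fit: EvoModelFit
                     ) -> tuple[np.ndarray, np.ndarray]:
    """BLUP of every node's state under the fitted model; missing tips imputed.

    Returns (states, variances), both (n_nodes, p). Observed tips are
    returned as-is with zero variance.
    """
    Y = traits.aligned_to(tree)
    p = Y.shape[1]
    nodes = np.arange(tree.n_nodes)
    K = _kernel(tree, fit.family if fit.family != "scOU_shift" else "OU",
                alpha=fit.alpha, eb_rate=fit.eb_rate, nodes=nodes)
    if fit.family == "scOU_shift":
        X_all = _shift_design(tree, fit.alpha, fit.shift_edges, nodes)
        beta = np.vstack([fit.root_state[None, :],
                          fit.shift_values if fit.shift_values is not None else
                          np.zeros((0, p))])
        mean_all = X_all @ beta
    else:
        mean_all = np.broadcast_to(fit.root_state, (tree.n_nodes, p)).copy()

    states = mean_all.copy()
    variances = np.zeros((tree.n_nodes, p))
    rate = fit.sigma2 if fit.n_traits == 1 else 1.0  # multivariate: R carries scale
    for t in range(p):
        obs = ~np.isnan(Y[:, t])
        if not obs.any():
            raise ValueError(f"trait {t}: all tips missing")
        oidx = np.flatnonzero(obs)
        Koo = K[np.ix_(oidx, oidx)] + 1e-10 * np.eye(len(oidx)) * max(K.max(), 1.0)
        Kno = K[:, oidx]
        resid = Y[oidx, t] - mean_all[oidx, t]
        sol = np.linalg.solve(Koo, resid)
        states[:, t] = mean_all[:, t] + Kno @ sol
        # conditional variance (per unit rate), scaled by the trait's rate
        scale = fit.trait_cov[t, t] if fit.trait_cov is not None and fit.n_traits > 1 \
            else fit.sigma2
        cvar = np.diag(K) - np.einsum("no,on->n", Kno, np.linalg.solve(Koo, Kno.T))
        variances[:, t] = np.maximum(cvar, 0.0) * scale
        states[oidx, t] = Y[oidx, t]
        variances[oidx, t] = 0.0
    return states, variances


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------

def phylo_pca(tree: PhyloTree, traits: TraitMatrix, ridge: float | None = None,
              n_grid: int = 10) -> dict:
    """L2-regularized phylogenetic PCA.

    The evolutionary trait covariance is estimated by penalized likelihood
    (ridge toward a scaled identity); when `ridge` is None the strength is
    chosen from a log-spaced grid by approximate leave-one-out
    cross-validation on the phylogenetically whitened residuals. Modes are
    the eigenvectors of the estimated covariance; scores are the projections
    of the phylogenetically centered tip data.
    """
    Y = traits.aligned_to(tree)
    if np.isnan(Y).any():
        raise ValueError("phylo_pca requires complete traits")
    n, p = Y.shape
    K = _kernel(tree, "BM") + 1e-10 * tree.tip_depth() * np.eye(n)
    cho = np.linalg.cholesky(K)
    ones = np.ones((n, 1))
    Ki_Y = np.linalg.solve(K, Y)
    Ki_1 = np.linalg.solve(K, ones)
    mu = (ones.T @ Ki_Y) / (ones.T @ Ki_1)
    Z = Y - ones @ mu
    Zw = np.linalg.solve(cho, Z)          # whitened residuals, iid rows under BM

    def cov_at(lam: float) -> np.ndarray:
        S = Zw.T @ Zw / n
        target = (np.trace(S) / p) * np.eye(p)
        return (n * S + lam * target) / (n + lam)

    if ridge is None:
        grid = np.r_[0.0, np.geomspace(1e-2, 1e3, n_grid - 1)]
        best_lam, best_score = None, np.inf
        for lam in grid:
            # approximate LOO: score row i under covariance fitted to the rest
            score = 0.0
            S_full = Zw.T @ Zw
            ok = True
            for i in range(n):
                zi = Zw[i]
                S_i = (S_full - np.outer(zi, zi)) / (n - 1)
                target = (np.trace(S_i) / p) * np.eye(p)
                R_i = ((n - 1) * S_i + lam * target) / (n - 1 + lam)
                sgn, logdet = np.linalg.slogdet(R_i)
                if sgn <= 0:
                    ok = False
                    break
                score += logdet + zi @ np.linalg.solve(R_i, zi)
            if ok and score < best_score:
                best_score, best_lam = score, lam
        if best_lam is None:
            raise RuntimeError("no ridge value produced a finite CV objective")
        ridge = float(best_lam)

    R = cov_at(ridge)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for c in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, c]))
        if evecs[j, c] < 0:
            evecs[:, c] = -evecs[:, c]
    scores = Z @ evecs
    return {"modes": evecs, "eigenvalues": evals, "scores": scores,
            "mean": mu.ravel(), "covariance": R, "ridge": ridge}


# ---------------------------------------------------------------------------
# Lineage divergence curves
# ---------------------------------------------------------------------------

def lineage_divergence(areasA: np.ndarray, timesA: np.ndarray,
                       areasB: np.ndarray, timesB: np.ndarray,
                       timepoints: np.ndarray,
                       covariate: np.ndarray | None = None) -> dict:
    """Divergence of per-element relative areas between two lineages.

    Each lineage's per-element relative areas (rows = its own timepoints)
    are linearly interpolated at the shared `timepoints`; divergence(t) is
    ``1 - Pearson r`` between the two lineages' element vectors. When a
    covariate sampled at the same timepoints is given, its Pearson
    correlation with the divergence curve is reported.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if len(timepoints) < 3:
        raise ValueError("need at least 3 shared timepoints")

    def interp(areas, times):
        areas = np.asarray(areas, float)
        times = np.asarray(times, float)
        order = np.argsort(times)
        areas, times = areas[order], times[order]
        out = np.empty((len(timepoints), areas.shape[1]))
        for j in range(areas.shape[1]):
            out[:, j] = np.interp(timepoints, times, areas[:, j])
        return out

    A = interp(areasA, timesA)
    B = interp(areasB, timesB)
    div = np.array([1.0 - pearsonr(A[i], B[i])[0] if np.std(A[i]) > 0 and np.std(B[i]) > 0
                    else 0.0 for i in range(len(timepoints))])
    out = {"timepoints": timepoints, "divergence": div}
    if covariate is not None:
        covariate = np.asarray(covariate, float)
        r, pval = pearsonr(div, covariate)
        out["covariate_r"] = float(r)
        out["covariate_p"] = float(pval)
    return out
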