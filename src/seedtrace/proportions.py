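"""Estimating observed clone proportions from bulk read counts.

For anatomical site k and mutation cluster j, the data are variant reads
A_kj, reference reads R_kj, and a variant-read probability omega_kj that
converts mutation cellular frequency to expected VAF (0.5 for a diploid
heterozygous autosomal SNV). Under a binomial read-count model,

    A_kj ~ Binom(A_kj + R_kj, omega_kj * F_kj),    F = U B,

where B (C x M) is the clone-by-mutation matrix implied by the clone tree
(B_cm = 1 iff cluster m lies on the root-to-c path) and U (K x C) holds the
fraction of site k composed of clone c, constrained to U >= 0 and row sums
<= 1. An L1 penalty promotes sparsity, since most entries of U are zero.

Two estimators are provided: the exact binomial likelihood, and a quadratic
(inverse-variance weighted least squares) approximation

    min_U || W ⊙ (F - U B) ||_F^2 + l1 * ||U||_1    s.t.  U 1 <= 1, U >= 0

with F the empirical frequencies (A/(A+R))/omega clipped to [0, 1] and W
the inverse variances of those frequency estimates. Both are solved by
proximal projected gradient descent; on the feasible set the L1 term is
linear, so the proximal step is an exact projection onto the capped simplex.

U is thresholded (strictly > 5% by default) into per-site clone presence
calls, which become witness nodes; leaf clones present nowhere are pruned
iteratively since they are not supported by the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clone_tree import CLONE, CloneTree, attach_witness_nodes

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 0.5
PRESENCE_THRESHOLD = 0.05
DEFAULT_L1 = 0.1
_WEIGHT_VAR_FLOOR = 1e-4


@dataclass
class ReadCountTable:
    """Variant/reference read counts per (site, mutation cluster)."""

    sites: List[str]
    clusters: List[str]
    var_reads: np.ndarray    # (K, M)
    ref_reads: np.ndarray    # (K, M)
    omega: np.ndarray        # (K, M), in (0, 1]

    def __post_init__(self) -> None:
        K, M = len(self.sites), len(self.clusters)
        for name in ("var_reads", "ref_reads", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (K, M):
                raise ValueError(f"{name} shape {arr.shape} != ({K}, {M})")
            setattr(self, name, arr)
        if (self.var_reads < 0).any() or (self.ref_reads < 0).any():
            raise ValueError("read counts must be nonnegative")
        if (self.omega <= 0).any() or (self.omega > 1).any():
            raise ValueError("omega must lie in (0, 1]")

    @property
    def depth(self) -> np.ndarray:
        return self.var_reads + self.ref_reads

    def empirical_frequencies(self) -> np.ndarray:
        """F = (A / (A+R)) / omega, clipped to [0, 1]; zero-depth cells -> 0."""
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, self.var_reads / np.maximum(depth, 1), 0.0)
        return np.clip(vaf / self.omega, 0.0, 1.0)

    def inverse_variance_weights(self) -> np.ndarray:
        """W_kj = 1 / Var[F_kj], pseudocount-stabilized; zero-depth cells get
        weight 0 (and are logged)."""
        depth = self.depth
        n = np.maximum(depth, 1)
        p = (self.var_reads + 0.5) / (n + 1.0)   # keeps variance positive at A=0
        var = p * (1 - p) / n / self.omega ** 2
        W = 1.0 / np.maximum(var, _WEIGHT_VAR_FLOOR / n)
        n_zero = int((depth == 0).sum())
        if n_zero:
            logger.warning("%d zero-depth (site, cluster) cells assigned zero weight",
                           n_zero)
        return np.where(depth > 0, W, 0.0)

    @classmethod
    def from_tsv(cls, path) -> "ReadCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"site": str, "cluster": str})
        required = {"site", "cluster", "var_reads", "ref_reads"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"read-count TSV missing columns: {sorted(missing)}")
        if "omega" not in df.columns:
            df["omega"] = DEFAULT_OMEGA
        sites = list(dict.fromkeys(df["site"]))        # first-appearance order
        clusters = list(dict.fromkeys(df["cluster"]))
        K, M = len(sites), len(clusters)
        A = np.zeros((K, M))
        R = np.zeros((K, M))
        om = np.full((K, M), DEFAULT_OMEGA)
        si = {s: i for i, s in enumerate(sites)}
        ci = {c: j for j, c in enumerate(clusters)}
        for row in df.itertuples():
            i, j = si[row.site], ci[row.cluster]
            A[i, j] = row.var_reads
            R[i, j] = row.ref_reads
            om[i, j] = row.omega
        return cls(sites, clusters, A, R, om)

    def to_tsv(self, path) -> None:
        rows = []
        for i, s in enumerate(self.sites):
            for j, c in enumerate(self.clusters):
                rows.append((s, c, int(self.var_reads[i, j]),
                             int(self.ref_reads[i, j]), self.omega[i, j]))
        pd.DataFrame(rows, columns=["site", "cluster", "var_reads",
                                    "ref_reads", "omega"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class CloneMutationMatrix:
    """B (C x M): clone c carries mutation cluster m iff m lies on its root path."""

    clones: List[str]
    clusters: List[str]
    B: np.ndarray

    def mutations_of(self, clone: str) -> frozenset:
        i = self.clones.index(clone)
        return frozenset(c for j, c in enumerate(self.clusters) if self.B[i, j])


def clone_mutation_matrix(tree: CloneTree,
                          edge_to_cluster: Mapping[Tuple[str, str], Sequence[str] | str],
                          clusters: Optional[Sequence[str]] = None,
                          root_clusters: Sequence[str] = (),
                          ) -> CloneMutationMatrix:
    """Build B from a map of clone-tree edges to mutation clusters.

    Each edge may carry zero or more clusters; a cluster appearing on more
    than one edge violates the infinite-sites assumption and raises.
    ``root_clusters`` are truncal: carried by the root clone and hence by
    every clone.
    """
    edge_clusters: Dict[Tuple[str, str], List[str]] = {}
    seen: Dict[str, Tuple[str, str]] = {}
    for m in root_clusters:
        seen[m] = ("<root>", "<root>")
    for edge, val in edge_to_cluster.items():
        cl = [val] if isinstance(val, str) else list(val)
        edge_clusters[tuple(edge)] = cl
        for m in cl:
            if m in seen:
                raise ValueError(
                    f"cluster {m!r} mapped to edges {seen[m]} and {tuple(edge)} "
                    "(infinite-sites violation)")
            seen[m] = tuple(edge)
    clones = tree.clone_nodes()
    if clusters is None:
        clusters = sorted(seen)
    clusters = list(clusters)
    ci = {m: j for j, m in enumerate(clusters)}
    B = np.zeros((len(clones), len(clusters)))
    for m in root_clusters:
        B[:, ci[m]] = 1.0
    for i, clone in enumerate(clones):
        path = tree.path_from_root(clone)
        for p, c in zip(path[:-1], path[1:]):
            for m in edge_clusters.get((p, c), []):
                B[i, ci[m]] = 1.0
    return CloneMutationMatrix(clones, clusters, B)


def _project_capped_simplex(V: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto {u >= 0, sum(u) <= 1}."""
    U = np.maximum(V, 0.0)
    over = U.sum(axis=1) > 1.0
    if np.any(over):
        for i in np.nonzero(over)[0]:
            U[i] = _project_simplex(V[i])
    return U

def _project_simplex(v: np.ndarray) -> np.ndarray:
    # Held-Wolfe-Crowder sort-based projection onto the unit simplex
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, len(v) + 1)
    rho = np.nonzero(u - css / idx > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class ObservedProportions:
    """U (K x C): fraction of each site composed of each clone."""

    sites: List[str]
    clones: List[str]
    U: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (len(self.sites), len(self.clones)):
            raise ValueError("U shape mismatch")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.U, index=self.sites, columns=self.clones)


def estimate_U_quadratic(reads: ReadCountTable, Bmat: CloneMutationMatrix,
                         l1_strength: float = DEFAULT_L1,
                         max_iter: int = 50000, tol: float = 1e-11,
                         ) -> ObservedProportions:
    """Weighted-least-squares clone proportions.

    Rows of U are independent, so each site is solved separately by monotone
    accelerated proximal gradient descent (projection onto the capped
    simplex; on that set the L1 penalty is linear, making the proximal step
    an exact projection). The inverse-variance weights span several orders
    of magnitude — zero-VAF cells are strongly constrained — so the step
    size uses each row's own curvature, 1 / lambda_max(B W_k^2 B^T).
    """
    F = reads.empirical_frequencies()
    W = reads.inverse_variance_weights()
    B = Bmat.B
    K, C = F.shape[0], B.shape[0]
    U = np.zeros((K, C))
    for k in range(K):
        w2 = W[k] ** 2
        f = F[k]
        H = (B * w2) @ B.T                       # curvature of row objective
        L = max(float(np.linalg.eigvalsh(H)[-1]), 1e-12)
        step = 1.0 / (2.0 * L)

        def obj(u: np.ndarray) -> float:
            r = f - u @ B
            return float(np.sum(w2 * r * r) + l1_strength * np.abs(u).sum())

        u = np.zeros(C)
        z = u.copy()
        t = 1.0
        prev_obj = obj(u)
        window_obj = prev_obj
        for it in range(1, max_iter + 1):
            grad = -2.0 * (w2 * (f - z @ B)) @ B.T + l1_strength
            u_new = _project_capped_simplex((z - step * grad)[None, :])[0]
            o = obj(u_new)
            if o > prev_obj:                     # function-value restart
                z, t = u_new, 1.0
            else:
                t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
                z = u_new + ((t - 1) / t_new) * (u_new - u)
                t = t_new
            u, prev_obj = u_new, o
            if it % 200 == 0:                    # windowed convergence check
                if window_obj - o < tol * max(1.0, abs(window_obj)):
                    break
                window_obj = o
        U[k] = u
    return ObservedProportions(reads.sites, Bmat.clones, U)


def estimate_U_binomial(reads: ReadCountTable, Bmat: CloneMutationMatrix,
                        l1_strength: float = DEFAULT_L1,
                        max_iter: int = 500) -> ObservedProportions:
    """Maximum-likelihood clone proportions under the exact binomial model.

    Initialized at the quadratic solution; ascends the L1-penalized binomial
    log-likelihood with backtracking projected gradient steps.
    """
    A, R, om = reads.var_reads, reads.ref_reads, reads.omega
    B = Bmat.B
    eps = 1e-9

    def penalized_ll(U: np.ndarray) -> float:
        F = np.clip(U @ B, 0.0, 1.0)
        p = np.clip(om * F, eps, 1 - eps)
        return float(np.sum(A * np.log(p) + R * np.log1p(-p))
                     - l1_strength * np.abs(U).sum())

    U = estimate_U_quadratic(reads, Bmat, l1_strength).U.copy()
    ll = penalized_ll(U)
    step = 1e-3 / max(A.max() + R.max(), 1.0)
    for _ in range(max_iter):
        F = np.clip(U @ B, eps, 1.0 - eps)
        p = np.clip(om * F, eps, 1 - eps)
        dF = A / F - R * om / (1 - p)
        grad = dF @ B.T - l1_strength
        improved = False
        for _ in range(30):
            U_new = _project_capped_simplex(U + step * grad)
            ll_new = penalized_ll(U_new)
            if ll_new > ll:
                U, ll = U_new, ll_new
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return ObservedProportions(reads.sites, Bmat.clones, U)


def call_presence(props: ObservedProportions, tree: CloneTree,
                  threshold: float = PRESENCE_THRESHOLD,
                  ) -> Tuple[pd.DataFrame, CloneTree]:
    """Threshold U into presence calls and prune unsupported leaf clones.

    A clone is present in a site iff its proportion there is strictly above
    ``threshold``. Leaf clones present in no site are removed from the tree;
    removal is iterated because it can expose new unsupported leaves.
    Returns the presence matrix (restricted to surviving clones) and the
    pruned tree.
    """
    presence = props.U > threshold
    keep = {c: presence[:, j].any() for j, c in enumerate(props.clones)}
    pruned = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(pruned.nodes()):
            if (pruned.node_kind.get(node, CLONE) == CLONE and node != pruned.root
                    and pruned.is_leaf(node) and not keep.get(node, True)):
                logger.info("pruning unsupported leaf clone %r", node)
                pruned.remove_leaf(node)
                changed = True
    surviving = [c for c in props.clones if c in set(pruned.nodes())]
    cols = [props.clones.index(c) for c in surviving]
    df = pd.DataFrame(presence[:, cols], index=props.sites, columns=surviving)
    return df, pruned


def presence_to_witness_tree(presence: pd.DataFrame, tree: CloneTree) -> CloneTree:
    """Attach witness leaves for every presence call (alternate entry point
    when a clone-presence matrix is supplied directly, e.g. from
    single-cell or lineage-tracing data)."""
    return attach_witness_nodes(tree, presence.to_numpy(dtype=bool),
                                list(presence.index), list(presence.columns))


def load_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)
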