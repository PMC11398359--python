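"""Stochastic search over vertex labelings of a clone tree.

The labeling problem is combinatorial: each of C tree nodes takes one of K
anatomical sites, with witness-node labels fixed by observation. The search
maximizes the evidence lower bound

    ELBO(q) = E_q[log p(U, T, V)] + H(q),

where the (unnormalized) log-joint is minus the weighted sum of the
parsimony metrics and metastasis-prior scores of a labeling, and H is the
entropy of a factorized categorical posterior over the unfixed columns.

Optimization follows the straight-through Gumbel-softmax estimator: per
column, Gumbel(0, 1) noise is added to the logits psi; the hard sample V is
the argmax while the relaxed sample nu is a tempered softmax of the same
perturbed logits. Forward evaluation uses V; gradients are taken as if V
were nu (the straight-through contract), which keeps the reported metrics
integer-exact while allowing gradient ascent on psi. The temperature tau is
annealed from a high value (exploration) to a small nonzero value where nu
approaches V and the gradient bias vanishes. Many chains with independent
initializations run in parallel (sample size proportional to K*C) to
capture multiple posterior modes, i.e. multiple migration histories.

Since the straight-through estimator only needs gradients of a multilinear
relaxed objective, those gradients are computed analytically here (softmax
Jacobians chained through the matrix forms of the metrics) and applied with
Adam; no autodiff framework is involved.

Additional machinery:

* **Polytomy resolution** — nodes with more than two children receive
  floor(children/2) zero-mutation "resolver" children; every original child
  may stay put or reattach under a resolver, a categorical choice optimized
  jointly with the labels. Resolvers that end up childless or do not
  improve the history are removed afterwards.
* **Optimal-subtree fixing** — after a first search round, maximal
  monochromatic subtrees (internally 0 migrations) are frozen and a second
  round re-optimizes only the remaining columns.
* **Minimum-migration guarantee** — when polytomy resolution is off, a
  unit-cost small-parsimony dynamic program (Fitch–Hartigan style) injects
  one provably minimum-migration labeling into the candidate pool, so the
  Pareto front always contains a minimum-m solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .clone_tree import (RESOLVER, CloneTree, MigrationHistory,
                         VertexLabeling, migration_edges_of)
from .parsimony import (MACHINA_RULE, ParsimonyModel, compute_metrics,
                        parsimony_score)
from .priors import (GeneticDistanceMatrix, OrganotropismVector,
                     genetic_distance_score, organotropism_score)

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Knobs of the labeling search.

    sample_size: number of parallel chains; None means min(sample_cap,
    sample_alpha * K * C). Iterations grow linearly with the number of
    clones. tau anneals exponentially from tau_start to tau_end.
    """

    sample_size: Optional[int] = None
    sample_cap: int = 1024
    sample_alpha: int = 16
    n_iter: Optional[int] = None
    iter_base: int = 80
    iter_per_clone: int = 4
    tau_start: float = 3.0
    tau_end: float = 0.01
    lr: float = 0.15
    seed: int = 0
    restarts: int = 1
    resolve_polytomies: bool = False
    fix_root_to_primary: bool = True
    comigration_rule: str = MACHINA_RULE
    soft_indicator_h: float = 0.5
    collect_fraction: float = 0.25   # tail fraction of iterations sampled
    max_candidates_per_run: int = 20000
    wide_weightings: bool = True     # pipeline also searches under equal weights

    def resolved_sample_size(self, K: int, C: int) -> int:
        if self.sample_size is not None:
            return max(1, self.sample_size)
        return int(min(self.sample_cap, max(16, self.sample_alpha * K * C)))

    def resolved_n_iter(self, C: int) -> int:
        if self.n_iter is not None:
            return self.n_iter
        return self.iter_base + self.iter_per_clone * C


# ---------------------------------------------------------------------------
# Problem setup


@dataclass
class _Problem:
    tree: CloneTree                      # working tree (resolvers included)
    base_tree: CloneTree                 # tree before polytomy augmentation
    sites: List[str]
    primary: str
    nodes: List[str]
    node_index: Dict[str, int]
    site_index: Dict[str, int]
    A0: np.ndarray                       # fixed adjacency (N, N)
    fixed_mask: np.ndarray               # (N,) bool: column not optimized
    fixed_labels: np.ndarray             # (N,) int site index, -1 if free
    edge_weight: np.ndarray              # (N, N): wm + w_gen * (-log D)
    neg_log_o: np.ndarray                # (K,) -log o, 0 where inapplicable
    movable: List[Tuple[int, List[int]]]  # (child index, option parent indices)
    model: ParsimonyModel


def _setup_problem(tree: CloneTree, primary: str, model: ParsimonyModel,
                   D: Optional[GeneticDistanceMatrix],
                   o: Optional[OrganotropismVector],
                   config: SearchConfig) -> _Problem:
    base = tree
    movable: List[Tuple[str, List[str]]] = []
    if config.resolve_polytomies:
        tree, movable = resolve_polytomies(tree)
    else:
        tree = tree.copy()
    sites = sorted({primary} | set(tree.witness_site.values()))
    nodes = tree.preorder()
    ni = {n: i for i, n in enumerate(nodes)}
    si = {s: i for i, s in enumerate(sites)}
    N, K = len(nodes), len(sites)
    movable_children = {c for c, _ in movable}
    A0 = np.zeros((N, N))
    for p, c in tree.edges():
        if c not in movable_children:
            A0[ni[p], ni[c]] = 1.0
    fixed_mask = np.zeros(N, dtype=bool)
    fixed_labels = np.full(N, -1, dtype=int)
    for w, site in tree.witness_site.items():
        fixed_mask[ni[w]] = True
        fixed_labels[ni[w]] = si[site]
    if config.fix_root_to_primary:
        fixed_mask[ni[tree.root]] = True
        fixed_labels[ni[tree.root]] = si[primary]
    if D is None:
        D = GeneticDistanceMatrix.from_tree(tree)
    edge_weight = np.full((N, N), model.wm)
    if model.w_gen > 0:
        for (p, c), d in D.distance.items():
            if p in ni and c in ni:
                edge_weight[ni[p], ni[c]] += model.w_gen * (-np.log(d))
    neg_log_o = np.zeros(K)
    if o is not None and model.w_org > 0:
        for s in sites:
            if s != primary:
                if s not in o.freq:
                    raise KeyError(f"site {s!r} missing from organotropism vector")
                neg_log_o[si[s]] = -np.log(o.freq[s])
    mov_idx = [(ni[c], [ni[p] for p in opts]) for c, opts in movable]
    return _Problem(tree=tree, base_tree=base, sites=sites, primary=primary,
                    nodes=nodes, node_index=ni, site_index=si, A0=A0,
                    fixed_mask=fixed_mask, fixed_labels=fixed_labels,
                    edge_weight=edge_weight, neg_log_o=neg_log_o,
                    movable=mov_idx, model=model)


# ---------------------------------------------------------------------------
# Polytomy resolution


def resolve_polytomies(tree: CloneTree) -> Tuple[CloneTree, List[Tuple[str, List[str]]]]:
    """Augment every polytomy with resolver nodes and reassignable children.

    For each node with more than two children, floor(children/2) resolver
    nodes (minimum 1) are added as its children with 0-mutation edges. Each
    original child may stay under the node or reattach under one of its
    resolvers; the returned list maps each such child to its candidate
    parents. The attachment choice is optimized jointly with the labels.
    """
    out = tree.copy()
    movable: List[Tuple[str, List[str]]] = []
    for node in tree.preorder():
        kids = list(tree.children.get(node, []))
        if len(kids) <= 2:
            continue
        r = max(1, len(kids) // 2)
        resolvers = []
        for t in range(r):
            rid = f"{node}__res{t}"
            out.add_leaf(node, rid, RESOLVER, 0)
            resolvers.append(rid)
        for c in kids:
            movable.append((c, [node] + resolvers))
    return out, movable


def _cleanup_resolvers(tree: CloneTree, labeling: Dict[str, str],
                       model: ParsimonyModel, rule: str) -> Tuple[CloneTree, Dict[str, str]]:
    """Drop childless resolvers, then greedily drop resolvers whose removal
    does not worsen the weighted parsimony score."""
    tree = tree.copy()
    labeling = dict(labeling)

    def drop(res: str) -> None:
        parent = tree.parent[res]
        for child in list(tree.children.get(res, [])):
            mc = tree.edge_mutation_count.pop((res, child), 0)
            tree.children[res].remove(child)
            tree.parent[child] = parent
            tree.children[parent].append(child)
            tree.edge_mutation_count[(parent, child)] = mc
        tree.remove_leaf(res)
        labeling.pop(res, None)

    for res in [n for n, k in tree.node_kind.items() if k == RESOLVER]:
        if tree.is_leaf(res):
            drop(res)
    resolvers = [n for n, k in tree.node_kind.items() if k == RESOLVER]
    if resolvers:
        lab = VertexLabeling(labeling)
        cur = parsimony_score(compute_metrics(tree, lab, rule), model)
        for res in resolvers:
            trial_tree = tree.copy()
            trial_lab = dict(labeling)
            t_parent = trial_tree.parent[res]
            for child in list(trial_tree.children.get(res, [])):
                mc = trial_tree.edge_mutation_count.pop((res, child), 0)
                trial_tree.children[res].remove(child)
                trial_tree.parent[child] = t_parent
                trial_tree.children[t_parent].append(child)
                trial_tree.edge_mutation_count[(t_parent, child)] = mc
            trial_tree.remove_leaf(res)
            trial_lab.pop(res, None)
            score = parsimony_score(
                compute_metrics(trial_tree, VertexLabeling(trial_lab), rule), model)
            if score <= cur:
                tree, labeling, cur = trial_tree, trial_lab, score
    return tree, labeling


# ---------------------------------------------------------------------------
# Minimum-migration guarantee (small-parsimony DP)


def guarantee_min_migrations(tree: CloneTree, primary: str,
                             fix_root: bool = True,
                             sites: Optional[Sequence[str]] = None) -> VertexLabeling:
    """One labeling achieving the global minimum number of migrations.

    Unit-cost small-parsimony dynamic programming over the site alphabet
    (the Fitch–Hartigan optimum): witness leaves are constrained to their
    observed site, other nodes are free, and the root may be pinned to the
    primary site. Ties are broken toward the parent's site, then by site
    order, so the result is deterministic.
    """
    if sites is None:
        sites = sorted({primary} | set(tree.witness_site.values()))
    sites = list(sites)
    K = len(sites)
    si = {s: i for i, s in enumerate(sites)}
    INF = float("inf")
    cost: Dict[str, np.ndarray] = {}
    order = tree.preorder()[::-1]      # children before parents
    for node in order:
        kids = tree.children.get(node, [])
        c = np.zeros(K)
        for ch in kids:
            # min over child label l of cost[l] + [l != k]
            child_cost = cost[ch]
            c += np.minimum(child_cost, child_cost.min() + 1.0)
        if node in tree.witness_site:
            mask = np.full(K, INF)
            mask[si[tree.witness_site[node]]] = 0.0
            c = c + mask
        cost[node] = c
    labeling: Dict[str, str] = {}
    root_cost = cost[tree.root]
    if fix_root:
        root_k = si[primary]
        if not np.isfinite(root_cost[root_k]):
            raise ValueError("root constrained to an infeasible site")
    else:
        root_k = int(np.argmin(root_cost))
    labeling[tree.root] = sites[root_k]
    stack = [(ch, root_k) for ch in tree.children.get(tree.root, [])]
    while stack:
        node, parent_k = stack.pop()
        c = cost[node]
        # keep the parent's site when it is among the minimizers of c + [k != parent]
        trans = c + 1.0
        trans[parent_k] = c[parent_k]
        k = int(np.argmin(trans))
        if trans[parent_k] == trans[k]:
            k = parent_k
        labeling[node] = sites[k]
        stack.extend((ch, k) for ch in tree.children.get(node, []))
    return VertexLabeling(labeling)


# ---------------------------------------------------------------------------
# ELBO (public, single-sample)


def elbo(labeling: VertexLabeling, tree: CloneTree, model: ParsimonyModel,
         D: Optional[GeneticDistanceMatrix] = None,
         o: Optional[OrganotropismVector] = None,
         primary: Optional[str] = None,
         psi: Optional[np.ndarray] = None,
         unfixed_columns: Optional[Sequence[int]] = None,
         rule: str = MACHINA_RULE) -> float:
    """ELBO of one hard labeling: minus its weighted score, plus the entropy
    of the factorized categorical posterior (0 if no logits are given)."""
    metrics = compute_metrics(tree, labeling, rule)
    score = parsimony_score(metrics, model)
    history = MigrationHistory(tree, labeling, *metrics,
                               migration_edges=migration_edges_of(tree, labeling))
    if D is not None and model.w_gen > 0:
        score += model.w_gen * genetic_distance_score(history, D)
    if o is not None and model.w_org > 0 and primary is not None:
        score += model.w_org * organotropism_score(history, o, primary)
    H = 0.0
    if psi is not None:
        cols = range(psi.shape[1]) if unfixed_columns is None else unfixed_columns
        for j in cols:
            p = _softmax(psi[:, j])
            H += float(-(p * np.log(np.maximum(p, 1e-30))).sum())
    return -score + H


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def gumbel_softmax_sample(psi: np.ndarray, tau: float,
                          rng: np.random.Generator,
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """One straight-through Gumbel-softmax draw from column logits.

    Perturbs each column of ``psi`` (K sites x C columns) with i.i.d.
    Gumbel(0, 1) noise; returns the hard one-hot sample V (argmax of the
    perturbed logits) and the relaxed sample nu (softmax of the perturbed
    logits at temperature ``tau``). As tau grows, nu approaches the
    column-uniform distribution; as tau -> 0+, nu approaches V. Forward
    evaluation uses V while gradients flow through nu.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    y = psi + rng.gumbel(size=psi.shape)
    hard = np.argmax(y, axis=0)
    V = np.zeros_like(psi)
    V[hard, np.arange(psi.shape[1])] = 1.0
    nu = _softmax(y / tau, axis=0)
    return V, nu


# ---------------------------------------------------------------------------
# The chain engine


class _Adam:
    def __init__(self, shape, lr):
        self.lr = np.float32(lr)
        self.m = np.zeros(shape, dtype=np.float32)
        self.v = np.zeros(shape, dtype=np.float32)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        """Return the update for gradient *ascent* on the ELBO."""
        self.t += 1
        self.m *= np.float32(0.9)
        self.m += np.float32(0.1) * grad
        self.v *= np.float32(0.999)
        self.v += np.float32(0.001) * grad * grad
        mhat = self.m / np.float32(1 - 0.9 ** self.t)
        vhat = self.v / np.float32(1 - 0.999 ** self.t)
        np.sqrt(vhat, out=vhat)
        vhat += np.float32(1e-8)
        mhat /= vhat
        return self.lr * mhat


@dataclass
class _ChainState:
    psi: np.ndarray          # (x, K, N)
    phi: Optional[np.ndarray]  # (x, n_mov, O) padded logits or None
    phi_mask: Optional[np.ndarray]
    fixed_mask: np.ndarray   # (x, N) bool
    fixed_labels: np.ndarray  # (x, N) int


def _init_state(problem: _Problem, x: int, rng: np.random.Generator,
                fixed_mask: Optional[np.ndarray] = None,
                fixed_labels: Optional[np.ndarray] = None) -> _ChainState:
    N, K = len(problem.nodes), len(problem.sites)
    psi = rng.uniform(0.0, 1.0, size=(x, K, N)).astype(np.float32)
    if fixed_mask is None:
        fixed_mask = np.broadcast_to(problem.fixed_mask, (x, N)).copy()
        fixed_labels = np.broadcast_to(problem.fixed_labels, (x, N)).copy()
    phi = phi_mask = None
    if problem.movable:
        O = max(len(opts) for _, opts in problem.movable)
        phi = rng.uniform(0.0, 1.0, size=(x, len(problem.movable), O)).astype(np.float32)
        phi_mask = np.zeros((len(problem.movable), O), dtype=bool)
        for i, (_, opts) in enumerate(problem.movable):
            phi_mask[i, len(opts):] = True
        phi = np.where(phi_mask, np.float32(-1e9), phi)
    return _ChainState(psi, phi, phi_mask, fixed_mask, fixed_labels)


def _soft_ind(x: np.ndarray, h: float) -> np.ndarray:
    return x / (x + h)


def _soft_ind_grad(x: np.ndarray, h: float) -> np.ndarray:
    return h / (x + h) ** 2


def _run_chains(problem: _Problem, state: _ChainState, config: SearchConfig,
                rng: np.random.Generator, n_iter: int,
                collector: Dict[bytes, Tuple[np.ndarray, Optional[np.ndarray]]],
                ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Anneal tau over n_iter straight-through Gumbel-softmax steps.

    Returns final hard labels (x, N) and hard attachment choices
    (x, n_mov) or None. Hard samples from the tail iterations are stored in
    ``collector`` keyed by their dedup bytes.
    """
    x, K, N = state.psi.shape
    w = problem.model
    h = config.soft_indicator_h
    prim = problem.site_index[problem.primary]
    eye_off = ~np.eye(K, dtype=bool)
    adam_psi = _Adam(state.psi.shape, config.lr)
    adam_phi = _Adam(state.phi.shape, config.lr) if state.phi is not None else None
    fixedL = state.fixed_labels
    fixedM = state.fixed_mask
    onehot_fixed = np.zeros((x, K, N), dtype=np.float32)
    xs = np.arange(x)[:, None]
    ns = np.arange(N)[None, :]
    safe_lab = np.where(fixedL >= 0, fixedL, 0)
    onehot_fixed[xs, safe_lab, ns] = 1.0
    onehot_fixed *= fixedM[:, None, :]
    collect_from = int(n_iter * (1 - config.collect_fraction))
    taus = (config.tau_start * (config.tau_end / config.tau_start) ** (
        np.arange(n_iter) / max(n_iter - 1, 1))).astype(np.float32)
    A0 = problem.A0.astype(np.float32)
    edge_weight = problem.edge_weight.astype(np.float32)
    neg_log_o = problem.neg_log_o.astype(np.float32)
    _csym = (A0 * edge_weight)
    _csym = (_csym + _csym.T).astype(np.float32)
    _a0t = np.ascontiguousarray(A0.T)
    hard_labels = None
    hard_attach = None
    for it in range(n_iter):
        tau = np.float32(taus[it])
        # --- sample
        y = state.psi + rng.gumbel(size=state.psi.shape).astype(np.float32)
        hard_labels = np.argmax(y, axis=1)                       # (x, N)
        hard_labels = np.where(fixedM, fixedL, hard_labels)
        V = np.zeros((x, K, N), dtype=np.float32)
        V[xs, hard_labels, ns] = np.float32(1.0)
        nu = _softmax(y / tau, axis=1)
        nu = np.where(fixedM[:, None, :], onehot_fixed, nu)
        if state.phi is not None:
            gphi = rng.gumbel(size=state.phi.shape).astype(np.float32)
            yphi = np.where(state.phi_mask, np.float32(-1e9), state.phi + gphi)
            hard_attach = np.argmax(yphi, axis=2)                # (x, n_mov)
            aphi = _softmax(yphi / tau, axis=2)
            A = np.broadcast_to(A0, (x, N, N)).copy()
            for i, (ci, opts) in enumerate(problem.movable):
                A[:, np.array(opts), ci] = np.float32(0.0)
                chosen = np.array(opts)[hard_attach[:, i]]
                A[np.arange(x), chosen, ci] = np.float32(1.0)
        else:
            A = None

        # --- collect hard candidates from the annealed tail
        if it >= collect_from and len(collector) < config.max_candidates_per_run:
            lab_bytes = hard_labels.astype(np.int16)
            att = hard_attach.astype(np.int16) if hard_attach is not None else None
            for b in range(x):
                key = lab_bytes[b].tobytes() + (att[b].tobytes() if att is not None else b"")
                if key not in collector:
                    collector[key] = (hard_labels[b].copy(),
                                      hard_attach[b].copy() if hard_attach is not None else None)

        # --- gradients of the loss at the hard point (straight-through)
        # edge terms: sum_e A_e * edge_weight_e * (1 - V_u . V_v)
        if A is None:
            gV_edge = -(V @ _csym)
            VA = V @ A0
            VAT = V @ _a0t
            P = VA @ V.transpose(0, 2, 1)
        else:
            Cmat = A * edge_weight                                   # (x, N, N)
            gV_edge = -(V @ Cmat + V @ Cmat.transpose(0, 2, 1))
            VA = V @ A
            VAT = V @ A.transpose(0, 2, 1)
            P = VA @ V.transpose(0, 2, 1)
        Poff = P * eye_off
        out_deg = Poff.sum(axis=2)                                    # (x, K)
        # dL/dP
        S = w.wc * _soft_ind_grad(Poff, h) * eye_off
        S += w.ws * _soft_ind_grad(out_deg, h)[:, :, None] * eye_off
        if neg_log_o.any():
            S[:, prim, :] += np.float32(w.w_org) * neg_log_o[None, :]
            S[:, prim, prim] = 0.0
        gV_P = S @ VAT + S.transpose(0, 2, 1) @ VA
        gV_loss = gV_edge + gV_P                                       # dLoss/dV

        # ELBO ascent: grad = -dLoss/dV, chained through softmax(y/tau)
        g = -gV_loss
        dot = (g * nu).sum(axis=1, keepdims=True)
        gy = nu * (g - dot) / tau
        # entropy term on the unperturbed logits
        p_psi = _softmax(state.psi, axis=1)
        logp = np.log(np.maximum(p_psi, 1e-30))
        Hcol = -(p_psi * logp).sum(axis=1, keepdims=True)
        g_ent = -p_psi * (logp + Hcol)
        grad_psi = gy + g_ent
        grad_psi = np.where(fixedM[:, None, :], 0.0, grad_psi)
        state.psi += adam_psi.step(grad_psi)

        if state.phi is not None:
            # dLoss/dA_{p,c} = edge_weight * (1 - V_p.V_c) + (V^T S V)_{p,c},
            # needed only at the movable entries
            gphi_loss = np.zeros_like(state.phi)
            for i, (ci, opts) in enumerate(problem.movable):
                po = np.array(opts)
                vc = V[:, :, ci]                                  # (x, K)
                vp = V[:, :, po]                                  # (x, K, P)
                svci = (S @ vc[:, :, None])[:, :, 0]              # (x, K)
                dot = (vp * vc[:, :, None]).sum(axis=1)           # (x, P)
                quad = (vp * svci[:, :, None]).sum(axis=1)
                gphi_loss[:, i, :len(opts)] = (
                    edge_weight[po, ci][None, :] * (1.0 - dot) + quad)
            ga = -gphi_loss
            dot_a = (ga * aphi).sum(axis=2, keepdims=True)
            gy_a = aphi * (ga - dot_a) / tau
            p_phi = _softmax(np.where(state.phi_mask, -1e9, state.phi), axis=2)
            logq = np.log(np.maximum(p_phi, 1e-30))
            Hq = -(p_phi * logq).sum(axis=2, keepdims=True)
            g_ent_a = -p_phi * (logq + Hq)
            grad_phi = np.where(state.phi_mask, 0.0, gy_a + g_ent_a)
            state.phi += adam_phi.step(grad_phi)
    return hard_labels, hard_attach


# ---------------------------------------------------------------------------
# Subtree fixing


def fix_optimal_subtrees(problem: _Problem, hard_labels: np.ndarray,
                         base_fixed_mask: np.ndarray,
                         base_fixed_labels: np.ndarray,
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Freeze maximal monochromatic subtrees of each chain's hard labeling.

    A subtree all of whose nodes (witness leaves included) share one label
    has 0 migrations, 0 comigrations, and 0 seeding sites internally, so no
    other labeling of it can be better; its columns are frozen for the
    second round. Only subtrees containing at least one edge are frozen.
    Returns per-chain (fixed_mask, fixed_labels).
    """
    tree, ni = problem.tree, problem.node_index
    x, N = hard_labels.shape
    fixed_mask = base_fixed_mask.copy()
    fixed_labels = base_fixed_labels.copy()
    post = tree.preorder()[::-1]
    kids_idx = {ni[n]: [ni[c] for c in tree.children.get(n, [])] for n in tree.nodes()}
    mono = np.zeros((x, N), dtype=bool)
    for n in post:
        i = ni[n]
        ks = kids_idx[i]
        if not ks:
            mono[:, i] = True
        else:
            ok = np.ones(x, dtype=bool)
            for k in ks:
                ok &= mono[:, k] & (hard_labels[:, k] == hard_labels[:, i])
            mono[:, i] = ok
    for n in tree.preorder():
        i = ni[n]
        parent_i = ni[tree.parent[n]] if n != tree.root else None
        is_max = mono[:, i] if parent_i is None else (mono[:, i] & ~mono[:, parent_i])
        has_edge = bool(kids_idx[i])
        if not has_edge:
            continue
        sub = [ni[m] for m in tree.subtree_nodes(n)]
        sel = is_max
        if sel.any():
            for j in sub:
                fixed_mask[sel, j] = True
                fixed_labels[sel, j] = hard_labels[sel, i]
    return fixed_mask, fixed_labels


# ---------------------------------------------------------------------------
# Search driver


def search(tree: CloneTree, primary: str, model: ParsimonyModel,
           D: Optional[GeneticDistanceMatrix] = None,
           o: Optional[OrganotropismVector] = None,
           config: Optional[SearchConfig] = None) -> List[MigrationHistory]:
    """Run the full two-round stochastic search; return deduplicated candidates.

    ``tree`` must already carry witness leaves. Hard samples from the
    annealed tail of every chain and restart are pooled and deduplicated by
    (labeling, resolved topology); the minimum-migration small-parsimony
    solution is injected when polytomy resolution is off. Candidates whose
    (m, c, s) is dominated within the pool are dropped — they can never
    reach the Pareto front — so the returned set is front-equivalent to the
    full pool.
    """
    config = config or SearchConfig()
    if config.resolve_polytomies:
        # per-candidate materialization is Python-side; keep the pool bounded
        config = replace(config, max_candidates_per_run=min(
            config.max_candidates_per_run, 2000))
    if D is None:
        D = GeneticDistanceMatrix.from_tree(tree)
    problem = _setup_problem(tree, primary, model, D, o, config)
    K, N = len(problem.sites), len(problem.nodes)
    C = len(problem.tree.clone_nodes())
    x = config.resolved_sample_size(K, C)
    n_iter = config.resolved_n_iter(C)
    seeds = np.random.SeedSequence(config.seed).spawn(config.restarts)
    collector: Dict[bytes, Tuple[np.ndarray, Optional[np.ndarray]]] = {}
    front_per_restart = []
    for r in range(config.restarts):
        rng = np.random.default_rng(seeds[r])
        state = _init_state(problem, x, rng)
        hard_labels, _ = _run_chains(problem, state, config, rng, n_iter, collector)
        # round 2: freeze optimal subtrees, re-search the remaining columns
        fm, fl = fix_optimal_subtrees(problem, hard_labels,
                                      state.fixed_mask, state.fixed_labels)
        if not fm.all():
            state2 = _init_state(problem, x, rng, fixed_mask=fm, fixed_labels=fl)
            if state.phi is not None:
                state2.phi = state.phi      # keep round-1 attachment posteriors warm
            hard_labels, _ = _run_chains(problem, state2, config, rng, n_iter,
                                         collector)
        want_trace = logger.isEnabledFor(logging.DEBUG) or config.restarts > 1
        if want_trace and not config.resolve_polytomies:
            # non-convergence is not an error: report the final score spread
            from .parsimony import edge_structures, metrics_batch
            _, ei, ea = edge_structures(problem.tree, problem.node_index)
            m, c, s = metrics_batch(hard_labels, ei, ea, len(problem.sites),
                                    config.comigration_rule)
            p = model.wm * m + model.wc * c + model.ws * s
            logger.debug("restart %d: final score spread min=%.2f "
                         "median=%.2f max=%.2f", r, p.min(),
                         float(np.median(p)), p.max())
            tuples = set(zip(m.tolist(), c.tolist(), s.tolist()))
            front_per_restart.append(
                {t for t in tuples
                 if not any(all(a <= b for a, b in zip(u, t)) and u != t
                            for u in tuples)})
    if len(front_per_restart) > 1:
        converged = front_per_restart[-1] <= set().union(*front_per_restart[:-1])
        logger.info("front %s across restarts (unchanged front is the "
                    "practical convergence criterion)",
                    "stable" if converged else "still growing")
    logger.info("search collected %d distinct hard samples", len(collector))

    histories: Dict[Tuple, MigrationHistory] = {}
    if not config.resolve_polytomies:
        # inject the guaranteed minimum-migration labeling into the pool
        fitch = guarantee_min_migrations(problem.tree, primary,
                                         fix_root=config.fix_root_to_primary,
                                         sites=problem.sites)
        flab = np.array([problem.site_index[fitch[n]] for n in problem.nodes])
        collector.setdefault(flab.astype(np.int16).tobytes(), (flab, None))
        # batch metrics, then materialize only candidates whose (m, c, s) is
        # not dominated within the pool (dominated ones cannot reach the front)
        from .parsimony import edge_structures, metrics_batch
        _, edge_index, edge_anc = edge_structures(problem.tree, problem.node_index)
        labels_all = np.stack([v[0] for v in collector.values()])
        K = len(problem.sites)
        m, c, s = metrics_batch(labels_all, edge_index, edge_anc, K,
                                config.comigration_rule)
        tuples = list(zip(m.tolist(), c.tolist(), s.tolist()))
        uniq = set(tuples)
        nondom = {t for t in uniq
                  if not any(all(a <= b for a, b in zip(u, t)) and u != t
                             for u in uniq)}
        for (labels, _), mcs in zip(collector.values(), tuples):
            if mcs not in nondom:
                continue
            lab_map = {n: problem.sites[labels[i]]
                       for i, n in enumerate(problem.nodes)}
            v = VertexLabeling(lab_map)
            hist = MigrationHistory(problem.tree, v, *mcs,
                                    migration_edges_of(problem.tree, v))
            histories.setdefault(hist.key(), hist)
    else:
        for labels, attach in collector.values():
            hist = _materialize(problem, labels, attach, config)
            histories.setdefault(hist.key(), hist)
    return list(histories.values())


def _materialize(problem: _Problem, labels: np.ndarray,
                 attach: Optional[np.ndarray], config: SearchConfig,
                 ) -> MigrationHistory:
    lab = {n: problem.sites[labels[i]] for i, n in enumerate(problem.nodes)}
    tree = problem.tree
    if attach is not None:
        tree = tree.copy()
        for i, (ci, opts) in enumerate(problem.movable):
            child = problem.nodes[ci]
            new_parent = problem.nodes[opts[attach[i]]]
            old_parent = tree.parent[child]
            if new_parent != old_parent:
                mc = tree.edge_mutation_count.pop((old_parent, child), 0)
                tree.children[old_parent].remove(child)
                tree.parent[child] = new_parent
                tree.children[new_parent].append(child)
                tree.edge_mutation_count[(new_parent, child)] = mc
        tree, lab = _cleanup_resolvers(tree, lab, problem.model,
                                       config.comigration_rule)
    return _history_from_labeling(tree, VertexLabeling(lab), config.comigration_rule)


def _history_from_labeling(tree: CloneTree, labeling: VertexLabeling,
                           rule: str) -> MigrationHistory:
    m, c, s = compute_metrics(tree, labeling, rule)
    return MigrationHistory(tree, labeling, m, c, s,
                            migration_edges=migration_edges_of(tree, labeling))


def refine_history(history: MigrationHistory, D: GeneticDistanceMatrix,
                   rule: str = MACHINA_RULE,
                   keep_root: bool = True) -> MigrationHistory:
    """Deterministic local refinement of a history within its metric class.

    Single free-node relabelings that keep (m, c, s) unchanged are accepted
    when they lexicographically decrease (genetic-distance score, canonical
    labeling key); nodes and sites are scanned in a fixed order, so
    stochastic-search results lying on the same plateau converge to the same
    representative. Used to make the reported top history reproducible
    across reruns with different seeds.
    """
    tree = history.tree
    lab = dict(history.labeling.site_of)
    sites = sorted(set(lab.values()))
    free = [n for n in tree.preorder()
            if n not in tree.witness_site and not (keep_root and n == tree.root)]
    base = history.metrics
    free_set = set(free)
    cur_h = history
    cur_gd = genetic_distance_score(history, D)
    cur_key = cur_h.labeling.key()

    def try_assign(assignment):
        nonlocal cur_h, cur_gd, cur_key
        saved = {n: lab[n] for n in assignment}
        lab.update(assignment)
        v = VertexLabeling(dict(lab))
        if compute_metrics(tree, v, rule) == base:
            h2 = _history_from_labeling(tree, v, rule)
            gd2 = genetic_distance_score(h2, D)
            if gd2 < cur_gd - 1e-12 or (gd2 <= cur_gd + 1e-12
                                        and h2.labeling.key() < cur_key):
                cur_h, cur_gd, cur_key = h2, gd2, h2.labeling.key()
                return True
        lab.update(saved)
        return False

    def blocks():
        # maximal connected components of free nodes sharing one label
        seen = set()
        out = []
        for n in free:
            if n in seen:
                continue
            comp, stack = [], [n]
            while stack:
                u = stack.pop()
                if u in seen or u not in free_set or lab[u] != lab[n]:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(tree.children.get(u, []))
                if u != tree.root:
                    stack.append(tree.parent[u])
            out.append(comp)
        return out

    improved = True
    while improved:
        improved = False
        for n in free:
            for s in sites:
                if s != lab[n] and try_assign({n: s}):
                    improved = True
        # block moves escape symmetric plateaus (e.g. an unobserved interior
        # block that can sit in either of two sites at identical cost)
        for comp in blocks():
            if len(comp) < 2:
                continue
            cur_site = lab[comp[0]]
            for s in sites:
                if s != cur_site and try_assign({n: s for n in comp}):
                    improved = True
                    break
    return cur_h


def dominance_polish(history: MigrationHistory, rule: str = MACHINA_RULE,
                     keep_root: bool = True, max_passes: int = 50,
                     ) -> MigrationHistory:
    """Greedy deterministic descent in the dominance order.

    All single free-node relabelings are scored in one batch; if any yields
    metrics dominating the current (m, c, s), the lexicographically best
    such move is applied and the scan repeats. Stochastic search can leave
    a front member one move away from a dominating labeling; this pass
    closes those gaps deterministically.
    """
    from .parsimony import edge_structures, metrics_batch

    tree = history.tree
    nodes = tree.preorder()
    ni = {n: i for i, n in enumerate(nodes)}
    _, edge_index, edge_anc = edge_structures(tree, ni)
    lab = dict(history.labeling.site_of)
    sites = sorted(set(lab.values()))
    si = {s: i for i, s in enumerate(sites)}
    K = len(sites)
    free = [ni[n] for n in nodes
            if n not in tree.witness_site and not (keep_root and n == tree.root)]
    cur = np.array([si[lab[n]] for n in nodes])
    base = history.metrics
    for _ in range(max_passes):
        variants = []
        moves = []
        for i in free:
            for k in range(K):
                if k == cur[i]:
                    continue
                v = cur.copy()
                v[i] = k
                variants.append(v)
                moves.append((i, k))
        if not variants:
            break
        m, c, s = metrics_batch(np.stack(variants), edge_index, edge_anc, K, rule)
        best = None
        for j, (i, k) in enumerate(moves):
            t = (int(m[j]), int(c[j]), int(s[j]))
            if all(a <= b for a, b in zip(t, base)) and t != base:
                cand = (t, i, k)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        base, i, k = best
        cur[i] = k
    lab = {n: sites[cur[ni[n]]] for n in nodes}
    return _history_from_labeling(tree, VertexLabeling(lab), rule)
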