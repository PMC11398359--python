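"""End-to-end per-patient inference: reads -> proportions -> labelings -> ranked front."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .calibrate import PatientFront
from .clone_tree import CloneTree, MigrationHistory, migration_graph_from_labeling
from .parsimony import ParsimonyModel
from .pareto import RankedSolution, pareto_filter, rank_front
from .priors import GeneticDistanceMatrix, OrganotropismVector
from .proportions import (CloneMutationMatrix, ReadCountTable, call_presence,
                          estimate_U_binomial, estimate_U_quadratic,
                          presence_to_witness_tree)
from .search import (SearchConfig, dominance_polish, refine_history,
                     search)

# Repository default ("pan-cancer") parsimony model: produced by calibrating
# on the packaged synthetic cohorts (scripts/acceptance.py recomputes the
# calibration); these are repository defaults, not published cohort values.
DEFAULT_MODEL = ParsimonyModel(wm=0.55, wc=0.27, ws=0.18)
DEFAULT_PRIOR_WEIGHT = 0.1


@dataclass
class PatientResult:
    patient: str
    witness_tree: CloneTree
    primary: str
    ranked: List[RankedSolution]
    U: Optional[pd.DataFrame] = None
    presence: Optional[pd.DataFrame] = None
    D: Optional[GeneticDistanceMatrix] = None

    @property
    def top(self) -> MigrationHistory:
        return self.ranked[0].history

    def front_summary(self) -> PatientFront:
        metrics = np.array([r.metrics for r in self.ranked])
        gd = np.array([r.genetic_distance for r in self.ranked])
        org = None
        if all(r.organotropism is not None for r in self.ranked):
            org = np.array([r.organotropism for r in self.ranked])
        return PatientFront(self.patient, metrics, gd, org)

    def top_migration_graph(self):
        return migration_graph_from_labeling(self.top.tree, self.top.labeling)


def evaluate_patient(tree: CloneTree, primary: str,
                     reads: Optional[ReadCountTable] = None,
                     B: Optional[CloneMutationMatrix] = None,
                     presence: Optional[pd.DataFrame] = None,
                     model: Optional[ParsimonyModel] = None,
                     o: Optional[OrganotropismVector] = None,
                     config: Optional[SearchConfig] = None,
                     estimator: str = "quadratic",
                     patient: str = "patient",
                     l1_strength: float = 0.1) -> PatientResult:
    """Infer and rank a patient's Pareto front of migration histories.

    Either ``reads`` + ``B`` (clone proportions are estimated and thresholded
    into witness nodes, unsupported leaf clones pruned) or a precomputed
    ``presence`` matrix (estimation skipped) must be supplied.
    """
    model = model or DEFAULT_MODEL
    config = config or SearchConfig()
    U_frame = None
    if presence is not None:
        witness_tree = presence_to_witness_tree(presence, tree)
    elif reads is not None:
        if B is None:
            raise ValueError("reads require a clone-mutation matrix B")
        est = estimate_U_quadratic if estimator == "quadratic" else estimate_U_binomial
        props = est(reads, B, l1_strength=l1_strength)
        presence, pruned = call_presence(props, tree)
        witness_tree = presence_to_witness_tree(presence, pruned)
        U_frame = props.as_frame()
    else:
        raise ValueError("either reads or a presence matrix is required")
    D = GeneticDistanceMatrix.from_tree(witness_tree)
    # wide search: explore under several parsimony weightings so that every
    # corner of the Pareto front is reachable, then pool the candidates
    w_gen = model.w_gen or DEFAULT_PRIOR_WEIGHT
    w_org = (model.w_org or DEFAULT_PRIOR_WEIGHT) if o is not None else 0.0
    weightings = [(model.wm, model.wc, model.ws)]
    if config.wide_weightings:
        weightings.append((1.0, 1.0, 1.0))
    candidates: Dict = {}
    for i, (wm, wc, ws) in enumerate(dict.fromkeys(weightings)):
        search_model = ParsimonyModel(wm, wc, ws, w_gen=w_gen, w_org=w_org)
        sub_config = replace(config, seed=config.seed + 7919 * i)
        for h in search(witness_tree, primary, search_model, D=D, o=o,
                        config=sub_config):
            candidates.setdefault(h.key(), h)
    front = pareto_filter(list(candidates.values()))
    # deterministic dominance polish: single-move descent from one
    # representative per metric tuple can reveal labelings that dominate the
    # sampled front; iterate until the tuple set is stable
    if not config.resolve_polytomies:
        for _ in range(3):
            changed = False
            for tup in {h.metrics for h in front}:
                rep = min((h for h in front if h.metrics == tup),
                          key=lambda h: h.labeling.key())
                polished = dominance_polish(rep, rule=config.comigration_rule,
                                            keep_root=config.fix_root_to_primary)
                if polished.metrics != tup and polished.key() not in candidates:
                    candidates[polished.key()] = polished
                    changed = True
            if not changed:
                break
            front = pareto_filter(list(candidates.values()))
    ranked = rank_front(front, model, D=D, o=o, primary=primary)
    # deterministic refinement of the reported top solution: descend to the
    # canonical (genetic-distance-minimal) member of its metric class so
    # reruns with different seeds report the same history
    refined = refine_history(ranked[0].history, D, rule=config.comigration_rule,
                             keep_root=config.fix_root_to_primary)
    if refined.labeling.key() != ranked[0].history.labeling.key():
        rest = [r.history for r in ranked[1:]
                if r.history.labeling.key() != refined.labeling.key()]
        ranked = rank_front([refined] + rest, model, D=D, o=o, primary=primary)
    return PatientResult(patient=patient, witness_tree=witness_tree,
                         primary=primary, ranked=ranked, U=U_frame,
                         presence=presence, D=D)
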