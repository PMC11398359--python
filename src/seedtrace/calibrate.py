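"""Cohort calibration of parsimony-metric weights.

Different cancer types favor different trade-offs among migrations,
comigrations, and seeding sites. Calibration fits cohort-specific weights
(wm, wc, ws) by making the distribution that the weighted parsimony score
induces over each patient's Pareto front match the distribution induced by
the metastasis priors (genetic distance, plus organotropism when site
labels permit). Concretely, per patient both scores are turned into softmin
distributions — the prior scores z-scored within the front to mix their
scales, the parsimony scores raw with the weights normalized to sum 1 (see
:func:`cross_entropy_loss` for why) — and the loss is the summed
cross-entropy from the prior distribution to the parsimony distribution,
minimized by projected gradient descent from equal weights.
Patients whose front has a single solution contribute nothing to the loss.

Fitted weights re-rank every patient's front ("maximum calibrated parsimony
solution"); stability of the resulting top choice is assessed by refitting
on bootstrap resamples of the informative patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .parsimony import ParsimonyModel

SOFTMIN_TEMPERATURE = 1.0
_EPS = 1e-8


@dataclass
class PatientFront:
    """Per-solution scores of one patient's Pareto front."""

    patient: str
    metrics: np.ndarray                 # (n_solutions, 3) int
    genetic: np.ndarray                 # (n_solutions,)
    organotropism: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.metrics = np.atleast_2d(np.asarray(self.metrics, dtype=float))
        self.genetic = np.asarray(self.genetic, dtype=float)
        if self.organotropism is not None:
            self.organotropism = np.asarray(self.organotropism, dtype=float)
        if len(self.metrics) == 0:
            raise ValueError(f"patient {self.patient}: empty front")

    @property
    def n(self) -> int:
        return len(self.metrics)

    def prior_scores(self) -> np.ndarray:
        """Combined prior score: z-scored genetic distance plus, when
        available, z-scored organotropism. Lower is better."""
        z = _zscore(self.genetic)
        if self.organotropism is not None:
            z = z + _zscore(self.organotropism)
        return z


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < _EPS:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _softmin(scores: np.ndarray, temperature: float = SOFTMIN_TEMPERATURE) -> np.ndarray:
    z = -scores / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def cross_entropy_loss(cohort: Sequence[PatientFront], w: np.ndarray) -> float:
    """Sum over multi-solution patients of CE(prior dist, parsimony dist).

    The parsimony distribution is a softmin of the raw weighted scores with
    the weights normalized to sum 1 (z-scoring them would collapse every
    two-solution front to the same +-1 pair and zero the gradient); the
    prior scores are z-scored within each front only to put genetic
    distance and organotropism on a common scale before combining.
    """
    wn = np.asarray(w, dtype=float)
    wn = wn / wn.sum()
    total = 0.0
    for pf in cohort:
        if pf.n < 2:
            continue
        q = _softmin(pf.metrics @ wn)
        prior = _softmin(pf.prior_scores())
        total += float(-(prior * np.log(np.maximum(q, 1e-30))).sum())
    return total


def calibrate_weights(cohort: Sequence[PatientFront],
                      init: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                      max_iter: int = 300, grad_tol: float = 1e-6,
                      ) -> ParsimonyModel:
    """Fit (wm, wc, ws) by gradient descent on the cross-entropy loss.

    Weights are kept nonnegative by projection and returned normalized to
    sum 1. If every front is a singleton the loss is constant and the
    initial weights are returned unchanged (with a warning logged).
    """
    import logging
    logger = logging.getLogger(__name__)
    informative = [pf for pf in cohort if pf.n > 1]
    w = np.asarray(init, dtype=float)
    if not informative:
        logger.warning("all fronts are singletons; weights unchanged")
        return ParsimonyModel(*(w / w.sum()))

    def loss(wv: np.ndarray) -> float:
        return cross_entropy_loss(informative, wv)

    def grad(wv: np.ndarray) -> np.ndarray:
        g = np.zeros(3)
        h = 1e-5
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            g[i] = (loss(wv + e) - loss(wv - e)) / (2 * h)
        return g

    cur = loss(w)
    step = 0.5
    for _ in range(max_iter):
        g = grad(w)
        if np.linalg.norm(g) < grad_tol:
            break
        improved = False
        for _ in range(40):
            w_new = np.maximum(w - step * g, 1e-6)
            val = loss(w_new)
            if val < cur - 1e-12:
                w, cur = w_new, val
                step *= 1.4
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    w = w / w.sum()
    return ParsimonyModel(*w)


def rank_order(pf: PatientFront, model: ParsimonyModel) -> np.ndarray:
    """Indices of a front ordered by calibrated parsimony, priors as
    tie-breakers, solution index last (deterministic)."""
    w = np.array([model.wm, model.wc, model.ws])
    p = pf.metrics @ w
    gd = pf.genetic
    org = pf.organotropism if pf.organotropism is not None else np.zeros(pf.n)
    keys = list(zip(np.round(p, 9), np.round(gd, 9), np.round(org, 9), range(pf.n)))
    return np.array(sorted(range(pf.n), key=lambda i: keys[i]))


def rescore_cohort(cohort: Sequence[PatientFront], model: ParsimonyModel,
                   ) -> Dict[str, np.ndarray]:
    """Per-patient solution ordering under the fitted weights."""
    return {pf.patient: rank_order(pf, model) for pf in cohort}


def bootstrap_stability(cohort: Sequence[PatientFront], B: int = 100,
                        rng: Optional[np.random.Generator] = None,
                        init: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                        ) -> Tuple[Dict[str, float], float]:
    """Fraction of bootstrap refits in which each patient keeps its top solution.

    Patients with singleton fronts are excluded from resampling (they carry
    no gradient) but every patient is re-ranked under each refit. Returns
    (per-patient agreement fraction, cohort mean).
    """
    rng = rng or np.random.default_rng(0)
    subset = [pf for pf in cohort if pf.n > 1]
    if not subset:
        raise ValueError("no patients with multi-solution fronts to bootstrap")
    full = calibrate_weights(cohort, init=init)
    reference = {pf.patient: rank_order(pf, full)[0] for pf in cohort}
    agree = {pf.patient: 0 for pf in cohort}
    for _ in range(B):
        sample = [subset[i] for i in rng.integers(0, len(subset), len(subset))]
        model = calibrate_weights(sample, init=init)
        for pf in cohort:
            if rank_order(pf, model)[0] == reference[pf.patient]:
                agree[pf.patient] += 1
    frac = {k: v / B for k, v in agree.items()}
    return frac, float(np.mean(list(frac.values())))
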