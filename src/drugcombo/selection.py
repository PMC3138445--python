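"""Ranking, clustering, mixture analysis and conditional slices.

These are pure selections over a :class:`~drugcombo.performance.PerformanceMap`
— none of them recompute or alter scores.  A *mixture* is a subset of the
drug panel; its combinations are the grid rows in which every non-member
drug sits at zero concentration, so nesting a mixture inside a larger one
can only enlarge the candidate set and the best achievable score is
monotone in mixture inclusion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ClusterCountError, MixtureRestrictionError
from .models import FittedResponseModel
from .performance import PerformanceMap


def rank_combinations(pmap: PerformanceMap, top_k: int) -> list[tuple[np.ndarray, float]]:
    """Top combinations by descending score; ties keep canonical grid order."""
    if top_k > len(pmap):
        raise ValueError(f"top_k {top_k} exceeds grid size {len(pmap)}")
    # stable sort on -score preserves grid order within ties
    order = np.argsort(-pmap.score, kind="stable")[:top_k]
    return [(pmap.grid.conc[i], float(pmap.score[i])) for i in order]


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignment: np.ndarray = field(repr=False)
    centers: np.ndarray
    seed: int


def kmeans_scores(scores: np.ndarray, k: int, seed: int) -> ClusterResult:
    """1-D k-means over performance scores.

    k-means++ initialization with 10 restarts; cluster ids are relabeled
    1..k in ascending order of center so that id k is always the
    best-performing group.
    """
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= len(scores):
        raise ClusterCountError(f"k={k} outside 1..{len(scores)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterResult(
        k=k, assignment=relabel[km.labels_], centers=np.sort(centers), seed=seed
    )


@dataclass(frozen=True)
class MixtureEntry:
    """Best/worst performance of one drug subset (others held at zero)."""

    drugs: tuple[int, ...]
    best_combination: np.ndarray
    best_score: float
    worst_score: float
    best_predicted_nc: float
    best_predicted_cc: float


@dataclass(frozen=True)
class MixtureReport:
    """One entry per non-empty drug subset, in subset canonical order."""

    entries: tuple[MixtureEntry, ...]

    def entry(self, drugs: tuple[int, ...]) -> MixtureEntry:
        key = tuple(sorted(drugs))
        for e in self.entries:
            if e.drugs == key:
                return e
        raise KeyError(f"no mixture entry for {key}")


def mixture_analysis(pmap: PerformanceMap) -> MixtureReport:
    """Best and worst achievable score for every non-empty drug mixture.

    Requires a map over the full factorial grid.  For each subset S, the
    restriction keeps grid rows with zero concentration for every drug
    outside S (the all-zero row is therefore in every restriction); a drug
    without a zero level makes proper restrictions empty and raises.
    """
    panel = pmap.grid.panel
    n = panel.n_drugs
    conc = pmap.grid.conc
    zero = conc == 0.0
    entries = []
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            outside = [d for d in range(n) if d not in subset]
            mask = zero[:, outside].all(axis=1) if outside else np.ones(len(conc), bool)
            rows = np.flatnonzero(mask)
            if len(rows) == 0:
                missing = [panel.drugs[d] for d in outside if 0.0 not in panel.levels[d]]
                raise MixtureRestrictionError(
                    f"mixture {subset} restriction empty; drugs without a zero level: {missing}"
                )
            s = pmap.score[rows]
            best_local = rows[np.argmax(s)]  # argmax keeps lowest index on ties
            entries.append(
                MixtureEntry(
                    drugs=subset,
                    best_combination=conc[best_local],
                    best_score=float(pmap.score[best_local]),
                    worst_score=float(s.min()),
                    best_predicted_nc=float(pmap.predicted_nc[best_local]),
                    best_predicted_cc=float(pmap.predicted_cc[best_local]),
                )
            )
    return MixtureReport(entries=tuple(entries))


def conditional_curve(
    model: FittedResponseModel, vary: int, fixed: np.ndarray, levels: np.ndarray
) -> list[tuple[float, float]]:
    """Predicted response along one drug's levels with the others held fixed."""
    fixed = np.asarray(fixed, dtype=float)
    out = []
    for lv in np.asarray(levels, dtype=float):
        combo = fixed.copy()
        combo[vary] = lv
        out.append((float(lv), float(model.predict(combo))))
    return out


def conditional_surface(
    model: FittedResponseModel,
    vary_pair: tuple[int, int],
    fixed: np.ndarray,
    levels_a: np.ndarray,
    levels_b: np.ndarray,
) -> np.ndarray:
    """Predicted response over the product of two drugs' levels, others fixed.

    Returns an array of shape (len(levels_a), len(levels_b)).
    """
    fixed = np.asarray(fixed, dtype=float)
    a, b = vary_pair
    surf = np.empty((len(levels_a), len(levels_b)))
    for i, la in enumerate(np.asarray(levels_a, dtype=float)):
        for j, lb in enumerate(np.asarray(levels_b, dtype=float)):
            combo = fixed.copy()
            combo[a], combo[b] = la, lb
            surf[i, j] = model.predict(combo)
    return surf
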