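"""System-level drug-drug interaction inference by exhaustive best-subset OLS.

The response of each cell type is regressed on the 15 interaction regressors
of the 4-drug full-interaction basis — the four scaled concentrations, six
pairwise products, four three-drug products and the single four-drug product.
Every non-empty regressor subset (2^15 - 1 = 32767 models for p = 15) is fit
by OLS with intercept; for each model size the minimum-RSS subset is kept.
A model size is then chosen by an elbow rule on the RSS curve, and the
selected terms of two cell types are partitioned into cell-type-specific and
common interactions with their coefficient signs.

The search precomputes the augmented Gram matrix once and solves a tiny
normal-equation system per subset, so the full p = 15 enumeration runs in
seconds on one CPU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import RankError, RegressorCountError
from .models import InputScaler, lr_regressors, lr_subsets
from .simulate import ResponseTable

__all__ = [
    "term_names",
    "build_interaction_design",
    "SubsetRegressionResult",
    "best_subset_regression",
    "select_model_size",
    "InteractionClassification",
    "classify_interactions",
]


def term_names(drugs: tuple[str, ...]) -> list[str]:
    """Human-readable names of the full-interaction regressors, canonical order."""
    return ["*".join(drugs[i] for i in s) for s in lr_subsets(len(drugs))]


def build_interaction_design(
    table: ResponseTable,
    cell_line: str,
    scaler: InputScaler | None = None,
    allow_any_n: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Regressor matrix X (rows x 15) and response vector y for one cell line.

    Columns follow the canonical subset order shared with the
    full-interaction model family.  By default the panel must have exactly
    4 drugs (15 regressors); pass ``allow_any_n`` to build the 2^n - 1
    column design for other panel sizes.
    """
    n = table.panel.n_drugs
    if n != 4 and not allow_any_n:
        raise RegressorCountError(
            f"interaction design expects a 4-drug panel (15 regressors); got {n} drugs"
        )
    if scaler is None:
        scaler = InputScaler.from_panel(table.panel)
    X = lr_regressors(scaler.scale(table.conc))
    y = np.asarray(table.responses[cell_line], dtype=float)
    return X, y


@dataclass(frozen=True)
class SubsetRegressionResult:
    """Best subset per model size from an exhaustive all-subsets search.

    ``subsets[s]``, ``rss[s]`` and ``coefs[s]`` describe the minimum-RSS
    model with exactly ``s`` regressors (1-based keys); coefficient vectors
    are ordered (intercept, then the subset's regressors in canonical
    order).  ``n_models_examined`` counts every candidate subset.
    """

    p: int
    subsets: dict[int, tuple[int, ...]] = field(repr=False)
    rss: dict[int, float] = field(repr=False)
    coefs: dict[int, np.ndarray] = field(repr=False)
    n_models_examined: int = 0

    def selected_terms(self, size: int) -> dict[int, float]:
        """Map regressor index -> coefficient for the best model of ``size``."""
        beta = self.coefs[size]
        return {j: float(beta[i + 1]) for i, j in enumerate(self.subsets[size])}


def best_subset_regression(X: np.ndarray, y: np.ndarray) -> SubsetRegressionResult:
    """Exhaustive minimum-RSS subset per model size (OLS with intercept).

    Examines all 2^p - 1 non-empty column subsets.  Ties are broken by
    lexicographic subset order (the first minimum encountered wins).
    Rank-deficient subsets are skipped; if every subset of some size is
    rank deficient that size is absent from the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    if m <= p + 1:
        raise RankError(f"best-subset search needs more than p+1={p + 1} rows, got {m}")
    A = np.column_stack([np.ones(m), X])
    G = A.T @ A
    b = A.T @ y
    yty = float(y @ y)

    subsets: dict[int, tuple[int, ...]] = {}
    rss: dict[int, float] = {}
    coefs: dict[int, np.ndarray] = {}
    examined = 0
    for size in range(1, p + 1):
        best_rss = np.inf
        best_subset = None
        best_beta = None
        for subset in itertools.combinations(range(p), size):
            examined += 1
            idx = np.concatenate(([0], np.asarray(subset) + 1))
            Gs = G[np.ix_(idx, idx)]
            bs = b[idx]
            try:
                c, low = _cho_factor(Gs)
            except np.linalg.LinAlgError:
                continue  # rank deficient; skip with this subset unavailable
            beta = _cho_solve(c, low, bs)
            r = yty - float(bs @ beta)
            if r < best_rss - 1e-14:
                best_rss = r
                best_subset = subset
                best_beta = beta
        if best_subset is not None:
            subsets[size] = best_subset
            rss[size] = max(best_rss, 0.0)
            coefs[size] = best_beta
    return SubsetRegressionResult(
        p=p, subsets=subsets, rss=rss, coefs=coefs, n_models_examined=examined
    )


def _cho_factor(Gs: np.ndarray):
    # thin wrappers so scipy stays an optional micro-optimization point
    return np.linalg.cholesky(Gs), True


def _cho_solve(c: np.ndarray, low: bool, bs: np.ndarray) -> np.ndarray:
    z = np.linalg.solve(c, bs)  # small triangular systems; plain solve is fine
    return np.linalg.solve(c.T, z)


def select_model_size(result: SubsetRegressionResult, tau: float = 0.01) -> int:
    """Elbow rule: smallest size after which RSS stops improving meaningfully.

    Returns the smallest available size ``s`` such that for every larger
    available size ``s'``, ``(RSS(s) - RSS(s')) / RSS(s) < tau``.  A size
    with RSS exactly 0 (perfect fit) is returned immediately.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    sizes = sorted(result.rss)
    for s in sizes:
        if result.rss[s] == 0.0:
            return s
        if all(
            (result.rss[s] - result.rss[t]) / result.rss[s] < tau
            for t in sizes
            if t > s
        ):
            return s
    raise RuntimeError("unreachable: the largest size always satisfies the rule")


@dataclass(frozen=True)
class InteractionClassification:
    """Partition of two cell types' selected terms, with per-type signs.

    ``signs_a``/``signs_b`` map regressor index -> +1/-1 for the terms
    selected in each cell type; the three partitions are disjoint and cover
    the union of the two selected sets.
    """

    a_only: tuple[int, ...]
    b_only: tuple[int, ...]
    common: tuple[int, ...]
    signs_a: dict[int, int]
    signs_b: dict[int, int]


def classify_interactions(
    terms_a: dict[int, float], terms_b: dict[int, float]
) -> InteractionClassification:
    """Partition selected terms into A-only / B-only / common with signs.

    Inputs are regressor-index -> coefficient maps (as returned by
    :meth:`SubsetRegressionResult.selected_terms`) built over the same
    canonical regressor ordering.
    """
    set_a, set_b = set(terms_a), set(terms_b)
    return InteractionClassification(
        a_only=tuple(sorted(set_a - set_b)),
        b_only=tuple(sorted(set_b - set_a)),
        common=tuple(sorted(set_a & set_b)),
        signs_a={j: int(np.sign(c)) for j, c in terms_a.items()},
        signs_b={j: int(np.sign(c)) for j, c in terms_b.items()},
    )
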