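"""Response-surface model families for factorial drug-combination data.

Four families map a concentration vector to a predicted normalized response:

* ``LR_FULL_INTERACTION`` — linear regression on all non-empty subset
  products of the (unit-scaled) concentrations: singletons, pairwise,
  ... up to the full n-wise product (2^n - 1 regressors plus intercept).
* ``QUADRATIC_RSF`` — quadratic response surface: linear terms, pairwise
  products and squares (2n + n(n-1)/2 regressors plus intercept).
* ``MLP_1x4`` — a single hidden layer of 4 tanh units with a linear output.
* ``CASCADE_2x1`` — a cascade-forward net: one tanh hidden unit whose output
  is concatenated with the raw inputs into a linear output layer.

Inputs are always scaled to [0, 1] by the per-drug maximum grid level before
regressor construction or network evaluation; raw µM values span three
orders of magnitude and would make product regressors ill-conditioned.
Networks are trained by Bayesian regularization: an L2-penalized squared
error whose penalty ratio alpha/beta is re-estimated each outer iteration by
the MacKay evidence update, with multiple seeded restarts.  Predictions are
clamped ("saturated") to [0, 1] at prediction time only — the training loss
sees raw outputs.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
import scipy.stats

from .design import CombinationGrid, DrugPanel
from .errors import (
    ConvergenceWarning,
    RankError,
    ScalerError,
    ShapeError,
    UndefinedCorrelationError,
)

LINEAR_FAMILIES = ("LR_FULL_INTERACTION", "QUADRATIC_RSF")
NETWORK_FAMILIES = ("MLP_1x4", "CASCADE_2x1")
FAMILIES = LINEAR_FAMILIES + NETWORK_FAMILIES


# ---------------------------------------------------------------------------
# input scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputScaler:
    """Maps concentrations to [0,1] by dividing by the per-drug maximum level."""

    max_conc: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.max_conc, dtype=float)
        if m.ndim != 1 or np.any(m <= 0):
            raise ScalerError("per-drug maxima must be a 1-D positive vector")
        object.__setattr__(self, "max_conc", m)

    @classmethod
    def from_panel(cls, panel: DrugPanel) -> "InputScaler":
        return cls(max_conc=panel.max_levels)

    def scale(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if conc.shape[-1] != self.max_conc.shape[0]:
            raise ShapeError(
                f"combination has {conc.shape[-1]} entries, scaler expects {self.max_conc.shape[0]}"
            )
        return conc / self.max_conc


def scale_inputs(conc: np.ndarray, scaler: InputScaler) -> np.ndarray:
    """Unit-scale one combination or an array of combinations."""
    return scaler.scale(conc)


# ---------------------------------------------------------------------------
# regressor construction
# ---------------------------------------------------------------------------

def lr_subsets(n: int) -> list[tuple[int, ...]]:
    """Canonical order of the 2^n - 1 non-empty drug subsets.

    Singletons first, then pairs, triples, ...; lexicographic within a size.
    This ordering is shared with the interaction-inference module so that
    regressor indices mean the same thing everywhere.
    """
    return [
        s
        for size in range(1, n + 1)
        for s in itertools.combinations(range(n), size)
    ]


def lr_regressors(x: np.ndarray) -> np.ndarray:
    """Full-interaction regressors: one product per non-empty drug subset."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    cols = [x[:, list(s)].prod(axis=1) for s in lr_subsets(n)]
    out = np.column_stack(cols)
    return out


def qrf_regressors(x: np.ndarray) -> np.ndarray:
    """Quadratic response-surface regressors: linear, pairwise products, squares."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    cols = [x[:, i] for i in range(n)]
    cols += [x[:, i] * x[:, j] for i, j in itertools.combinations(range(n), 2)]
    cols += [x[:, i] ** 2 for i in range(n)]
    return np.column_stack(cols)


_REGRESSOR_FN = {"LR_FULL_INTERACTION": lr_regressors, "QUADRATIC_RSF": qrf_regressors}


# ---------------------------------------------------------------------------
# model spec / fitted model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Family choice plus hyperparameters.

    ``hidden`` is the hidden-layer width (fixed at 4 for the MLP and 1 for
    the cascade by default).  ``restarts``/``seed`` control network
    initialization; ``ridge`` enables a penalized fallback for
    underdetermined linear fits.
    """

    family: str
    hidden: int = 4
    restarts: int = 5
    seed: int = 0
    max_outer: int = 30
    inner_maxiter: int = 80
    tol: float = 1e-6
    ridge: bool = False
    ridge_lambda: float = 1e-6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.family == "CASCADE_2x1":
            object.__setattr__(self, "hidden", 1)


@dataclass
class FittedResponseModel:
    """A trained response-surface model with its scaler and training summary."""

    spec: ModelSpec
    scaler: InputScaler
    params: np.ndarray = field(repr=False)
    train_mse: float = np.nan
    iterations: int = 0
    restart_chosen: int = 0
    converged: bool = True

    @property
    def n_inputs(self) -> int:
        return self.scaler.max_conc.shape[0]

    def predict_raw(self, conc: np.ndarray) -> np.ndarray:
        """Unsaturated model output for one or many combinations."""
        conc = np.asarray(conc, dtype=float)
        single = conc.ndim == 1
        x = self.scaler.scale(np.atleast_2d(conc))
        if self.spec.family in LINEAR_FAMILIES:
            X = _REGRESSOR_FN[self.spec.family](x)
            out = self.params[0] + X @ self.params[1:]
        elif self.spec.family == "MLP_1x4":
            out = _mlp_forward(self.params, x, self.spec.hidden)
        else:
            out = _cascade_forward(self.params, x)
        return out[0] if single else out

    def predict(self, conc: np.ndarray) -> np.ndarray:
        """Saturated prediction in [0, 1]."""
        return np.clip(self.predict_raw(conc), 0.0, 1.0)

    # -- plain-text round trip ------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "drugcombo-model/1",
            "family": self.spec.family,
            "hidden": self.spec.hidden,
            "max_conc": self.scaler.max_conc.tolist(),
            "params": self.params.tolist(),
            "train_mse": self.train_mse,
            "iterations": self.iterations,
            "restart_chosen": self.restart_chosen,
            "converged": self.converged,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedResponseModel":
        doc = json.loads(text)
        if doc.get("format") != "drugcombo-model/1":
            raise ValueError("not a drugcombo model document")
        return cls(
            spec=ModelSpec(family=doc["family"], hidden=doc["hidden"]),
            scaler=InputScaler(np.array(doc["max_conc"], dtype=float)),
            params=np.array(doc["params"], dtype=float),
            train_mse=doc["train_mse"],
            iterations=doc["iterations"],
            restart_chosen=doc["restart_chosen"],
            converged=doc["converged"],
        )


def predict(model: FittedResponseModel, conc: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`FittedResponseModel.predict`."""
    return model.predict(conc)


# ---------------------------------------------------------------------------
# linear families
# ---------------------------------------------------------------------------

def fit_linear_family(
    conc: np.ndarray,
    y: np.ndarray,
    family: str,
    scaler: InputScaler,
    ridge: bool = False,
    ridge_lambda: float = 1e-6,
) -> FittedResponseModel:
    """Ordinary least squares (with intercept) on the family's regressors.

    Raises :class:`RankError` when the system is underdetermined or rank
    deficient, unless ``ridge`` enables a small L2 penalty (intercept
    unpenalized).
    """
    if family not in LINEAR_FAMILIES:
        raise ValueError(f"{family!r} is not a linear family")
    x = scaler.scale(np.atleast_2d(np.asarray(conc, dtype=float)))
    y = np.asarray(y, dtype=float)
    X = _REGRESSOR_FN[family](x)
    A = np.column_stack([np.ones(len(X)), X])
    p = A.shape[1]
    if not ridge:
        if A.shape[0] < p:
            raise RankError(f"{A.shape[0]} rows for {p} parameters; enable ridge to fit anyway")
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p:
            raise RankError(f"design matrix rank {rank} < {p}; enable ridge to fit anyway")
    else:
        pen = np.full(p, ridge_lambda)
        pen[0] = 0.0
        beta = np.linalg.solve(A.T @ A + np.diag(pen), A.T @ y)
    resid = y - A @ beta
    spec = ModelSpec(family=family, ridge=ridge, ridge_lambda=ridge_lambda)
    return FittedResponseModel(
        spec=spec,
        scaler=scaler,
        params=beta,
        train_mse=float(np.mean(resid**2)),
        iterations=1,
    )


# ---------------------------------------------------------------------------
# network families
# ---------------------------------------------------------------------------

def _mlp_shapes(n: int, hidden: int) -> int:
    return n * hidden + hidden + hidden + 1


def _mlp_unpack(theta: np.ndarray, n: int, hidden: int):
    i = 0
    W1 = theta[i : i + n * hidden].reshape(n, hidden); i += n * hidden
    b1 = theta[i : i + hidden]; i += hidden
    w2 = theta[i : i + hidden]; i += hidden
    b2 = theta[i]
    return W1, b1, w2, b2

def _mlp_forward(theta: np.ndarray, X: np.ndarray, hidden: int) -> np.ndarray:
    W1, b1, w2, b2 = _mlp_unpack(theta, X.shape[1], hidden)
    Z = np.tanh(X @ W1 + b1)
    return Z @ w2 + b2


def _mlp_jacobian(theta: np.ndarray, X: np.ndarray, hidden: int) -> np.ndarray:
    m, n = X.shape
    W1, b1, w2, b2 = _mlp_unpack(theta, n, hidden)
    Z = np.tanh(X @ W1 + b1)          # (m, hidden)
    D = (1.0 - Z**2) * w2             # (m, hidden)
    JW1 = (X[:, :, None] * D[:, None, :]).reshape(m, n * hidden)
    return np.column_stack([JW1, D, Z, np.ones(m)])


def _cascade_size(n: int) -> int:
    return (n + 1) + (n + 2)


def _cascade_unpack(theta: np.ndarray, n: int):
    w1, b1 = theta[:n], theta[n]
    w2 = theta[n + 1 : 2 * n + 1]
    a, b2 = theta[2 * n + 1], theta[2 * n + 2]
    return w1, b1, w2, a, b2


def _cascade_forward(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    w1, b1, w2, a, b2 = _cascade_unpack(theta, X.shape[1])
    h = np.tanh(X @ w1 + b1)
    return X @ w2 + a * h + b2


def _cascade_jacobian(theta: np.ndarray, X: np.ndarray) -> np.ndarray:
    m, n = X.shape
    w1, b1, w2, a, b2 = _cascade_unpack(theta, n)
    h = np.tanh(X @ w1 + b1)
    dh = 1.0 - h**2
    Jw1 = X * (a * dh)[:, None]
    return np.column_stack([Jw1, a * dh, X, h, np.ones(m)])


def _net_init(family: str, n: int, hidden: int, rng: np.random.Generator) -> np.ndarray:
    """Small uniform init scaled by fan-in, per layer."""
    if family == "MLP_1x4":
        s1, s2 = 1.0 / np.sqrt(n), 1.0 / np.sqrt(hidden)
        return np.concatenate([
            rng.uniform(-s1, s1, n * hidden),
            rng.uniform(-s1, s1, hidden),
            rng.uniform(-s2, s2, hidden),
            rng.uniform(-s2, s2, 1),
        ])
    s1 = 1.0 / np.sqrt(n)
    s2 = 1.0 / np.sqrt(n + 1)
    return np.concatenate([
        rng.uniform(-s1, s1, n + 1),
        rng.uniform(-s2, s2, n + 1),
        rng.uniform(-s2, s2, 1),
    ])


def _train_bayes_once(
    forward, jacobian, theta0: np.ndarray, X: np.ndarray, y: np.ndarray, spec: ModelSpec
) -> tuple[np.ndarray, float, int, bool]:
    """One restart of evidence-framework training.

    Minimizes ``beta*ED + alpha*EW`` (ED = half SSE, EW = half ||theta||^2)
    with L-BFGS-B, then re-estimates alpha and beta from the effective number
    of parameters gamma = sum lam_i/(lam_i + alpha), lam_i the eigenvalues of
    the Gauss-Newton Hessian beta * J'J.
    """
    m = len(y)
    theta = theta0.copy()
    alpha, beta = 1e-2, 1.0
    converged = False
    outer = 0
    for outer in range(1, spec.max_outer + 1):
        def objective(th, a=alpha, b=beta):
            r = y - forward(th, X)
            g = -b * (jacobian(th, X).T @ r) + a * th
            return 0.5 * b * (r @ r) + 0.5 * a * (th @ th), g

        res = scipy.optimize.minimize(
            objective, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": spec.inner_maxiter},
        )
        theta = res.x
        r = y - forward(theta, X)
        ED = 0.5 * float(r @ r)
        EW = 0.5 * float(theta @ theta)
        J = jacobian(theta, X)
        lam = np.linalg.eigvalsh(beta * (J.T @ J))
        lam = np.clip(lam, 0.0, None)
        gamma = float(np.sum(lam / (lam + alpha)))
        alpha_new = gamma / (2.0 * EW) if EW > 1e-12 else alpha
        beta_new = (m - gamma) / (2.0 * ED) if ED > 1e-12 else 1e12
        alpha_new = float(np.clip(alpha_new, 1e-8, 1e8))
        beta_new = float(np.clip(beta_new, 1e-8, 1e12))
        rel = abs(alpha_new - alpha) / (alpha + 1e-12) + abs(beta_new - beta) / (beta + 1e-12)
        alpha, beta = alpha_new, beta_new
        if ED <= 1e-12 or rel < spec.tol:
            converged = True
            break
    return theta, 2.0 * ED / m, outer, converged


def fit_network(
    conc: np.ndarray, y: np.ndarray, spec: ModelSpec, scaler: InputScaler
) -> FittedResponseModel:
    """Fit an MLP_1x4 or CASCADE_2x1 network with Bayesian regularization.

    Runs ``spec.restarts`` seeded initializations and keeps the restart with
    the lowest final training MSE (ties broken by lowest restart index).
    Emits :class:`ConvergenceWarning` if no restart met the tolerance.
    """
    if spec.family not in NETWORK_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a network family")
    X = scaler.scale(np.atleast_2d(np.asarray(conc, dtype=float)))
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("network training needs at least 2 rows")
    n = X.shape[1]
    if spec.family == "MLP_1x4":
        forward = lambda th, Z: _mlp_forward(th, Z, spec.hidden)
        jacobian = lambda th, Z: _mlp_jacobian(th, Z, spec.hidden)
    else:
        forward, jacobian = _cascade_forward, _cascade_jacobian

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.restarts)
    best = None
    for r, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        theta0 = _net_init(spec.family, n, spec.hidden, rng)
        theta, mse, iters, conv = _train_bayes_once(forward, jacobian, theta0, X, y, spec)
        if best is None or mse < best[1]:
            best = (theta, mse, iters, conv, r)
    theta, mse, iters, conv, r = best
    if not conv:
        warnings.warn(
            f"{spec.family} training did not meet tolerance in {spec.max_outer} outer "
            "iterations; returning best-found model",
            ConvergenceWarning,
        )
    return FittedResponseModel(
        spec=spec, scaler=scaler, params=theta,
        train_mse=float(mse), iterations=iters, restart_chosen=r, converged=conv,
    )


def fit_response_model(
    conc: np.ndarray, y: np.ndarray, spec: ModelSpec, scaler: InputScaler
) -> FittedResponseModel:
    """Dispatch to the linear or network fitter by family."""
    if spec.family in LINEAR_FAMILIES:
        return fit_linear_family(
            conc, y, spec.family, scaler, ridge=spec.ridge, ridge_lambda=spec.ridge_lambda
        )
    return fit_network(conc, y, spec, scaler)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitEvaluation:
    mse: float
    pearson_r: float


def evaluate_fit(predicted: np.ndarray, observed: np.ndarray) -> FitEvaluation:
    """Mean squared error and Pearson R between predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or len(predicted) < 2:
        raise ShapeError("predicted and observed must be equal-length 1-D vectors (n >= 2)")
    mse = float(np.mean((predicted - observed) ** 2))
    if np.ptp(observed) == 0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for a constant observed vector", mse=mse
        )
    r = float(scipy.stats.pearsonr(predicted, observed).statistic)
    return FitEvaluation(mse=mse, pearson_r=r)


def learning_curve(
    table,
    cell_line: str,
    grid: CombinationGrid,
    family: str,
    sizes: tuple[int, ...],
    repeats: int,
    seed: int,
    spec: ModelSpec | None = None,
) -> dict[int, float]:
    """Mean full-grid prediction MSE versus training-set size.

    ``table`` must cover the full grid (its rows aligned with ``grid``); for
    each size, ``repeats`` fresh uniform designs are drawn, a model of the
    requested family is fitted on each, and the full-grid prediction MSE
    against the table's responses is averaged.
    """
    from .design import sample_training_design

    y_full = table.responses[cell_line]
    if len(table) != len(grid):
        raise ShapeError("learning_curve requires a table covering the full grid")
    scaler = InputScaler.from_panel(grid.panel)
    base = spec if spec is not None else ModelSpec(family=family)
    if base.family != family:
        base = replace(base, family=family)
    ss = np.random.SeedSequence(seed)
    out: dict[int, float] = {}
    for size in sizes:
        mses = []
        for child in ss.spawn(repeats):
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            design = sample_training_design(grid, size, sub_seed)
            idx = design.grid_indices
            m = fit_response_model(
                table.conc[idx], y_full[idx], replace(base, seed=sub_seed), scaler
            )
            pred = m.predict(grid.conc)
            mses.append(float(np.mean((pred - y_full) ** 2)))
        out[size] = float(np.mean(mses))
    return out
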