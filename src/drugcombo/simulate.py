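"""Synthetic two-cell-type viability surfaces for factorial drug screens.

Ground truth is built from three ingredients that mirror what a plate-based
ATP viability screen actually measures:

* per-drug sigmoidal dose response (a Hill curve for the surviving fraction),
* Bliss independence as the non-interacting baseline — survival under a
  combination is the product of single-drug survivals,
* planted pairwise / three-way interaction terms that add (synergy,
  ``gamma < 0``) or remove (antagonism/protection, ``gamma > 0``) killing on
  top of the Bliss product.  Interactions act on products of fractional
  inhibitions, so they are scale-free and vanish exactly at zero dose: an
  untreated well always reads 1.0, matching normalization to untreated
  controls.

Measurements add truncated Gaussian plate noise and clamp to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import CombinationGrid, DrugPanel, default_four_drug_panel, default_three_drug_panel
from .errors import ShapeError

__all__ = [
    "HillParams",
    "InteractionTerm",
    "SyntheticTruth",
    "ResponseTable",
    "hill_viability",
    "truth_response",
    "simulate_measurements",
    "merge_tables",
    "default_two_celltype_scenario",
    "default_three_drug_truth",
    "SELECTIVE_COMBINATION",
]


@dataclass(frozen=True)
class HillParams:
    """Single-drug Hill curve: ec50 (µM), slope h, maximal inhibition imax."""

    ec50: float
    h: float
    imax: float

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if not self.h > 0:
            raise ValueError(f"Hill slope must be positive, got {self.h}")
        if not 0.0 <= self.imax <= 1.0:
            raise ValueError(f"imax must be in [0,1], got {self.imax}")


@dataclass(frozen=True)
class InteractionTerm:
    """A planted drug-drug interaction on a 2- or 3-drug subset.

    ``gamma`` multiplies the product of the member drugs' fractional
    inhibitions; negative values deepen killing (synergy), positive values
    rescue viability (antagonism).
    """

    drug_subset: tuple[int, ...]
    gamma: float

    def __post_init__(self) -> None:
        if len(self.drug_subset) not in (2, 3):
            raise ValueError("interaction subsets must have 2 or 3 drugs")
        if len(set(self.drug_subset)) != len(self.drug_subset):
            raise ValueError("interaction drug indices must be distinct")


@dataclass(frozen=True)
class SyntheticTruth:
    """A noiseless response surface for one cell type over a panel."""

    panel: DrugPanel
    hill: tuple[HillParams, ...]
    interactions: tuple[InteractionTerm, ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.hill) != self.panel.n_drugs:
            raise ShapeError("one HillParams required per panel drug")
        for term in self.interactions:
            if any(i >= self.panel.n_drugs or i < 0 for i in term.drug_subset):
                raise ShapeError(f"interaction {term.drug_subset} indexes outside the panel")

    def response(self, conc: np.ndarray) -> np.ndarray:
        return truth_response(self, conc)


def hill_viability(c, p: HillParams):
    """Surviving fraction at concentration ``c`` (µM): 1 - imax·c^h/(c^h + ec50^h).

    Vectorized over ``c``; returns 1.0 at zero dose and decreases
    monotonically to ``1 - imax``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        ch = np.where(c > 0, c, np.nan) ** p.h
    inhib = np.where(c > 0, p.imax * ch / (ch + p.ec50**p.h), 0.0)
    out = 1.0 - inhib
    return out if out.ndim else float(out)


def _viability_matrix(truth: SyntheticTruth, conc: np.ndarray) -> np.ndarray:
    """Per-drug survival fractions, shape (n_rows, n_drugs)."""
    return np.column_stack(
        [hill_viability(conc[:, i], p) for i, p in enumerate(truth.hill)]
    )


def truth_response(truth: SyntheticTruth, conc: np.ndarray):
    """Noiseless normalized response at one combination or an array of them.

    ``clamp( prod_i v_i  +  sum_T gamma_T prod_{i in T} (1 - v_i), 0, 1 )``
    where ``v_i`` is the Hill survival of drug ``i``.  With no interactions
    this is exactly the Bliss-independence product.
    """
    conc = np.asarray(conc, dtype=float)
    single = conc.ndim == 1
    if single:
        conc = conc[None, :]
    if conc.shape[1] != truth.panel.n_drugs:
        raise ShapeError(
            f"combination has {conc.shape[1]} entries for a {truth.panel.n_drugs}-drug panel"
        )
    v = _viability_matrix(truth, conc)
    resp = v.prod(axis=1)
    s = 1.0 - v
    for term in truth.interactions:
        resp = resp + term.gamma * s[:, list(term.drug_subset)].prod(axis=1)
    resp = np.clip(resp, 0.0, 1.0)
    return float(resp[0]) if single else resp


@dataclass
class ResponseTable:
    """Combinations paired with normalized responses per cell line.

    ``conc`` has shape (n_rows, n_drugs); ``responses`` maps each cell-line
    name to a length-n_rows vector in [0, 1].  Replicates appear as repeated
    rows.
    """

    panel: DrugPanel
    conc: np.ndarray = field(repr=False)
    responses: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim != 2 or self.conc.shape[1] != self.panel.n_drugs:
            raise ShapeError("conc must be (n_rows, n_drugs)")
        n = self.conc.shape[0]
        for name, y in self.responses.items():
            y = np.asarray(y, dtype=float)
            if y.shape != (n,):
                raise ShapeError(f"cell line {name!r}: {y.shape} responses for {n} rows")
            if np.any((y < 0) | (y > 1)):
                raise ValueError(f"cell line {name!r} has responses outside [0,1]")
            self.responses[name] = y

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(self.responses)

    def __len__(self) -> int:
        return self.conc.shape[0]

    def subset(self, rows: np.ndarray) -> "ResponseTable":
        return ResponseTable(
            panel=self.panel,
            conc=self.conc[rows],
            responses={k: v[rows] for k, v in self.responses.items()},
        )


def simulate_measurements(
    truth: SyntheticTruth,
    grid: CombinationGrid,
    sigma: float = 0.05,
    seed: int = 0,
    replicates: int = 1,
) -> ResponseTable:
    """Simulate a plate readout of every grid row for one cell type.

    Each measurement is ``clamp(truth + N(0, sigma^2), 0, 1)``.  Replicates
    are emitted as repeated rows.  Bit-reproducible given ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.repeat(grid.conc, replicates, axis=0)
    clean = truth_response(truth, conc)
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean, 0.0, 1.0)
    return ResponseTable(panel=grid.panel, conc=conc, responses={truth.label: noisy})


def merge_tables(*tables: ResponseTable) -> ResponseTable:
    """Merge single-cell-line tables measured on identical combinations."""
    first = tables[0]
    responses: dict[str, np.ndarray] = {}
    for t in tables:
        if t.panel != first.panel or not np.array_equal(t.conc, first.conc):
            raise ShapeError("tables must share panel and combination rows to merge")
        for name, y in t.responses.items():
            if name in responses:
                raise ValueError(f"duplicate cell line {name!r}")
            responses[name] = y
    return ResponseTable(panel=first.panel, conc=first.conc.copy(), responses=responses)


#: A combination (µM, 4-drug panel order) at which the default cancer-like
#: truth is markedly lower than the normal-like truth: mid-range AG490 and
#: I-3-M engage both planted synergies in the cancer-like surface while the
#: gentler normal-like curves are barely inhibited.
SELECTIVE_COMBINATION = np.array([30.0, 0.3, 30.0, 10.0])


def default_two_celltype_scenario(seed: int = 0) -> tuple[SyntheticTruth, SyntheticTruth]:
    """The package's reference two-cell-type ground truth on the 4-drug panel.

    Returns ``(cancer_like, normal_like)``.  The cancer-like surface is more
    drug-sensitive (lower EC50s, deeper maximal inhibition) for three of the
    four drugs but nearly resistant to the MEK inhibitor U0126; the
    normal-like surface responds gently to the first three drugs and barely
    to GF109203X.  Both truths share one pairwise interaction, and each
    carries one private pairwise term, so interaction inference can be
    checked against a known common/private partition:

    * shared:        AG490 × I-3-M      antagonism (gamma +0.35 cancer,
      +0.25 normal)
    * cancer-only:   AG490 × GF109203X  synergy    (gamma -0.30)
    * normal-only:   U0126 × I-3-M      antagonism (gamma +0.25)

    Each cell type's single-agent sensitivities are concentrated on the
    drugs its interactions involve, so the Bliss-independence baseline does
    not leak the private interactions into the other cell type's surface.
    The truths are fixed documented constants; ``seed`` is accepted for API
    uniformity with the other generators and does not alter them.
    """
    del seed
    panel = default_four_drug_panel()
    cancer = SyntheticTruth(
        panel=panel,
        hill=(
            HillParams(ec50=30.0, h=1.2, imax=0.55),
            HillParams(ec50=3.0, h=1.2, imax=0.05),
            HillParams(ec50=30.0, h=1.2, imax=0.55),
            HillParams(ec50=10.0, h=1.2, imax=0.50),
        ),
        interactions=(
            InteractionTerm((0, 2), 0.35),
            InteractionTerm((0, 3), -0.30),
        ),
        label="cancer-like",
    )
    normal = SyntheticTruth(
        panel=panel,
        hill=(
            HillParams(ec50=60.0, h=1.0, imax=0.30),
            HillParams(ec50=6.0, h=1.0, imax=0.35),
            HillParams(ec50=60.0, h=1.0, imax=0.35),
            HillParams(ec50=30.0, h=1.0, imax=0.08),
        ),
        interactions=(
            InteractionTerm((0, 2), 0.25),
            InteractionTerm((1, 2), 0.25),
        ),
        label="normal-like",
    )
    return cancer, normal


def default_three_drug_truth() -> SyntheticTruth:
    """A single cancer-like truth on the 3-drug panel (512-point grid).

    Used for learning-curve and model-recovery experiments at the smaller
    factorial scale; parameters parallel the cancer-like member of
    :func:`default_two_celltype_scenario`.
    """
    panel = default_three_drug_panel()
    return SyntheticTruth(
        panel=panel,
        hill=(
            HillParams(ec50=30.0, h=1.2, imax=0.60),
            HillParams(ec50=3.0, h=1.2, imax=0.50),
            HillParams(ec50=30.0, h=1.2, imax=0.60),
        ),
        interactions=(InteractionTerm((0, 2), -0.30),),
        label="cancer-like",
    )
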