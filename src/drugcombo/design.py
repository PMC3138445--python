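"""Drug panels, factorial concentration grids and random training designs.

A *panel* is an ordered set of drugs, each with an ordered list of
concentration levels in µM (zero dose allowed and typically present).  The
*grid* is the full factorial product of the per-drug levels; all downstream
stages (model fitting, performance mapping, mixture analysis) index into the
grid by row number, so the row ordering is fixed once and for all:
lexicographic with the last drug's level index varying fastest.

Training designs are uniform random draws of grid rows without replacement,
mirroring a screen in which only a small subset of the factorial space is
measured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignSizeError, InvalidPanelError


@dataclass(frozen=True)
class DrugPanel:
    """An ordered drug panel with per-drug concentration levels (µM)."""

    drugs: tuple[str, ...]
    levels: tuple[tuple[float, ...], ...]
    units: str = "uM"

    def __post_init__(self) -> None:
        if len(self.drugs) == 0:
            raise InvalidPanelError("panel must contain at least one drug")
        if len(self.levels) != len(self.drugs):
            raise InvalidPanelError(
                f"{len(self.drugs)} drugs but {len(self.levels)} level lists"
            )
        if len(set(self.drugs)) != len(self.drugs):
            raise InvalidPanelError("drug names must be unique")
        for name, lv in zip(self.drugs, self.levels):
            if len(lv) == 0:
                raise InvalidPanelError(f"drug {name!r} has an empty level list")
            arr = np.asarray(lv, dtype=float)
            if np.any(arr < 0):
                raise InvalidPanelError(f"drug {name!r} has a negative level")
            if np.any(np.diff(arr) <= 0):
                raise InvalidPanelError(f"levels of drug {name!r} are not strictly ascending")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(len(lv) for lv in self.levels)

    @property
    def grid_size(self) -> int:
        return int(np.prod(self.n_levels))

    @property
    def max_levels(self) -> np.ndarray:
        """Per-drug maximum concentration (µM)."""
        return np.array([lv[-1] for lv in self.levels], dtype=float)

    def drug_index(self, name: str) -> int:
        try:
            return self.drugs.index(name)
        except ValueError:
            raise InvalidPanelError(f"unknown drug {name!r}") from None


def default_three_drug_panel() -> DrugPanel:
    """The 3-drug screening panel (8 levels each, 512 combinations)."""
    return DrugPanel(
        drugs=("AG490", "U0126", "I-3-M"),
        levels=(
            (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
            (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
            (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
        ),
    )


def default_four_drug_panel() -> DrugPanel:
    """The 4-drug screening panel (7 levels each, 2401 combinations)."""
    return DrugPanel(
        drugs=("AG490", "U0126", "I-3-M", "GF109203X"),
        levels=(
            (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
            (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0),
            (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
            (0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
        ),
    )


@dataclass(frozen=True)
class CombinationGrid:
    """Full factorial grid over a panel; ``conc`` has shape (n_rows, n_drugs)."""

    panel: DrugPanel
    conc: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.conc.shape != (self.panel.grid_size, self.panel.n_drugs):
            raise InvalidPanelError(
                f"grid shape {self.conc.shape} does not match panel "
                f"({self.panel.grid_size}, {self.panel.n_drugs})"
            )

    def __len__(self) -> int:
        return self.conc.shape[0]

    def row(self, i: int) -> np.ndarray:
        return self.conc[i]


def enumerate_grid(panel: DrugPanel) -> CombinationGrid:
    """Enumerate the full factorial combination grid in canonical order.

    Canonical order is lexicographic in the per-drug level indices with the
    last drug varying fastest (``itertools.product`` order), so row 0 is the
    all-lowest (typically all-zero) combination and the last row is the
    all-maximum combination.
    """
    rows = np.array(list(itertools.product(*panel.levels)), dtype=float)
    return CombinationGrid(panel=panel, conc=rows)


@dataclass(frozen=True)
class TrainingDesign:
    """Distinct grid-row indices selected for training, plus the seed used."""

    grid_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.grid_indices)
        if idx.ndim != 1 or len(np.unique(idx)) != len(idx):
            raise DesignSizeError("training design indices must be a 1-D set of distinct values")

    def __len__(self) -> int:
        return len(self.grid_indices)


def sample_training_design(grid: CombinationGrid, n: int, seed: int) -> TrainingDesign:
    """Draw ``n`` distinct grid rows uniformly without replacement.

    Reproducible given ``seed``; indices are returned sorted ascending for a
    canonical representation (the set, not the draw order, is the design).
    """
    size = len(grid)
    if not 1 <= n <= size:
        raise DesignSizeError(f"design size {n} outside 1..{size}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(size, size=n, replace=False))
    return TrainingDesign(grid_indices=idx, seed=seed)
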