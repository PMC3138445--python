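"""Exception hierarchy for drugcombo.

Every error raised on a contract violation derives from :class:`DrugComboError`
so callers can catch the package's failures in one clause; most also derive
from the matching builtin (``ValueError`` et al.) for idiomatic handling.
"""


class DrugComboError(Exception):
    """Base class for all drugcombo errors."""


class InvalidPanelError(DrugComboError, ValueError):
    """A drug panel violates its invariants (empty, unsorted or negative levels)."""


class DesignSizeError(DrugComboError, ValueError):
    """Requested training-design size is outside ``1..grid_size``."""


class ShapeError(DrugComboError, ValueError):
    """A concentration vector or table does not match the panel dimension."""


class ScalerError(DrugComboError, ValueError):
    """Input scaler has a non-positive maximum concentration."""


class RankError(DrugComboError, ValueError):
    """Underdetermined or rank-deficient least-squares fit without ridge fallback."""


class UndefinedCorrelationError(DrugComboError, ValueError):
    """Pearson correlation requested against a constant observed vector.

    Carries the mean squared error, which is still well defined.
    """

    def __init__(self, message: str, mse: float):
        super().__init__(message)
        self.mse = mse


class PanelMismatchError(DrugComboError, ValueError):
    """Two objects built over different drug panels were combined."""


class ClusterCountError(DrugComboError, ValueError):
    """More clusters requested than points available."""


class MixtureRestrictionError(DrugComboError, ValueError):
    """A proper drug-subset restriction is empty because a drug has no zero level."""


class RegressorCountError(DrugComboError, ValueError):
    """Interaction design requested on a panel that is not the 4-drug layout."""


class TableParseError(DrugComboError, ValueError):
    """A response-table file failed validation; message names the offending cell."""


class ConfigError(DrugComboError, ValueError):
    """A pipeline configuration is inconsistent or incomplete."""


class ConvergenceWarning(UserWarning):
    """Network training hit the iteration budget without meeting tolerance."""
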