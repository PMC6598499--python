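"""Exception hierarchy shared by all thermoniche modules."""


class ThermonicheError(Exception):
    """Base class for all package-specific errors."""


class DataError(ThermonicheError):
    """Invalid or unusable input data (bad values, malformed records)."""


class EstimationError(ThermonicheError):
    """An estimator could not produce a result (too few points, etc.)."""


class ConsistencyError(ThermonicheError):
    """Inputs that should agree (labels, lengths) do not."""


class FitError(ThermonicheError):
    """Nonlinear fit could not be performed or did not converge."""


class AlignmentError(ThermonicheError):
    """Sequence alignment problems (unequal lengths, no comparable sites)."""


class TreeError(ThermonicheError):
    """Phylogeny problems (unrooted input, non-ultrametric where required)."""


class SpecError(ThermonicheError):
    """Infeasible synthetic-panel specification."""
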