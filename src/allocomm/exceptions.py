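"""Exception hierarchy for allocomm."""


class AllocommError(Exception):
    """Base class for all allocomm errors."""


class FormatError(AllocommError):
    """A structure/trajectory file could not be interpreted (e.g. atom-count mismatch)."""


class DegenerateEnsembleError(AllocommError):
    """The ensemble has too few frames for the requested statistic (F < 2)."""


class SelectionError(AllocommError):
    """An atom selection matched nothing."""


class InvalidPairError(AllocommError):
    """A residue pair is invalid for the requested operation (e.g. i == j)."""


class DesignError(AllocommError):
    """A synthetic-ensemble design is inconsistent or not realisable."""


class CalibrationError(AllocommError):
    """Automatic threshold calibration is impossible on this input."""


class AssemblyError(AllocommError):
    """Network components were computed on differing residue sets."""


class ComparisonError(AllocommError):
    """Two networks cannot be compared (incompatible residue universes)."""
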