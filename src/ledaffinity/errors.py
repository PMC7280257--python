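"""Exception hierarchy for the ledaffinity pipeline."""


class LedAffinityError(Exception):
    """Base class for all errors raised by this package."""


class PdbParseError(LedAffinityError):
    """A PDB-format record could not be parsed (message names the line)."""


class LigandNotFoundError(LedAffinityError):
    """The requested het code/chain matched no hetero atom."""


class EmptyClusterError(LedAffinityError):
    """No residue had any atom within the contact cutoff of the ligand."""


class ConfigurationError(LedAffinityError):
    """Required settings (e.g. charge/multiplicity) were not supplied."""


class PlacementError(LedAffinityError):
    """Toy-structure generation could not satisfy the minimum atom separation."""


class LedParseError(LedAffinityError):
    """A required section or labelled line is missing from LED output text."""


class UnsupportedTopologyError(LedAffinityError):
    """LED output describes a fragment count other than two."""


class SingularDesignError(LedAffinityError):
    """The regression design matrix is rank deficient."""


class InsufficientDataError(LedAffinityError):
    """Fewer data points than the model needs for a residual dof."""


class FoldSingularityError(LedAffinityError):
    """A leave-one-out training design is singular (message names the fold)."""


class SchemaError(LedAffinityError):
    """An input table is missing a required column."""
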