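"""Exception hierarchy shared across the package.

Each error class corresponds to a distinct failure mode of the analysis;
the command-line layer maps them onto distinct exit codes.
"""


class PathprsError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class FormatError(PathprsError):
    """A required input file is malformed or misses mandatory columns."""

    exit_code = 2


class EmptyInputError(PathprsError):
    """An input contained zero usable records after validation."""

    exit_code = 3


class EmptyOverlapError(PathprsError):
    """Two datasets share no SNPs after harmonization."""

    exit_code = 4


class BuildMismatchError(PathprsError):
    """Genome-build tags of two datasets disagree; no liftover is attempted."""

    exit_code = 5


class ThresholdEmptyError(PathprsError):
    """No SNP survives the discovery P-value threshold."""

    exit_code = 6


class DegenerateWeightsError(PathprsError):
    """All score weights are zero; the association estimator is undefined."""

    exit_code = 7


class PanelLookupError(PathprsError):
    """A SNP id was requested that the reference panel does not carry."""

    exit_code = 8


class GeneSetError(PathprsError):
    """A gene-set definition refers to genes absent from the annotation."""

    exit_code = 9


class StratumError(PathprsError):
    """A significance stratum has too few pool SNPs for matched sampling."""

    exit_code = 10


class GeneExclusionError(PathprsError):
    """A gene cannot be analysed (no SNP data or singular genotype matrix)."""

    exit_code = 11


class ConfigError(PathprsError):
    """A run configuration file is invalid or contains unknown keys."""

    exit_code = 12
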