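"""Exception hierarchy shared by all modules."""


class ParalogonError(Exception):
    """Base class for all package errors."""


class UnknownGeneError(ParalogonError, KeyError):
    """A gene id was not found in the genome."""


class CrossChromosomeError(ParalogonError):
    """Distance/span requested between loci on different chromosomes."""


class UnplacedScaffoldError(ParalogonError):
    """Operation requires a placed chromosome but the locus sits on an
    unplaced scaffold."""


class SchemaError(ParalogonError):
    """A file does not conform to the documented column schema."""


class ParseError(ParalogonError):
    """A row or label could not be parsed; the message names the line/leaf."""


class ConfigurationError(ParalogonError):
    """Invalid species-tree / window / pipeline configuration."""


class ReplayError(ParalogonError):
    """An event history referenced an entity that does not exist at the time
    the event applies; the message names the event index."""


class ReconciliationError(ParalogonError):
    """Gene-tree leaf could not be mapped onto the species tree."""
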