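"""Exception hierarchy shared across the pipeline stages."""


class MutlogError(Exception):
    """Base class for all data and configuration errors raised by mutlog."""


class ConfigurationError(MutlogError):
    """Invalid simulation or run configuration (e.g. genes cannot be placed)."""


class VcfParseError(MutlogError):
    """A VCF record that should be usable is missing required fields."""


class DataIntegrityError(MutlogError):
    """Inputs contradict each other (e.g. reference base mismatch at a variant)."""


class MissingContextError(MutlogError):
    """A requested trinucleotide context does not occur in the genome."""


class NormalizationError(MutlogError):
    """Size factors cannot be computed from the coverage matrix."""


class UnknownContigError(MutlogError):
    """A variant references a contig absent from the genome assets."""
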