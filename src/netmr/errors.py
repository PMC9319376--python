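"""Exception hierarchy for netmr.

Every failure mode a caller may want to branch on gets its own class;
everything derives from :class:`NetmrError` so blanket handling stays easy.
"""


class NetmrError(Exception):
    """Base class for all netmr errors."""


class FormatError(NetmrError):
    """A summary-statistics file is structurally unreadable (e.g. a
    mandatory column is missing)."""


class ValidationError(NetmrError):
    """A record violates a domain invariant (non-positive SE, bad allele,
    p-value out of range, ...)."""


class HarmonizationError(NetmrError):
    """Exposure/outcome datasets share no usable instruments."""


class InsufficientInstrumentsError(NetmrError):
    """An estimator was called with fewer SNPs than it requires."""


class CollinearityError(NetmrError):
    """The multivariable exposure-effect matrix is rank deficient."""


class ConfigError(NetmrError):
    """A run configuration is incomplete or inconsistent."""
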