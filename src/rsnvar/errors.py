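"""Exception hierarchy used across the pipeline.

``ValidationError`` means the inputs violate a documented contract
(bad table, mismatched grids, empty mask...).  ``ConfigurationError``
means the requested configuration is internally inconsistent
(infeasible network membership, band edges above Nyquist...).
The CLI maps both to exit code 1; unexpected failures exit 2.
"""


class RsnvarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RsnvarError):
    """Input data violates a contract of the operation."""


class ConfigurationError(RsnvarError):
    """Requested configuration is infeasible or inconsistent."""
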