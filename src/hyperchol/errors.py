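"""Exception types shared across the pipeline."""


class HypercholError(Exception):
    """Base class for all package errors."""


class ConfigError(HypercholError):
    """A configuration value failed validation; the message names the field."""


class FixtureError(HypercholError):
    """Requested count-fixture is internally inconsistent or unrealizable."""


class OrientationError(HypercholError):
    """A panel SNV's effect allele matches neither REF nor ALT in the VCF."""


class UnknownStatinError(HypercholError):
    """Statin type/dose combination absent from the coefficient table."""


class NotSupportedError(HypercholError):
    """Input uses a feature outside the pipeline's scope (e.g. CNV records)."""


class CollinearityError(HypercholError):
    """Regression design matrix is rank deficient."""


class EvidenceConflictError(HypercholError):
    """Supplied ACMG evidence both asserts and retracts the same tag."""
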