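"""Exception types shared across the battery pipeline."""


class DNTBatteryError(Exception):
    """Base class for all package errors."""


class SchemaError(DNTBatteryError):
    """A screen table is missing required columns or has malformed rows."""


class ConfigurationError(DNTBatteryError):
    """Endpoint pairing / threshold configuration is inconsistent."""


class NormalizationError(DNTBatteryError):
    """Solvent-control wells are absent or have a non-positive mean."""


class AnalysisError(DNTBatteryError):
    """Replication is insufficient for the requested statistic."""


class FitInfeasibleError(DNTBatteryError):
    """Too few distinct concentrations for the requested model."""


class SelectionError(DNTBatteryError):
    """No converged fit available to select from."""
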