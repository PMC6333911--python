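"""Exception hierarchy for breedsim."""


class BreedSimError(Exception):
    """Base class for all breedsim errors."""


class ConfigError(BreedSimError):
    """Invalid configuration value or combination."""


class ParseError(BreedSimError):
    """Malformed input file; message names the file and offending line."""


class InfeasibleError(BreedSimError):
    """A request that cannot be satisfied (reports the violated bound)."""


class StandardizationError(BreedSimError):
    """Effect standardization impossible (no segregating QTL variance)."""


class SimulationError(BreedSimError):
    """Internal consistency failure during a simulation run."""
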