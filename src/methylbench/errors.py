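"""Exception types shared across the package."""


class MethylbenchError(Exception):
    """Base class for package errors."""


class ConfigurationError(MethylbenchError):
    """Invalid or infeasible configuration (bad densities, missing paths...)."""


class SimulationError(MethylbenchError):
    """A simulation could not proceed (e.g. no molecules survive degradation)."""


class ContractError(MethylbenchError):
    """An input violates a documented invariant (e.g. a call at a non-cytosine)."""


class ParseError(MethylbenchError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
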