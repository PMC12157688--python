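"""Exception types shared across the package."""


class EPPError(Exception):
    """Base class for all package errors."""


class ValidationError(EPPError):
    """Invalid user input: malformed table, duplicate channels, bad config."""


class EPPIOError(EPPError):
    """Unreadable or garbled input file; the message names the offending segment."""


class WidenSignal(EPPError):
    """Internal control-flow signal: the current kernel width produced a grid
    too complex to analyze (too many clusters or edges, or a non-chainable
    boundary); the caller doubles W and restarts from the weight array."""
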