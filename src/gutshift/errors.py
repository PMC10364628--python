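"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: FormatError/ConsistencyError/ValueError/OSError
are input errors (exit 1); AnalysisError is a statistical/structural failure
of an otherwise well-formed input (exit 2).
"""


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. contribution and compound files) do not."""


class AnalysisError(RuntimeError):
    """An analysis step cannot proceed (e.g. fewer than 3 subjects per group)."""
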