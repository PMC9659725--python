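"""Exception types shared across the pipeline.

The CLI maps these onto process exit codes: schema problems exit 2,
statistical precondition failures exit 3.
"""


class SchemaError(ValueError):
    """Malformed or inconsistent input table / configuration."""


class StatsPreconditionError(ValueError):
    """A statistical routine was called on data that cannot support it
    (empty group, zero variance reference, no events, ...)."""


class DegenerateReferenceError(StatsPreconditionError):
    """Control-group standard deviation is zero for a measure."""
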