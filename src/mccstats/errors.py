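"""Exception hierarchy.

All package errors derive from :class:`MccStatsError` so callers can catch
one type; the three subclasses distinguish bad user input, evaluation of a
formula outside its mathematical domain, and probabilistically infeasible
scenario requests.
"""


class MccStatsError(Exception):
    """Base class for all errors raised by mccstats."""


class InputError(MccStatsError, ValueError):
    """Malformed or invalid user input (labels, counts, files, options)."""


class DomainError(MccStatsError, ValueError):
    """A formula was evaluated outside its mathematical domain.

    Examples: Fisher's z at |x| >= 1, the phi gradient at a table with a
    zero margin.  Callers constructing confidence intervals typically map
    this to an NA result rather than propagating.
    """


class InfeasibleError(MccStatsError, ValueError):
    """Requested probabilities are incompatible (no valid joint exists)."""
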