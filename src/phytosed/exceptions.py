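"""Exception hierarchy.

``ValidityError`` flags inputs outside an operation's contract;
``DomainError`` flags mathematically undefined model evaluations (e.g. a
non-positive drag base); ``BuoyancyError`` is the dedicated signal that a
particle is not negatively buoyant and therefore has no settling velocity.
"""


class PhytosedError(Exception):
    """Base class for all package errors."""


class ValidityError(PhytosedError, ValueError):
    """An input violates a precondition (wrong range, sign, or shape)."""


class DomainError(PhytosedError, ValueError):
    """A model is evaluated outside its mathematical domain of validity."""


class BuoyancyError(PhytosedError, ValueError):
    """The particle floats (rho <= rho_sw): no sedimentation velocity exists."""


class SchemaError(PhytosedError, ValueError):
    """A data table does not match the expected column/unit schema."""
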