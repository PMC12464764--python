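"""Combinatorial capacity of an idealized polyketide-synthase assembly line.

Each two-carbon chain-extension unit can end in one of five reduction
states — keto, R-alcohol, S-alcohol, olefin, or fully saturated.  An
N-membered macrolactone built from two-carbon units uses N/2 units, one of
which is retained as the keto anchor for macrolactonization; the remaining
units vary freely, giving 5^(N/2 − 1) idealized products (78,125 for a
16-membered ring).  Arithmetic is exact Python integers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

#: keto, R-alcohol, S-alcohol, olefin, saturated
DEFAULT_N_STATES = 5
DEFAULT_UNIT_LENGTH = 2


@dataclass(frozen=True)
class PKSSpec:
    n_states_per_unit: int = DEFAULT_N_STATES
    n_variable_units: int = 0

    def __post_init__(self) -> None:
        if self.n_states_per_unit < 1:
            raise ValueError("n_states_per_unit must be >= 1")
        if self.n_variable_units < 0:
            raise ValueError("n_variable_units must be >= 0")


def state_count(spec: PKSSpec) -> int:
    """Exact number of reduction-state combinations: states ** variable units."""
    return spec.n_states_per_unit ** spec.n_variable_units


def macrolactone_variable_units(
    ring_size: int, unit_length: int = DEFAULT_UNIT_LENGTH
) -> int:
    """Variable extension units in an idealized N-membered macrolactone.

    ring_size / unit_length units total, minus the one retained as the keto
    anchor.  The ring size must divide evenly into units.
    """
    if ring_size <= 0 or unit_length <= 0:
        raise ValueError("ring_size and unit_length must be positive")
    if ring_size % unit_length != 0:
        raise ValueError(
            f"ring size {ring_size} is not a multiple of unit length {unit_length}"
        )
    return ring_size // unit_length - 1


def macrolactone_state_count(
    ring_size: int,
    n_states_per_unit: int = DEFAULT_N_STATES,
    unit_length: int = DEFAULT_UNIT_LENGTH,
) -> int:
    """Idealized product count for an N-membered macrolactone."""
    spec = PKSSpec(
        n_states_per_unit=n_states_per_unit,
        n_variable_units=macrolactone_variable_units(ring_size, unit_length),
    )
    return state_count(spec)
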