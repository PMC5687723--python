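"""Nearest-neighbor melting temperature (Sugimoto parameters, salt-corrected).

Tm is computed from the two-state nearest-neighbor model::

    Tm(C) = 1000 * dH / (dS + R * ln(C_T / x)) - 273.15 + 16.6 * log10([Na+])

where dH (kcal/mol) and dS (cal/(mol*K)) are sums over the 16 dinucleotide
stacks of the Sugimoto et al. parameter set plus a duplex-initiation term,
R = 1.987 cal/(mol*K), C_T is the primer concentration and x is 4 for
non-self-complementary oligos (1 for self-complementary ones).  The
16.6*log10[Na+] term is the classical monovalent-salt correction.  This is
the equation used by the Oligo Calc web calculator, which this module
mirrors, including its choice to evaluate the primer against a perfectly
complementary strand: engineered primer-template mismatches are ignored in
the Tm (a documented approximation — no mismatch or dangling-end terms).

Defaults: 50 nM primer, 50 mM Na+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .alphabet import is_concrete, reverse_complement

__all__ = [
    "SUGIMOTO_NN",
    "NN_INITIATION",
    "TmParameters",
    "DegenerateBaseInPrimer",
    "PrimerTooShort",
    "melting_temperature",
]

R_GAS = 1.987  # cal / (mol * K)

#: Sugimoto et al. stack parameters: 5'->3' dinucleotide -> (dH kcal/mol, dS cal/(mol*K))
SUGIMOTO_NN: dict[str, tuple[float, float]] = {
    "AA": (-8.0, -21.9),
    "AT": (-5.6, -15.2),
    "TA": (-6.6, -18.4),
    "CA": (-8.2, -21.0),
    "GT": (-9.4, -25.5),
    "CT": (-6.6, -16.4),
    "GA": (-8.8, -23.5),
    "CG": (-11.8, -29.0),
    "GC": (-10.5, -26.4),
    "GG": (-10.9, -28.4),
}
# complementary stacks read off the other strand share the same parameters
for _stack, _vals in list(SUGIMOTO_NN.items()):
    SUGIMOTO_NN.setdefault(reverse_complement(_stack), _vals)

NN_INITIATION: tuple[float, float] = (0.6, -9.0)

MIN_PRIMER_LEN = 8


class DegenerateBaseInPrimer(ValueError):
    pass


class PrimerTooShort(ValueError):
    pass


@dataclass(frozen=True)
class TmParameters:
    """Concentrations and (overridable) stack table for the Tm model.

    ``primer_conc`` and ``na_conc`` are molar.  Defaults are the Oligo Calc
    ones: 50 nM primer, 50 mM sodium.
    """

    primer_conc: float = 50e-9
    na_conc: float = 50e-3
    nn_table: dict[str, tuple[float, float]] = field(default_factory=lambda: SUGIMOTO_NN)
    initiation: tuple[float, float] = NN_INITIATION

    def __post_init__(self):
        if self.primer_conc <= 0 or self.na_conc <= 0:
            raise ValueError("concentrations must be strictly positive")


def melting_temperature(primer: str, params: TmParameters | None = None) -> float:
    """Nearest-neighbor Tm of ``primer`` against its perfect complement, in C.

    Deterministic to well below 0.01 C.  Requires a concrete (ACGT-only)
    primer of at least 8 nt.
    """
    params = params or TmParameters()
    if len(primer) < MIN_PRIMER_LEN:
        raise PrimerTooShort(f"{len(primer)} nt < {MIN_PRIMER_LEN} nt")
    if not is_concrete(primer):
        raise DegenerateBaseInPrimer(primer)

    dh, ds = params.initiation
    for i in range(len(primer) - 1):
        h, s = params.nn_table[primer[i : i + 2]]
        dh += h
        ds += s

    x = 1.0 if primer == reverse_complement(primer) else 4.0
    tm_k = (dh * 1000.0) / (ds + R_GAS * math.log(params.primer_conc / x))
    return tm_k - 273.15 + 16.6 * math.log10(params.na_conc)
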