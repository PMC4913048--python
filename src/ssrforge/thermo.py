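"""Oligonucleotide thermodynamics: GC content and nearest-neighbor Tm.

The melting temperature uses the unified nearest-neighbor parameter set of
Allawi & SantaLucia (Biochemistry 1997, as consolidated in SantaLucia, PNAS
1998): per-stack enthalpies/entropies plus terminal A·T / G·C initiation
terms, an entropic monovalent-salt correction of 0.368·(N−1)·ln[Na+], and

    Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15

with R = 1.987 cal/(K·mol) and C_T the total oligo strand concentration
(non-self-complementary duplex assumption). Divalent-cation and dNTP
corrections are out of scope.
"""

from __future__ import annotations

import math

from ssrforge.errors import DomainError

_ACGT = frozenset("ACGT")

#: minimum oligo length for which the two-state NN model is considered valid
MIN_OLIGO_LENGTH = 8

R_GAS = 1.987  # cal / (K * mol)

# (delta_H kcal/mol, delta_S cal/(K*mol)); key XY means 5'-XY-3' stacked on
# its Watson-Crick complement. Symmetric entries filled via reverse-complement.
NN_UNIFIED = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

INIT_AT = (2.3, 4.1)    # terminal A·T pair
INIT_GC = (0.1, -2.8)   # terminal G·C pair


def _check_acgt(oligo: str, op: str) -> None:
    if not oligo:
        raise DomainError(f"{op}: empty oligo")
    bad = set(oligo) - _ACGT
    if bad:
        raise DomainError(f"{op}: non-ACGT character(s) {sorted(bad)} in {oligo!r}")


def gc_fraction(oligo: str) -> float:
    """GC content as a percentage of an ACGT oligo."""
    _check_acgt(oligo, "gc_fraction")
    gc = sum(1 for c in oligo if c in "GC")
    return 100.0 * gc / len(oligo)


def melting_temperature(
    oligo: str,
    monovalent_mM: float = 50.0,
    oligo_nM: float = 50.0,
) -> float:
    """Nearest-neighbor melting temperature in °C.

    Parameters
    ----------
    oligo : str
        Primer sequence 5'→3', ACGT only, length >= 8.
    monovalent_mM : float
        Total monovalent cation concentration (mM).
    oligo_nM : float
        Total oligo strand concentration (nM).
    """
    _check_acgt(oligo, "melting_temperature")
    n = len(oligo)
    if n < MIN_OLIGO_LENGTH:
        raise DomainError(
            f"melting_temperature: two-state NN model unsupported below "
            f"{MIN_OLIGO_LENGTH} nt (got {n})"
        )
    if monovalent_mM <= 0 or oligo_nM <= 0:
        raise DomainError("melting_temperature: concentrations must be positive")

    d_h = 0.0
    d_s = 0.0
    for end in (oligo[0], oligo[-1]):
        ih, is_ = INIT_AT if end in "AT" else INIT_GC
        d_h += ih
        d_s += is_
    for i in range(n - 1):
        nh, ns = NN_UNIFIED[oligo[i:i + 2]]
        d_h += nh
        d_s += ns

    d_s += 0.368 * (n - 1) * math.log(monovalent_mM / 1000.0)
    c_t = oligo_nM * 1e-9
    return 1000.0 * d_h / (d_s + R_GAS * math.log(c_t / 4.0)) - 273.15
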