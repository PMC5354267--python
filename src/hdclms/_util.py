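"""Shared helpers: rounding conventions and residue alphabets."""

from __future__ import annotations

import math

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues reactive toward the NHS-ester end of sulfo-SDA (besides the N-terminus).
NHS_REACTIVE = frozenset("KSTY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in all reported tables).

    Python's built-in ``round`` is banker's rounding; report tables round
    0.5 up in magnitude instead.
    """
    factor = 10 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor if ndigits else float(rounded)


def int_percent(numerator: float, denominator: float) -> int:
    """Integer percentage, half away from zero; denominator must be nonzero."""
    return int(round_half_away(100.0 * numerator / denominator))


def is_linkable_end(sequence: str, pos: int) -> bool:
    """True if position ``pos`` (1-based) can carry the NHS-ester end of sulfo-SDA."""
    return pos == 1 or sequence[pos - 1] in NHS_REACTIVE


def linkable_pairs(sequence: str, positions=None):
    """All unordered distinct position pairs (i < j, 1-based) with at least one
    sulfo-SDA NHS-reactive end (K/S/T/Y or the N-terminus).

    ``positions`` optionally restricts the universe (e.g. to resolved residues).
    """
    if positions is None:
        positions = range(1, len(sequence) + 1)
    pos = sorted(positions)
    out = []
    for a in range(len(pos)):
        i = pos[a]
        i_ok = is_linkable_end(sequence, i)
        for b in range(a + 1, len(pos)):
            j = pos[b]
            if i_ok or is_linkable_end(sequence, j):
                out.append((i, j))
    return out
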