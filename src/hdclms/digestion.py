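"""In-silico protease digestion and theoretical observability of residues.

Cross-link coverage along a protein is limited by where proteases can cut:
a cross-linked residue can only be seen if it lies on a digest peptide short
enough for LC-MS. This module provides cleavage-site prediction, (co-)digestion
with missed cleavages, the set of residues theoretically observable for a given
peptide-length window, and the link-density summary statistics reported per
target (links per residue, regional densities, long-range fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import AMINO_ACIDS, int_percent, round_half_away


@dataclass(frozen=True)
class EnzymeRule:
    """Protease cleavage specificity: cut after ``cleave_after`` unless the
    next residue is in ``blocked_by_next``."""

    name: str
    cleave_after: frozenset
    blocked_by_next: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for s in (self.cleave_after, self.blocked_by_next):
            bad = set(s) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-canonical residues in enzyme rule: {bad}")


def trypsin(proline_rule: bool = True) -> EnzymeRule:
    """Classical trypsin: cut after K/R, optionally blocked before proline."""
    return EnzymeRule("trypsin", frozenset("KR"),
                      frozenset("P") if proline_rule else frozenset())


def glu_c(cleave_d: bool = False) -> EnzymeRule:
    """Glu-C (V8): cut after E; after D as well under phosphate-buffer specificity."""
    return EnzymeRule("glu-c", frozenset("DE" if cleave_d else "E"))


@dataclass(frozen=True)
class DigestPeptide:
    """A digest product, 1-based inclusive coordinates."""

    start: int
    end: int
    missed_cleavages: int
    enzymes: frozenset

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def cleavage_sites(sequence: str, rule: EnzymeRule,
                   on_noncanonical: str = "fail") -> list[int]:
    """1-based positions i after which ``rule`` cuts; the C-terminus is never a site.

    ``on_noncanonical``: "fail" raises on residues outside the 20-letter
    alphabet, "skip" treats them as non-cleavable.
    """
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        if on_noncanonical == "fail":
            raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
        if on_noncanonical != "skip":
            raise ValueError("on_noncanonical must be 'fail' or 'skip'")
    sites = []
    for i in range(1, len(sequence)):  # position len(sequence) excluded
        if sequence[i - 1] in rule.cleave_after and sequence[i] not in rule.blocked_by_next:
            sites.append(i)
    return sites


def digest(sequence: str, rules: Sequence[EnzymeRule] | EnzymeRule,
           max_missed: int = 0, on_noncanonical: str = "fail") -> list[DigestPeptide]:
    """All peptides delimited by the union of the rules' cleavage sites, with up
    to ``max_missed`` internal (missed) sites. Co-digestion = union of sites."""
    if isinstance(rules, EnzymeRule):
        rules = [rules]
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = sorted({s for r in rules for s in cleavage_sites(sequence, r, on_noncanonical)})
    names = frozenset(r.name for r in rules)
    bounds = [0] + sites + [len(sequence)]
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 1 + max_missed + 1, len(bounds))):
            peptides.append(DigestPeptide(bounds[a] + 1, bounds[b], b - a - 1, names))
    return peptides


def observable_residue_set(sequence: str, rules, len_min: int = 5, len_max: int = 45,
                           max_missed: int = 0) -> set[int]:
    """Residues lying on at least one digest peptide with length in
    [len_min, len_max]; the complement is theoretically inaccessible."""
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    observable: set[int] = set()
    for pep in digest(sequence, rules, max_missed):
        if len_min <= pep.length <= len_max:
            observable.update(range(pep.start, pep.end + 1))
    return observable


def links_per_residue(n_pairs: int, n_residues: int) -> float:
    """Unique residue pairs per residue, reported to 2 decimals
    (half away from zero)."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return round_half_away(n_pairs / n_residues, 2)


def region_link_density(pairs: Iterable[tuple[int, int]], region: tuple[int, int],
                        mode: str = "either") -> float:
    """Cross-link density of a sequence region: pairs touching the region per
    region residue, to 2 decimals.

    ``mode='either'`` counts a pair once if either end falls in the (1-based,
    inclusive) region; ``'both'`` requires both ends inside.
    """
    lo, hi = region
    if hi < lo:
        raise ValueError("empty region")
    if mode == "either":
        n = sum(1 for i, j in pairs if lo <= i <= hi or lo <= j <= hi)
    elif mode == "both":
        n = sum(1 for i, j in pairs if lo <= i <= hi and lo <= j <= hi)
    else:
        raise ValueError("mode must be 'either' or 'both'")
    return round_half_away(n / (hi - lo + 1), 2)


def long_range_fraction(pairs: Sequence[tuple[int, int]], min_sep: int = 11
                        ) -> tuple[int, int]:
    """(count, integer percent) of pairs strictly more than ``min_sep`` residues
    apart in sequence — the links that matter most for modelling."""
    pairs = list(pairs)
    count = sum(1 for i, j in pairs if abs(i - j) > min_sep)
    percent = int_percent(count, len(pairs)) if pairs else 0
    return count, percent
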