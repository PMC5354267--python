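"""Cross-link validation against crystal structures.

An observed sulfo-SDA cross-link is interpreted as an upper bound of 25 Å on
the Cα–Cα distance between the linked residues (the distance at which observed
cross-link distance distributions merge with those of decoy matches). Links
mapped onto a structure fall into three classes: *within* the bound, *over* it
(violations, reported as a percentage of the verifiable links), or
*unverifiable* when either residue is unresolved in the crystal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from ._util import THREE_TO_ONE, ONE_TO_THREE, int_percent, linkable_pairs
from .digestion import links_per_residue, long_range_fraction

DEFAULT_THRESHOLD = 25.0  # Å, Cα–Cα


@dataclass
class Residue:
    """One residue of a structure model; ``ca`` is None when unresolved."""

    seq_pos: int
    amino_acid: str
    ca: np.ndarray | None = None
    atoms: dict = field(default_factory=dict)  # name -> xyz, for full-atom models
    ss: str = "C"

    @property
    def resolved(self) -> bool:
        return self.ca is not None


class StructureModel:
    """Per-residue Cα (optionally full-atom) coordinates indexed by 1-based
    sequence position; unresolved residues keep their number without
    coordinates, matching PDB semantics."""

    def __init__(self, residues: Sequence[Residue]):
        residues = sorted(residues, key=lambda r: r.seq_pos)
        if any(b.seq_pos <= a.seq_pos for a, b in zip(residues, residues[1:])):
            raise ValueError("residue positions must be strictly increasing")
        self.residues = list(residues)
        self._by_pos = {r.seq_pos: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> Residue:
        return self._by_pos[pos]

    def __contains__(self, pos: int) -> bool:
        return pos in self._by_pos

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def resolved_positions(self) -> list[int]:
        return [r.seq_pos for r in self.residues if r.resolved]

    def ca_array(self) -> np.ndarray:
        """Coordinates of resolved residues, ordered by position."""
        return np.array([r.ca for r in self.residues if r.resolved])


def read_structure(pdb_text: str, chain_selector: str | None = None,
                   seq: str | None = None) -> StructureModel:
    """Parse a PDB text into a single-chain :class:`StructureModel`.

    The first chain is used unless ``chain_selector`` names one. Alternate
    locations keep the highest-occupancy CA (ties: first encountered).
    Insertion codes are rejected. If ``seq`` is given, author numbering is
    mapped onto it by the unique constant offset under which every resolved
    residue matches the sequence exactly.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError("no model/chain in PDB input")
    model = st[0]
    if chain_selector is None:
        chain = model[0]
    else:
        names = [ch.name for ch in model]
        if chain_selector not in names:
            raise ValueError(f"chain {chain_selector!r} not found (have {names})")
        chain = model[names.index(chain_selector)]

    residues = []
    for res in chain:
        if res.het_flag == "H" and res.name not in THREE_TO_ONE:
            continue  # waters/ligands
        if res.seqid.icode not in (" ", "\x00", ""):
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: "
                "renumber the structure explicitly")
        aa = THREE_TO_ONE.get(res.name, "X")
        best_ca = None
        atoms: dict = {}
        for atom in res:
            if atom.name == "CA":
                if best_ca is None or atom.occ > best_ca.occ:
                    best_ca = atom
            elif atom.altloc in ("", "\x00", "A"):
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if best_ca is None:
            continue  # CA-less residue: treat as unresolved (not listed)
        ca = np.array([best_ca.pos.x, best_ca.pos.y, best_ca.pos.z])
        residues.append(Residue(res.seqid.num, aa, ca, atoms))
    if not residues:
        raise ValueError("no CA atoms found")

    if seq is not None:
        offsets = set()
        n = len(seq)
        lo = 1 - min(r.seq_pos for r in residues)
        hi = n - max(r.seq_pos for r in residues)
        for off in range(lo, hi + 1):
            if all(seq[r.seq_pos + off - 1] == r.amino_acid for r in residues):
                offsets.add(off)
        if not offsets:
            mism = [(r.seq_pos, r.amino_acid) for r in residues
                    if not (1 <= r.seq_pos <= n) or seq[r.seq_pos - 1] != r.amino_acid]
            raise ValueError(
                f"structure cannot be aligned to the sequence; residues "
                f"mismatching at offset 0: {mism[:10]}")
        off = min(offsets)
        full = [Residue(p, seq[p - 1]) for p in range(1, n + 1)]
        for r in residues:
            full[r.seq_pos + off - 1] = Residue(r.seq_pos + off, r.amino_acid,
                                                r.ca, r.atoms)
        residues = full
    return StructureModel(residues)


def write_pdb(model: StructureModel, chain: str = "A") -> str:
    """Standard ATOM records for the resolved residues (CA, plus any extra
    atoms of full-atom models)."""
    lines = []
    serial = 0
    for r in model.residues:
        if not r.resolved:
            continue
        res3 = ONE_TO_THREE.get(r.amino_acid, "UNK")
        for name, xyz in [("CA", r.ca)] + [(n, x) for n, x in r.atoms.items()
                                           if n != "CA"]:
            serial += 1
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{res3:>4s} {chain}{r.seq_pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def ca_distance(model: StructureModel, i: int, j: int) -> float | None:
    """Euclidean Cα–Cα distance in Å, or None if either residue is unresolved."""
    if i not in model or j not in model:
        raise KeyError(f"position out of range: {(i, j)}")
    ri, rj = model[i], model[j]
    if not (ri.resolved and rj.resolved):
        return None
    return float(np.linalg.norm(ri.ca - rj.ca))


@dataclass(frozen=True)
class LinkClassification:
    pair: tuple
    distance: float | None
    link_class: str  # within | over | unverifiable
    threshold: float


def classify_links(pairs: Iterable[tuple[int, int]], model: StructureModel,
                   threshold: float = DEFAULT_THRESHOLD
                   ) -> tuple[list[LinkClassification], dict]:
    """Classify each residue pair against the distance bound.

    The summary's ``percent_over`` uses only verifiable links in the
    denominator (unverifiable ones are a separate class, not errors); it is
    None when nothing is verifiable.
    """
    rows = []
    for i, j in pairs:
        d = ca_distance(model, i, j)
        if d is None:
            cls = "unverifiable"
        else:
            cls = "within" if d <= threshold else "over"
        rows.append(LinkClassification((i, j), d, cls, threshold))
    counts = {c: sum(1 for r in rows if r.link_class == c)
              for c in ("within", "over", "unverifiable")}
    verifiable = counts["within"] + counts["over"]
    summary = {
        "n_pairs": len(rows),
        **counts,
        "percent_over": int_percent(counts["over"], verifiable) if verifiable else None,
    }
    return rows, summary


def random_distance_distribution(model: StructureModel, sequence: str,
                                 n_samples: int, seed: int) -> np.ndarray:
    """Cα distances of sulfo-SDA-linkable residue pairs sampled uniformly with
    replacement (both ends resolved) — the null distribution an observed link
    set is compared against."""
    pool = linkable_pairs(sequence, model.resolved_positions())
    if not pool:
        raise ValueError("no linkable resolved pairs in structure")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=n_samples)
    return np.array([ca_distance(model, *pool[k]) for k in idx])


@dataclass
class ValidationReport:
    """Machine-readable bundle of the per-target validation numbers."""

    classifications: list
    summary: dict
    long_range: tuple
    links_per_residue: float
    observed_hist: np.ndarray
    random_hist: np.ndarray
    bin_edges: np.ndarray
    threshold: float
    min_sep: int

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "long_range_count": self.long_range[0],
            "long_range_percent": self.long_range[1],
            "links_per_residue": self.links_per_residue,
            "threshold_A": self.threshold,
            "min_seq_separation": self.min_sep,
        }

    def histogram_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "observed_count": self.observed_hist, "random_count": self.random_hist,
        })


def validation_report(pairs: Sequence[tuple[int, int]], model: StructureModel,
                      sequence: str | None = None,
                      threshold: float = DEFAULT_THRESHOLD, min_sep: int = 11,
                      n_random: int = 10_000, seed: int = 0) -> ValidationReport:
    """Full per-target validation: link classes, long-range fraction, link
    density and observed-vs-random Cα distance histograms (1 Å bins)."""
    sequence = sequence if sequence is not None else model.sequence
    rows, summary = classify_links(pairs, model, threshold)
    observed = np.array([r.distance for r in rows if r.distance is not None])
    random_d = (random_distance_distribution(model, sequence, n_random, seed)
                if len(model.resolved_positions()) >= 2 else np.array([]))
    top = max([threshold + 1.0, *observed.tolist(), *random_d.tolist()])
    edges = np.arange(0.0, np.ceil(top) + 1.0, 1.0)
    obs_h, _ = np.histogram(observed, bins=edges)
    rnd_h, _ = np.histogram(random_d, bins=edges)
    return ValidationReport(
        classifications=rows, summary=summary,
        long_range=long_range_fraction(list(pairs), min_sep),
        links_per_residue=(links_per_residue(len(list(pairs)), len(sequence))
                           if len(sequence) else 0.0),
        observed_hist=obs_h, random_hist=rnd_h, bin_edges=edges,
        threshold=threshold, min_sep=min_sep,
    )
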