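"""Secondary-structure and solvent-accessibility bias of cross-link data.

Photo-cross-linking under-samples β-sheet regions: the observed fraction of
residue pairs touching a β-strand falls short of the fraction expected if
links were drawn without structural bias. This module quantifies that
comparison (observed vs combinatorial expectation), the K/R content of
structure classes (tryptic-site density), and relative solvent accessibility
(RSA) — residue surface area from sphere-dot (Shrake–Rupley) sampling divided
by a theoretical Gly-X-Gly maximum per residue type.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._util import NHS_REACTIVE, int_percent, linkable_pairs
from .structure import StructureModel

PROBE_RADIUS = 1.4  # Å, water probe
N_DOTS = 960

#: van der Waals radii by element for the full-atom surface
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

_DSSP_COLLAPSE = {"E": "E", "B": "E", "H": "H", "G": "H", "I": "H"}


def _max_asa_table() -> dict:
    with resources.files("hdclms.data").joinpath("max_asa.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df.aa, df.max_asa))


MAX_ASA = _max_asa_table()


@dataclass(frozen=True)
class SSAnnotation:
    """Per-residue secondary structure: E (β-strand), H (helix), C (coil)."""

    labels: str
    source: str = "external_file"

    def __post_init__(self):
        bad = set(self.labels) - set("EHC")
        if bad:
            raise ValueError(f"labels must be E/H/C, got {bad}")

    def __len__(self):
        return len(self.labels)


def collapse_dssp(code: str) -> str:
    """Collapse an 8-state DSSP code to E/H/C."""
    return _DSSP_COLLAPSE.get(code.upper(), "C")


def read_ss_table(path, sep: str = "\t") -> SSAnnotation:
    """Read a (position, label) table of DSSP-style codes; positions must be
    1..n contiguous."""
    df = pd.read_csv(path, sep=sep).sort_values("position")
    if list(df.position) != list(range(1, len(df) + 1)):
        raise ValueError("positions must be contiguous from 1")
    return SSAnnotation("".join(collapse_dssp(c) for c in df.label), "external_file")


def assign_ss(model: StructureModel) -> SSAnnotation:
    """Geometry-only fallback assigner from Cα coordinates.

    The i -> i+3 Cα distance is ~5.0–6.5 Å in an α-helix and ~9–11 Å in an
    extended strand; each window votes for the four residues it covers and
    any structured evidence beats coil (E wins E-vs-H ties, since a single
    covering window is all a strand terminus ever gets). Extended loops are
    geometrically strand-like at this resolution, so the fallback over-calls
    E in loop regions; external annotations remain canonical. Unresolved
    residues are coil.
    """
    n = len(model)
    votes = [dict.fromkeys("EHC", 0) for _ in range(n)]
    residues = model.residues
    for a in range(n - 3):
        r1, r2 = residues[a], residues[a + 3]
        if not (r1.resolved and r2.resolved):
            continue
        d = float(np.linalg.norm(r1.ca - r2.ca))
        if 5.0 <= d <= 6.5:
            lab = "H"
        elif 9.0 <= d <= 11.0:
            lab = "E"
        else:
            lab = "C"
        for k in range(a, a + 4):
            votes[k][lab] += 1
    labels = []
    for r, v in zip(residues, votes):
        if not r.resolved or not any(v.values()):
            labels.append("C")
        elif v["E"] > 0 and v["E"] >= v["H"]:
            labels.append("E")
        elif v["H"] > 0:
            labels.append("H")
        else:
            labels.append("C")
    return SSAnnotation("".join(labels), "builtin_assigner")


def _labels(ss) -> str:
    return ss.labels if isinstance(ss, SSAnnotation) else str(ss)


def beta_residue_fraction(ss) -> int:
    """Integer percentage of residues labelled β-strand."""
    labels = _labels(ss)
    if not labels:
        raise ValueError("empty annotation")
    return int_percent(labels.count("E"), len(labels))


def observed_pair_beta_fraction(pairs, ss, mode: str = "at_least_one"
                                ) -> tuple[int, int]:
    """(count, integer percent) of residue pairs whose ends touch a β-strand:
    ``at_least_one`` end, or ``both`` ends."""
    labels = _labels(ss)
    pairs = list(pairs)

    def hit(i, j):
        a, b = labels[i - 1] == "E", labels[j - 1] == "E"
        return (a or b) if mode == "at_least_one" else (a and b)

    if mode not in ("at_least_one", "both"):
        raise ValueError("mode must be 'at_least_one' or 'both'")
    count = sum(1 for i, j in pairs if hit(i, j))
    return count, (int_percent(count, len(pairs)) if pairs else 0)


def expected_pair_beta_fraction(ss, mode: str = "at_least_one",
                                universe: str = "all_pairs",
                                sequence: str | None = None) -> float:
    """Percentage of pairs that would touch a β-strand if links were drawn
    uniformly from the universe (no structural bias).

    ``all_pairs`` uses the closed combinatorial form over all unordered
    distinct pairs; ``linkable_pairs`` enumerates sulfo-SDA-linkable pairs and
    needs the sequence. Returned unrounded (percent).
    """
    labels = _labels(ss)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two residues")
    if universe == "all_pairs":
        b = labels.count("E")
        if mode == "at_least_one":
            return 100.0 * (1.0 - comb(n - b, 2) / comb(n, 2))
        if mode == "both":
            return 100.0 * comb(b, 2) / comb(n, 2)
        raise ValueError("mode must be 'at_least_one' or 'both'")
    if universe == "linkable_pairs":
        if sequence is None or len(sequence) != n:
            raise ValueError("linkable_pairs universe needs the aligned sequence")
        pool = linkable_pairs(sequence)
        count, _ = observed_pair_beta_fraction(pool, labels, mode)
        return 100.0 * count / len(pool)
    raise ValueError("universe must be 'all_pairs' or 'linkable_pairs'")


def kr_content_by_class(sequence: str, ss) -> dict:
    """K+R (tryptic-site) content overall, within β-strands, and outside them
    — integer percentages with the underlying counts."""
    labels = _labels(ss)
    if len(labels) != len(sequence):
        raise ValueError("sequence and annotation lengths differ")
    groups = {"overall": sequence,
              "strand": "".join(a for a, l in zip(sequence, labels) if l == "E"),
              "other": "".join(a for a, l in zip(sequence, labels) if l != "E")}
    out = {}
    for name, chunk in groups.items():
        kr = sum(1 for a in chunk if a in "KR")
        out[name] = {"percent": int_percent(kr, len(chunk)) if chunk else 0,
                     "kr_count": kr, "n_residues": len(chunk)}
    return out


# ------------------------------------------------------------------- RSA

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _sasa(centers: np.ndarray, radii: np.ndarray, n_dots: int,
          probe: float) -> np.ndarray:
    """Per-atom solvent-accessible surface area by dot sampling."""
    dots = _fibonacci_sphere(n_dots)
    ext = radii + probe
    tree = cKDTree(centers)
    areas = np.zeros(len(centers))
    rmax = ext.max()
    for i in range(len(centers)):
        pts = centers[i] + ext[i] * dots
        neigh = [j for j in tree.query_ball_point(centers[i], ext[i] + rmax)
                 if j != i]
        exposed = np.ones(n_dots, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * exposed.sum() / n_dots
    return areas


def atom_sasa(centers, radii, n_dots: int = N_DOTS, probe: float = PROBE_RADIUS
              ) -> np.ndarray:
    """Public wrapper: SASA (Å²) per atom for arbitrary sphere sets."""
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    return _sasa(centers, radii, n_dots, probe)


def ca_sphere_radius(aa: str, probe: float = PROBE_RADIUS) -> float:
    """Effective one-sphere residue radius for the Cα-only approximation,
    chosen so an isolated residue's accessible area equals its theoretical
    maximum."""
    return max(np.sqrt(MAX_ASA.get(aa, 180.0) / (4 * np.pi)) - probe, 1.0)


def compute_rsa(model: StructureModel, n_dots: int = N_DOTS,
                probe: float = PROBE_RADIUS) -> np.ndarray:
    """Relative solvent accessibility per residue (fraction, NaN when
    unresolved), capped at 1.5.

    Full-atom models sum atomic SASA over each residue's atoms with element
    van der Waals radii; Cα-only models fall back to one sphere per residue
    with a residue-specific radius — an approximation, adequate for
    buried-vs-exposed contrasts but not atomic detail.
    """
    resolved = [r for r in model.residues if r.resolved]
    if not resolved:
        raise ValueError("no resolved residues")
    full_atom = all(len(r.atoms) > 0 for r in resolved)
    centers, radii, owner = [], [], []
    for k, r in enumerate(resolved):
        if full_atom:
            for name, xyz in [("CA", r.ca)] + list(r.atoms.items()):
                centers.append(xyz)
                radii.append(VDW_RADII.get(name.strip()[0], 1.7))
                owner.append(k)
        else:
            centers.append(r.ca)
            radii.append(ca_sphere_radius(r.amino_acid, probe))
            owner.append(k)
    areas = _sasa(np.array(centers), np.array(radii), n_dots, probe)
    per_res = np.zeros(len(resolved))
    np.add.at(per_res, owner, areas)

    rsa = np.full(len(model), np.nan)
    pos_index = {r.seq_pos: i for i, r in enumerate(model.residues)}
    for k, r in enumerate(resolved):
        rsa[pos_index[r.seq_pos]] = min(per_res[k] / MAX_ASA.get(r.amino_acid, 180.0),
                                        1.5)
    return rsa


def rsa_summary(rsa: np.ndarray, ss, sequence: str | None = None,
                residue_subset: set | None = None) -> dict:
    """Mean RSA (percent) of β-strand vs all other residues, optionally
    restricted to a residue-type subset (e.g. the NHS-reactive K/S/T/Y).
    Empty classes report None."""
    labels = _labels(ss)
    if residue_subset is not None and sequence is None:
        raise ValueError("residue_subset needs the sequence")
    out = {}
    for name, want_e in (("strand", True), ("other", False)):
        vals = []
        for i, v in enumerate(rsa):
            if np.isnan(v):
                continue
            if (labels[i] == "E") != want_e:
                continue
            if residue_subset is not None and sequence[i] not in residue_subset:
                continue
            vals.append(v)
        out[name] = {"mean_rsa_percent": (100.0 * float(np.mean(vals))
                                          if vals else None),
                     "n": len(vals)}
    return out


def nhs_reactive_subset() -> set:
    return set(NHS_REACTIVE)
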