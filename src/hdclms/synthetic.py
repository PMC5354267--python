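"""Synthetic cross-linking study generator.

Builds toy protein targets — sequence, idealized Cα structure, secondary
structure, sulfo-SDA-linkable true cross-links — and simulates scored
target/decoy PSM tables over multiple LC-MS runs with a *known* true/false
composition. Every downstream stage (FDR estimation, distance validation,
saturation, digestion coverage, bias analysis) can therefore be tested against
ground truth without any external data.

Geometry uses ideal secondary-structure parameters: an α-helix rises 1.5 Å per
residue on a 2.3 Å radius (≈3.8 Å between consecutive Cα), a β-strand rises
3.3 Å per residue, and connecting loops are circular arcs with exact 3.5 Å
steps, so consecutive Cα–Cα distances always stay within the virtual-bond
convention of 3.8 ± 0.8 Å.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._util import AMINO_ACIDS, linkable_pairs, round_half_away
from .structure import Residue, StructureModel

FOLDS = ("helix-bundle", "beta-sandwich", "mixed")

_HELIX_RISE, _HELIX_RADIUS, _HELIX_TURN = 1.5, 2.3, math.radians(100.0)
_STRAND_RISE, _STRAND_WOBBLE = 3.3, 0.5
_LOOP_STEP = 3.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated cross-linking study.

    Score distributions are (location, scale) of Gaussians truncated at zero;
    defaults give true and false populations that overlap enough to make FDR
    estimation non-trivial. ``capture_prob`` is the probability that any one
    LC-MS run records a given PSM event, producing partially overlapping runs.
    """

    n_residues: int = 150
    fold_spec: str = "mixed"
    n_runs: int = 4
    n_true_psms: int = 2000
    n_false_psms: int = 600
    true_score_dist: tuple = (12.0, 2.0)
    false_score_dist: tuple = (6.0, 2.0)
    unresolved_fraction: float = 0.1
    capture_prob: float = 0.5
    decoy_td_share: float = 0.8
    decoy_multiplier: float | None = None
    protocols: tuple = ("trypsin",)
    backbone: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 20:
            raise ValueError("n_residues must be >= 20")
        if self.fold_spec not in FOLDS:
            raise ValueError(f"fold_spec must be one of {FOLDS}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for frac in (self.unresolved_fraction, self.capture_prob, self.decoy_td_share):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for loc, scale in (self.true_score_dist, self.false_score_dist):
            if loc < 0 or scale <= 0:
                raise ValueError("score distributions must have non-negative "
                                 "location and positive scale (scores are >= 0)")
        if self.decoy_multiplier is None and self.decoy_td_share <= 0.5:
            raise ValueError("decoy_td_share <= 0.5 needs an explicit "
                             "decoy_multiplier (see effective_decoy_multiplier)")

    @property
    def effective_decoy_multiplier(self) -> float:
        """Decoy events per false-target event.

        The (TD - DD)/TT estimator is unbiased only when E[TD - DD] equals the
        number of false target matches; with a TD share s among decoys that
        requires n_decoys = n_false / (2s - 1) — the count an equal-size decoy
        database produces in a real search. Override via ``decoy_multiplier``
        to simulate a deliberately mis-sized decoy model.
        """
        if self.decoy_multiplier is not None:
            return self.decoy_multiplier
        return 1.0 / (2.0 * self.decoy_td_share - 1.0)


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    true_links: set
    psm_labels: dict  # psm_id -> "true" | "false" | "decoy"

    def realized_false_fraction(self, accepted_pairs) -> float:
        """Fraction of accepted residue pairs that are not genuine links."""
        accepted = list(accepted_pairs)
        if not accepted:
            return 0.0
        wrong = sum(1 for p in accepted if tuple(sorted(p)) not in self.true_links)
        return wrong / len(accepted)


# ------------------------------------------------------------------ geometry

def _arc_points(start: np.ndarray, stop: np.ndarray, m: int) -> list[np.ndarray]:
    """m-1 interior points on a circular arc from start to stop such that all
    m chords have length exactly ``_LOOP_STEP``."""
    d = float(np.linalg.norm(stop - start))
    c = _LOOP_STEP
    if d >= m * c - 1e-9:  # (near-)straight line
        return [start + (stop - start) * k / m for k in range(1, m)]
    u = (stop - start) / d if d > 1e-9 else np.array([1.0, 0.0, 0.0])
    w = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, w)) > 0.9:
        w = np.array([1.0, 0.0, 0.0])
    v = w - np.dot(w, u) * u
    v /= np.linalg.norm(v)

    def gap(theta):
        return math.sin(m * theta / 2) / math.sin(theta / 2) - d / c

    theta = brentq(gap, 1e-9, 2 * math.pi / m - 1e-9)
    radius = c / (2 * math.sin(theta / 2))
    mid = (start + stop) / 2
    h = radius * math.cos(m * theta / 2)
    center = mid - v * h
    pts = []
    for k in range(1, m):
        g = -m * theta / 2 + k * theta
        pts.append(center + radius * (math.sin(g) * u + math.cos(g) * v))
    return pts


def _segment_coords(kind: str, length: int, origin: np.ndarray, up: bool
                    ) -> np.ndarray:
    t = np.arange(length)
    if kind == "H":
        ang = _HELIX_TURN * t
        x = origin[0] + _HELIX_RADIUS * np.cos(ang)
        y = origin[1] + _HELIX_RADIUS * np.sin(ang)
        z = _HELIX_RISE * t
    else:  # strand
        x = origin[0] + _STRAND_WOBBLE * np.where(t % 2 == 0, 1.0, -1.0)
        y = np.full(length, origin[1])
        z = _STRAND_RISE * t
    if not up:
        z = z.max() - z
    return np.column_stack([x, y, z + origin[2]])


_FOLD_PLAN = {
    # (cycle of segment kinds, segment length, lateral spacing, grid width)
    "helix-bundle": (("H",), 14, 8.0, 4),
    "beta-sandwich": (("E",), 8, 5.5, 4),
    "mixed": (("H", "E"), 11, 7.0, 4),
}


def _build_fold(n: int, fold_spec: str) -> tuple[np.ndarray, str]:
    kinds, seg_len, spacing, width = _FOLD_PLAN[fold_spec]
    coords: list[np.ndarray] = []
    labels: list[str] = []
    k = 0
    while len(coords) < n:
        kind = kinds[k % len(kinds)]
        col, row = k % width, k // width
        origin = np.array([col * spacing, row * spacing, 0.0])
        seg = _segment_coords(kind, seg_len, origin, up=(k % 2 == 0))
        if k > 0:  # connecting loop from previous segment end
            start, stop = coords[-1], seg[0]
            d = float(np.linalg.norm(stop - start))
            m = max(2, math.ceil(d / _LOOP_STEP))
            for p in _arc_points(start, stop, m):
                if len(coords) >= n:
                    break
                coords.append(p)
                labels.append("C")
        take = min(seg_len, n - len(coords))
        for i in range(take):
            coords.append(seg[i])
            labels.append(kind)
        k += 1
    return np.array(coords[:n]), "".join(labels[:n])


def _ideal_backbone(coords: np.ndarray, sequence: str) -> list[dict]:
    """Approximate N, C, O, Cβ placement around each Cα from local chain
    direction — crude but sufficient for surface-area tests."""
    n = len(coords)
    out = []
    for i in range(n):
        prev_d = coords[i] - coords[i - 1] if i > 0 else coords[i] - coords[i + 1]
        next_d = coords[i + 1] - coords[i] if i < n - 1 else coords[i] - coords[i - 1]
        prev_u = prev_d / (np.linalg.norm(prev_d) + 1e-12)
        next_u = next_d / (np.linalg.norm(next_d) + 1e-12)
        side = np.cross(prev_u, next_u)
        if np.linalg.norm(side) < 1e-6:
            side = np.cross(next_u, [0.0, 0.0, 1.0])
            if np.linalg.norm(side) < 1e-6:
                side = np.cross(next_u, [1.0, 0.0, 0.0])
        side /= np.linalg.norm(side)
        atoms = {
            "N": coords[i] - prev_u * 1.45,
            "C": coords[i] + next_u * 1.52,
            "O": coords[i] + next_u * 1.52 + side * 1.23,
        }
        if sequence[i] != "G":
            atoms["CB"] = coords[i] + side * 1.53
        out.append(atoms)
    return out


def make_structure(config: SyntheticConfig
                   ) -> tuple[StructureModel, str, str]:
    """Generate (structure, secondary-structure labels, sequence).

    Exactly round(unresolved_fraction x n) residues are unresolved: they keep
    their sequence number but carry no coordinates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    coords, labels = _build_fold(n, config.fold_spec)
    backbone = _ideal_backbone(coords, seq) if config.backbone else [{}] * n

    n_unres = int(round_half_away(config.unresolved_fraction * n))
    unresolved = set(rng.choice(n, size=n_unres, replace=False)) if n_unres else set()
    residues = []
    for i in range(n):
        if i in unresolved:
            residues.append(Residue(i + 1, seq[i], None, {}, labels[i]))
        else:
            residues.append(Residue(i + 1, seq[i], coords[i].copy(),
                                    dict(backbone[i]), labels[i]))
    return StructureModel(residues), labels, seq


def make_true_links(structure: StructureModel, sequence: str,
                    threshold: float = 25.0) -> set:
    """All genuinely cross-linkable residue pairs of the structure: one end
    K/S/T/Y or the N-terminus, both resolved, Cα–Cα <= threshold; normalized
    to i < j."""
    links = set()
    resolved = structure.resolved_positions()
    for i, j in linkable_pairs(sequence, resolved):
        d = np.linalg.norm(structure[i].ca - structure[j].ca)
        if d <= threshold:
            links.add((i, j))
    return links


# --------------------------------------------------------------- PSM tables

def _peptide_window(sequence: str, pos: int, flank: int = 3
                    ) -> tuple[str, int]:
    start = max(0, pos - 1 - flank)
    end = min(len(sequence), pos + flank + 1)
    return sequence[start:end], pos - start


def _truncated_scores(rng, dist: tuple, size: int) -> np.ndarray:
    loc, scale = dist
    a = (0.0 - loc) / scale
    return truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=size,
                         random_state=rng)


def simulate_psms(truth_links: set, sequence: str, config: SyntheticConfig
                  ) -> tuple[list, GroundTruth]:
    """Simulate scored target/decoy PSMs.

    True PSM events sample residue pairs from ``truth_links`` with scores from
    the true distribution; false events sample uniformly among non-true
    linkable pairs; decoy events carry decoy flags (80%/20% TD/DD by default)
    with false-distribution scores, their count scaled so that E[TD - DD]
    matches the false-target count (see
    :attr:`SyntheticConfig.effective_decoy_multiplier`). Each event is captured independently by every run
    with ``capture_prob`` (one PSM row per capturing run); uncaptured events
    vanish. Returns (PSMs, ground truth).
    """
    from .fdr import PSM  # local import to avoid a cycle

    if config.n_true_psms > 0 and not truth_links:
        raise ValueError("truth_links must be non-empty when n_true_psms > 0")
    rng = np.random.default_rng(config.seed + 1)
    truth_list = sorted(truth_links)
    # false and decoy events are random matches over the SAME universe of
    # non-true linkable pairs — the symmetry the target-decoy estimator
    # relies on (in real data the random-match space is so large that hits
    # on genuine links are negligible)
    pool = sorted(p for p in linkable_pairs(sequence) if p not in truth_links)
    if not pool:
        pool = sorted(linkable_pairs(sequence))

    events = []  # (label, pair, n_decoy_ends)
    if truth_list:
        for idx in rng.integers(0, len(truth_list), size=config.n_true_psms):
            events.append(("true", truth_list[idx], 0))
    for idx in rng.integers(0, len(pool), size=config.n_false_psms):
        events.append(("false", pool[idx], 0))
    n_decoys = int(round_half_away(config.n_false_psms
                                   * config.effective_decoy_multiplier))
    dd = rng.random(n_decoys) >= config.decoy_td_share  # True -> double decoy
    for k, idx in enumerate(rng.integers(0, len(pool), size=n_decoys)):
        events.append(("decoy", pool[idx], 2 if dd[k] else 1))

    psms: list = []
    labels: dict = {}
    for evt, (label, pair, n_dec) in enumerate(events):
        captured = np.nonzero(rng.random(config.n_runs) < config.capture_prob)[0]
        if captured.size == 0:
            continue
        dist = config.true_score_dist if label == "true" else config.false_score_dist
        scores = _truncated_scores(rng, dist, captured.size)
        protocol = str(rng.choice(list(config.protocols)))
        i, j = pair
        pep_a, rel_a = _peptide_window(sequence, i)
        pep_b, rel_b = _peptide_window(sequence, j)
        dec_a = n_dec >= 1
        dec_b = n_dec == 2
        if dec_a:
            pep_a = pep_a[::-1]  # reversed-sequence decoy peptide
        if dec_b:
            pep_b = pep_b[::-1]
        for run, score in zip(captured, scores):
            psm_id = f"psm{evt:06d}r{run}"
            psms.append(PSM(psm_id, f"run{run + 1}", pep_a, pep_b, rel_a, rel_b,
                            i, j, float(score), dec_a, dec_b, protocol=protocol))
            labels[psm_id] = label
    return psms, GroundTruth(set(truth_links), labels)


def simulate_study(config: SyntheticConfig, threshold: float = 25.0):
    """One call for the full study: structure, labels, sequence, truth and PSMs."""
    structure, ss, seq = make_structure(config)
    truth = make_true_links(structure, seq, threshold)
    psms, ground = simulate_psms(truth, seq, config)
    return structure, ss, seq, psms, ground


# ---------------------------------------------------------------------- I/O

def psms_to_frame(psms) -> pd.DataFrame:
    rows = [{"psm_id": p.psm_id, "run_id": p.run_id, "pep_seq_a": p.peptide_a,
             "pep_seq_b": p.peptide_b, "link_pos_a": p.link_pos_a,
             "link_pos_b": p.link_pos_b, "prot_pos_a": p.prot_pos_a,
             "prot_pos_b": p.prot_pos_b, "score": p.score,
             "is_decoy_a": p.is_decoy_a, "is_decoy_b": p.is_decoy_b,
             "protocol": p.protocol} for p in psms]
    return pd.DataFrame(rows)


def write_psm_table(psms, path, sep: str = "\t") -> None:
    psms_to_frame(psms).to_csv(path, sep=sep, index=False)


def write_fasta(sequence: str, path, name: str = "synthetic_target") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")


def write_ss_table(ss: str, path, sep: str = "\t") -> None:
    pd.DataFrame({"position": range(1, len(ss) + 1), "label": list(ss)}
                 ).to_csv(path, sep=sep, index=False)


def write_ground_truth(ground: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump({"true_links": sorted(map(list, ground.true_links)),
                   "psm_labels": ground.psm_labels}, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth({tuple(p) for p in d["true_links"]}, d["psm_labels"])
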