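"""Hierarchical target-decoy FDR for cross-link identifications.

Cross-link searches match spectra against target and decoy sequences; a match
is TT (both peptides target), TD (one decoy) or DD (both decoy). Decoy counts
estimate the number of false target matches, giving at a score threshold s

    FDR(s) = max(0, TD(s) - DD(s)) / TT(s)

over everything scoring >= s (TD overcounts false TTs once per decoy end, DD
corrects the double count). Identifications are controlled at three levels:
spectrum matches (PSMs), unique peptide pairs, and unique residue pairs, the
residue pair being the quantity of structural interest. Lower levels act as
noise prefilters: discarding low-scoring PSMs/peptide pairs before aggregation
can *increase* the number of residue pairs passing a given FDR, and
:func:`optimize_prefilters` searches prefilter cut-offs for exactly that.

Multiple PSMs supporting the same (peptide or residue) pair are aggregated
with a root-sum-of-squares score, so every extra observation helps but the
aggregate stays on the scale of a single PSM score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TD_CLASSES = ("TT", "TD", "DD")

#: canonical PSM table columns (the synthetic generator writes these)
PSM_COLUMNS = ["psm_id", "run_id", "pep_seq_a", "pep_seq_b", "link_pos_a",
               "link_pos_b", "prot_pos_a", "prot_pos_b", "score",
               "is_decoy_a", "is_decoy_b"]


@dataclass(frozen=True)
class PSM:
    """One scored spectrum-level cross-link match."""

    psm_id: str
    run_id: str
    peptide_a: str
    peptide_b: str
    link_pos_a: int
    link_pos_b: int
    prot_pos_a: int
    prot_pos_b: int
    score: float
    is_decoy_a: bool = False
    is_decoy_b: bool = False
    protocol: str = "trypsin"

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("PSM score must be non-negative")


@dataclass
class ScoredEntity:
    """A unique peptide pair or residue pair with aggregated score and
    target/decoy class; ``support`` lists the contributing PSM ids."""

    key: tuple
    score: float
    td_class: str
    support: list = field(default_factory=list)
    runs: frozenset = frozenset()
    q_value: float | None = None


@dataclass
class FDRResult:
    """Accepted entities at a nominal FDR with the chosen cut-offs."""

    accepted: list
    nominal_fdr: float
    score_cutoff: float
    counts: tuple  # (TT, TD, DD) at the cutoff
    psm_prefilter_fdr: float | None = None
    peppair_prefilter_fdr: float | None = None
    diagnostics: str = ""


def classify_td(is_decoy_a: bool, is_decoy_b: bool) -> str:
    """TT / TD / DD from the two decoy flags."""
    return TD_CLASSES[int(bool(is_decoy_a)) + int(bool(is_decoy_b))]


def aggregate_score(psm_scores: Sequence[float], root: bool = True) -> float:
    """Aggregate supporting-PSM scores: sqrt(sum of squares) by default
    (``root=False`` gives the plain sum of squares)."""
    if len(psm_scores) == 0:
        raise ValueError("cannot aggregate an empty score list")
    total = float(sum(s * s for s in psm_scores))
    return math.sqrt(total) if root else total


def _peptide_pair_key(psm: PSM) -> tuple:
    ends = sorted([(psm.peptide_a, psm.link_pos_a, psm.is_decoy_a),
                   (psm.peptide_b, psm.link_pos_b, psm.is_decoy_b)])
    return ("pep", ends[0][0], ends[0][1], ends[1][0], ends[1][1])


def _residue_pair_key(psm: PSM) -> tuple:
    i, j = sorted((psm.prot_pos_a, psm.prot_pos_b))
    return ("res", i, j)


def group_entities(psms: Iterable[PSM], level: str, root: bool = True
                   ) -> list[ScoredEntity]:
    """Group PSMs into unique peptide-pair or residue-pair entities.

    One entity per canonical key x TD class; the entity score aggregates all
    supporting PSM scores. Keys are invariant under swapping the two ends.
    """
    if level == "peptide_pair":
        keyfun = _peptide_pair_key
    elif level == "residue_pair":
        keyfun = _residue_pair_key
    else:
        raise ValueError("level must be 'peptide_pair' or 'residue_pair'")
    groups: dict[tuple, list[PSM]] = {}
    for p in psms:
        groups.setdefault((keyfun(p), classify_td(p.is_decoy_a, p.is_decoy_b)),
                          []).append(p)
    entities = []
    for (key, cls), members in groups.items():
        entities.append(ScoredEntity(
            key=key,
            score=aggregate_score([m.score for m in members], root=root),
            td_class=cls,
            support=[m.psm_id for m in members],
            runs=frozenset(m.run_id for m in members),
        ))
    return entities


def psms_as_entities(psms: Iterable[PSM]) -> list[ScoredEntity]:
    """View each PSM as its own entity (for the PSM-level prefilter)."""
    return [ScoredEntity(key=("psm", p.psm_id), score=p.score,
                         td_class=classify_td(p.is_decoy_a, p.is_decoy_b),
                         support=[p.psm_id], runs=frozenset([p.run_id]))
            for p in psms]


def estimate_fdr(entities: Sequence[ScoredEntity]) -> list[float]:
    """Per-entity q-values under the (TD - DD)/TT estimator.

    At each candidate threshold (every distinct score) the raw FDR is computed
    over all entities scoring at or above it — ties are all-in, so decoys tied
    with targets count against them. The q-value of an entity is the minimum
    raw FDR over thresholds at or below its score (suffix minimum), which makes
    q non-increasing in score. q-values are filled into ``entity.q_value`` and
    also returned in input order.
    """
    n = len(entities)
    if n == 0:
        return []
    scores = np.array([e.score for e in entities])
    cls = np.array([TD_CLASSES.index(e.td_class) for e in entities])
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tt = np.cumsum(cls[order] == 0)
    td = np.cumsum(cls[order] == 1)
    dd = np.cumsum(cls[order] == 2)
    # evaluate only at the last index of each tie group (threshold = that score)
    is_group_end = np.ones(n, dtype=bool)
    is_group_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(tt > 0, np.maximum(td - dd, 0) / np.maximum(tt, 1), 0.0)
    raw = np.where(is_group_end, raw, np.inf)  # only group ends are thresholds
    # suffix min: tie-group members automatically pick up their group end's raw
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    for e, qv in zip(entities, q):
        e.q_value = float(qv)
    return list(map(float, q))


def filter_at_fdr(entities: Sequence[ScoredEntity], alpha: float) -> FDRResult:
    """Accept TT entities with q-value <= alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if any(e.q_value is None for e in entities):
        estimate_fdr(entities)
    accepted = [e for e in entities if e.td_class == "TT" and e.q_value <= alpha]
    if not accepted:
        return FDRResult([], alpha, math.inf, (0, 0, 0),
                         diagnostics="no TT entity passes the threshold")
    cutoff = min(e.score for e in accepted)
    counts = tuple(sum(1 for e in entities if e.td_class == c and e.score >= cutoff)
                   for c in TD_CLASSES)
    return FDRResult(sorted(accepted, key=lambda e: -e.score), alpha, cutoff, counts)


def _prefilter(entities: Sequence[ScoredEntity], alpha: float) -> set:
    """Support PSM ids of entities (ANY class) passing alpha — decoys must
    survive prefilters so the next level can estimate its own FDR."""
    estimate_fdr(entities)
    keep: set = set()
    for e in entities:
        if e.q_value <= alpha:
            keep.update(e.support)
    return keep


def hierarchical_fdr(psms: Sequence[PSM], psm_alpha: float = 1.0,
                     peppair_alpha: float = 1.0, respair_alpha: float = 0.05,
                     root: bool = True) -> FDRResult:
    """PSM-level FDR prefilter, then unique-peptide-pair prefilter, then the
    unique-residue-pair FDR. Returns the residue-pair result with all three
    cut-offs recorded. Empty survivor sets yield an empty result with a
    diagnostic rather than an exception."""
    for a in (psm_alpha, peppair_alpha, respair_alpha):
        if not 0 < a <= 1:
            raise ValueError("alphas must be in (0, 1]")
    psms = list(psms)
    empty = FDRResult([], respair_alpha, math.inf, (0, 0, 0),
                      psm_prefilter_fdr=psm_alpha, peppair_prefilter_fdr=peppair_alpha)
    if not psms:
        return replace(empty, diagnostics="no input PSMs")

    keep_ids = _prefilter(psms_as_entities(psms), psm_alpha)
    survivors = [p for p in psms if p.psm_id in keep_ids]
    if not survivors:
        return replace(empty, diagnostics="no PSM survives the PSM-level prefilter")

    pep_entities = group_entities(survivors, "peptide_pair", root=root)
    keep_ids = _prefilter(pep_entities, peppair_alpha)
    survivors = [p for p in survivors if p.psm_id in keep_ids]
    if not survivors:
        return replace(empty, diagnostics="no PSM survives the peptide-pair prefilter")

    res_entities = group_entities(survivors, "residue_pair", root=root)
    result = filter_at_fdr(res_entities, respair_alpha)
    result.psm_prefilter_fdr = psm_alpha
    result.peppair_prefilter_fdr = peppair_alpha
    return result


DEFAULT_GRID = (1.0, 0.5, 0.2, 0.1, 0.05, 0.01)


def optimize_prefilters(psms: Sequence[PSM], respair_alpha: float = 0.05,
                        grid: Sequence[float] = DEFAULT_GRID, root: bool = True
                        ) -> tuple[tuple[float, float], FDRResult]:
    """Exhaustive search over prefilter alpha combinations, maximizing accepted
    residue pairs at ``respair_alpha``. Ties break toward the least filtering
    (larger alphas), PSM alpha compared first."""
    if not grid:
        raise ValueError("grid must be non-empty")
    best_key = None
    best: tuple[tuple[float, float], FDRResult] | None = None
    for pa in grid:
        for ppa in grid:
            res = hierarchical_fdr(psms, pa, ppa, respair_alpha, root=root)
            key = (len(res.accepted), pa, ppa)
            if best_key is None or key > best_key:
                best_key, best = key, ((pa, ppa), res)
    return best


# ---------------------------------------------------------------- I/O helpers

def read_psm_table(path, column_map: dict | None = None, sep: str = "\t"
                   ) -> list[PSM]:
    """Read a delimited PSM table; ``column_map`` renames third-party columns
    onto the canonical schema."""
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    has_protocol = "protocol" in df.columns
    return [PSM(str(r.psm_id), str(r.run_id), r.pep_seq_a, r.pep_seq_b,
                int(r.link_pos_a), int(r.link_pos_b),
                int(r.prot_pos_a), int(r.prot_pos_b), float(r.score),
                bool(r.is_decoy_a), bool(r.is_decoy_b),
                protocol=str(r.protocol) if has_protocol else "trypsin")
            for r in df.itertuples(index=False)]


def residue_pairs_frame(result: FDRResult) -> pd.DataFrame:
    """Accepted residue pairs as a DataFrame (pos_a, pos_b, score, q_value,
    n_psms, runs)."""
    rows = [{"pos_a": e.key[1], "pos_b": e.key[2], "score": e.score,
             "q_value": e.q_value, "n_psms": len(e.support),
             "runs": ";".join(sorted(e.runs))} for e in result.accepted]
    return pd.DataFrame(rows, columns=["pos_a", "pos_b", "score", "q_value",
                                       "n_psms", "runs"])


def fdr_summary(psms: Sequence[PSM], levels: Sequence[float] = (0.05, 0.10, 0.20),
                psm_alpha: float = 1.0, peppair_alpha: float = 1.0) -> dict:
    """Residue-pair counts at each nominal FDR level (JSON-serializable)."""
    out = {}
    for a in levels:
        res = hierarchical_fdr(psms, psm_alpha, peppair_alpha, a)
        out[f"{a:g}"] = {"n_residue_pairs": len(res.accepted),
                         "score_cutoff": res.score_cutoff if res.accepted else None,
                         "counts_TT_TD_DD": list(res.counts)}
    return out


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
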