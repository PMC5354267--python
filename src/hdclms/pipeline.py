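"""End-to-end orchestration: FDR -> validation -> saturation -> digestion ->
bias, with report assembly and enzyme attribution.

Stages degrade gracefully: without a structure the validation and RSA stages
are marked skipped while the sequence-only stages still run. All randomness is
seeded from the config; machine outputs go to files, logging to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from ._util import int_percent
from . import digestion as dig
from . import fdr as fdrmod
from . import saturation as sat
from . import ss_bias as bias
from . import structure as struc

log = logging.getLogger("hdclms")


@dataclass
class PipelineConfig:
    psm_table: str | Path
    fasta: str | Path | None = None
    pdb: str | Path | None = None
    ss_table: str | Path | None = None
    fdr_levels: tuple = (0.05, 0.10, 0.20)
    psm_alpha: float = 1.0
    peppair_alpha: float = 1.0
    optimize: bool = False
    distance_threshold: float = 25.0
    min_seq_sep: int = 11
    max_missed: int = 4
    len_min: int = 5
    len_max: int = 45
    n_random: int = 10_000
    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self):
        levels = tuple(self.fdr_levels)
        if list(levels) != sorted(levels) or not all(0 < a <= 1 for a in levels):
            raise ValueError("fdr_levels must be ascending fractions in (0, 1]")
        self.fdr_levels = levels


def _read_fasta(path) -> str:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages and assemble a machine-readable report.

    Returns a dict whose summary numbers are all re-derivable from the
    per-record tables written to ``outdir`` (when given).
    """
    # timings are logged, not stored: reruns with equal seeds must produce
    # byte-identical reports
    report: dict = {"config": {"fdr_levels": list(config.fdr_levels),
                               "distance_threshold": config.distance_threshold,
                               "seed": config.seed},
                    "inputs": {}, "stages": {}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for name, p in (("psm_table", config.psm_table), ("fasta", config.fasta),
                    ("pdb", config.pdb), ("ss_table", config.ss_table)):
        if p is not None:
            report["inputs"][name] = {"path": str(p), "sha256": _checksum(p)}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                report["stages"].setdefault(name, {"status": "ok"})
            except Exception as exc:  # noqa: BLE001 - abort with named stage
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return deco

    psms = fdrmod.read_psm_table(config.psm_table)
    sequence = _read_fasta(config.fasta) if config.fasta else None
    state: dict = {}

    @stage("fdr")
    def _fdr():
        if config.optimize:
            (pa, ppa), res = fdrmod.optimize_prefilters(
                psms, config.fdr_levels[0])
        else:
            pa, ppa = config.psm_alpha, config.peppair_alpha
            res = fdrmod.hierarchical_fdr(psms, pa, ppa, config.fdr_levels[0])
        state["result"] = res
        state["frame"] = fdrmod.residue_pairs_frame(res)
        levels = {}
        for a in config.fdr_levels:
            r = fdrmod.hierarchical_fdr(psms, pa, ppa, a)
            n = len(r.accepted)
            levels[f"{a:g}"] = {
                "n_residue_pairs": n,
                "links_per_residue": (dig.links_per_residue(n, len(sequence))
                                      if sequence else None),
                "long_range": dig.long_range_fraction(
                    [(e.key[1], e.key[2]) for e in r.accepted],
                    config.min_seq_sep),
            }
        report["stages"]["fdr"] = {"status": "ok",
                                   "psm_alpha": pa, "peppair_alpha": ppa,
                                   "levels": levels}
        if outdir is not None:
            state["frame"].to_csv(outdir / "residue_pairs.csv", index=False)

    @stage("saturation")
    def _saturation():
        by_run = sat.pairs_by_run_from_frame(state["frame"]) if len(state["frame"]) \
            else {}
        if not by_run:
            report["stages"]["saturation"] = {"status": "skipped",
                                              "reason": "no accepted pairs"}
            return
        curve = sat.saturation_curve(by_run, config.n_permutations, config.seed)
        slope = sat.saturation_slope(curve)
        report["stages"]["saturation"] = {
            "status": "ok", "exhaustive": curve.exhaustive,
            "mean_cumulative": [float(x) for x in curve.mean_cumulative],
            "saturated": slope["saturated"]}
        if outdir is not None:
            curve.frame().to_csv(outdir / "saturation_curve.csv", index=False)

    @stage("digestion")
    def _digestion():
        if sequence is None:
            report["stages"]["digestion"] = {"status": "skipped",
                                             "reason": "no FASTA"}
            return
        tryp = dig.trypsin()
        both = [tryp, dig.glu_c()]
        obs_t = dig.observable_residue_set(sequence, tryp, config.len_min,
                                           config.len_max, config.max_missed)
        obs_tg = dig.observable_residue_set(sequence, both, config.len_min,
                                            config.len_max, config.max_missed)
        attribution = enzyme_attribution(
            state["result"].accepted,
            {p.psm_id: p.protocol for p in psms})
        report["stages"]["digestion"] = {
            "status": "ok",
            "n_tryptic_sites": len(dig.cleavage_sites(sequence, tryp)),
            "observable_trypsin": len(obs_t),
            "observable_trypsin_gluc": len(obs_tg),
            "inaccessible_trypsin": len(sequence) - len(obs_t),
            "enzyme_attribution": attribution}

    @stage("validation")
    def _validation():
        if config.pdb is None:
            report["stages"]["validation"] = {"status": "skipped",
                                              "reason": "no PDB"}
            return
        model = struc.read_structure(Path(config.pdb).read_text(), seq=sequence)
        pairs = [(e.key[1], e.key[2]) for e in state["result"].accepted]
        rep = struc.validation_report(pairs, model, sequence or model.sequence,
                                      config.distance_threshold,
                                      config.min_seq_sep, config.n_random,
                                      config.seed)
        report["stages"]["validation"] = {"status": "ok", **rep.to_dict()}
        state["model"] = model
        if outdir is not None:
            rep.histogram_frame().to_csv(outdir / "distance_histogram.csv",
                                         index=False)

    @stage("bias")
    def _bias():
        model = state.get("model")
        if config.ss_table is not None:
            ss = bias.read_ss_table(config.ss_table)
        elif model is not None:
            ss = bias.assign_ss(model)
        else:
            report["stages"]["bias"] = {"status": "skipped",
                                        "reason": "no SS annotation or structure"}
            return
        pairs = [(e.key[1], e.key[2]) for e in state["result"].accepted]
        entry: dict = {
            "status": "ok",
            "beta_residue_percent": bias.beta_residue_fraction(ss),
            "observed_beta": bias.observed_pair_beta_fraction(pairs, ss),
            "expected_beta_percent": bias.expected_pair_beta_fraction(ss),
            "kr_by_class": bias.kr_content_by_class(
                sequence or model.sequence, ss) if (sequence or model) else None,
        }
        if model is not None:
            rsa = bias.compute_rsa(model)
            entry["rsa_by_class"] = bias.rsa_summary(rsa, ss)
            entry["rsa_nhs_reactive"] = bias.rsa_summary(
                rsa, ss, sequence or model.sequence, bias.nhs_reactive_subset())
        report["stages"]["bias"] = entry

    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def enzyme_attribution(accepted, psm_protocols: dict,
                       is_gluc=lambda name: "glu" in name.lower(),
                       region: tuple | None = None,
                       mode: str = "only") -> dict:
    """Residue pairs attributable to Glu-C-involving digestion.

    ``mode='only'``: a pair counts as Glu-C-added iff *all* its supporting
    PSMs come from Glu-C-involving protocols (nothing from trypsin alone would
    have found it). ``mode='any'`` counts pairs with any Glu-C support.
    ``region`` optionally restricts to pairs touching a 1-based interval.
    Trypsin-only + Glu-C-attributed partition the accepted set under 'only'.
    """
    pairs = list(accepted)
    if region is not None:
        lo, hi = region
        pairs = [e for e in pairs
                 if lo <= e.key[1] <= hi or lo <= e.key[2] <= hi]
    total = len(pairs)
    attributed = 0
    for e in pairs:
        flags = []
        for pid in e.support:
            if pid not in psm_protocols:
                raise ValueError(f"unlabeled PSM: {pid}")
            flags.append(is_gluc(psm_protocols[pid]))
        if (all(flags) if mode == "only" else any(flags)):
            attributed += 1
    return {"total": total, "gluc_attributed": attributed,
            "trypsin_only": total - attributed,
            "percent": int_percent(attributed, total) if total else 0}
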