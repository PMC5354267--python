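# Methods

This note documents the models behind `hdclms`, the defaults that matter,
and what the synthetic tests do and do not demonstrate about real data.

## Target-decoy FDR for cross-links

A cross-link PSM has two peptides, each matched against a target or a decoy
sequence, giving classes TT, TD and DD. Under the standard random-match model
(equal-size decoy database), a false match's ends are independently decoy
with probability ½, so false matches split 1:2:1 into TT:TD:DD and the number
of false TTs above a score threshold is estimated by TD − DD. We use the
classical cross-link estimator

    FDR(s) = max(0, TD(s) − DD(s)) / TT(s),

evaluated at every distinct score with ties counted all-in (decoys tied with
targets count against them — the conservative direction), and convert it to
q-values by a suffix minimum over thresholds, which makes q non-increasing in
score. `filter_at_fdr` accepts TT entities with q ≤ α; tied scores are always
accepted or rejected together.

**Aggregation.** Unique peptide pairs and unique residue pairs are scored as
the root of the sum of squared supporting-PSM scores. The root keeps the
aggregate on the scale of a single PSM score while rewarding every extra
observation; a plain sum-of-squares variant is available (`root=False`).
Entities are keyed order-invariantly (sorted peptide/link-position tuples,
sorted position pairs) and separately per TD class.

**Hierarchy.** The dataset is prefiltered by an FDR cut at the PSM level and
then at the unique-peptide-pair level before the residue-pair FDR. Prefilters
retain entities of *all* classes whose q passes the cut — decoys must survive
so the next level can estimate its own error; keeping only targets would
collapse downstream FDR estimates to zero. `optimize_prefilters` searches a
grid (default 1.0, 0.5, 0.2, 0.1, 0.05, 0.01 per level, exhaustive over the
product) for the combination maximizing accepted residue pairs, breaking ties
toward the least filtering.

## Synthetic studies

The generator exists so that FDR calibration and every downstream stage can
be measured against known truth.

- **Geometry.** Toy folds are built from ideal secondary-structure segments:
  α-helices (rise 1.5 Å/residue, radius 2.3 Å, 100°/residue) and β-strands
  (rise 3.3 Å/residue with a 0.5 Å zigzag), laid out on a grid and joined by
  circular-arc loops whose steps are exactly 3.5 Å. Consecutive Cα–Cα
  distances therefore always stay within the virtual-bond convention
  3.8 ± 0.8 Å. A fraction of residues (default 10%) is marked unresolved:
  they keep their sequence number but carry no coordinates, as in a PDB file
  with missing density. An optional backbone mode places N/C/O/Cβ at
  approximate ideal geometry for full-atom surface calculations.
- **Truth links** are all pairs with one end K/S/T/Y or the N-terminus, both
  ends resolved, and Cα–Cα ≤ 25 Å.
- **PSM simulation.** True events draw pairs from the truth set with scores
  from a Gaussian truncated at zero (default mean 12, sd 2); false and decoy
  events are random matches drawn from the *same* pool of non-true linkable
  pairs with noise scores (default mean 6, sd 2). Using one pool for both is
  deliberate: the target-decoy estimator assumes decoys mirror the false-
  target process, and on a toy-sized pair space an asymmetric pool would
  distort entity-level collision statistics. Decoys split 80/20 into
  one-decoy/two-decoy matches; their count defaults to
  n_false/(2·share − 1) so that E[TD − DD] equals the false-target count —
  the count an equal-size decoy database produces. A deliberately mis-sized
  decoy model can be simulated via `decoy_multiplier`.
- **Runs.** Each event is captured independently by each of the runs
  (default 4) with probability 0.5, one PSM row per capturing run; events
  captured nowhere are lost. This yields partially overlapping runs for the
  saturation analysis; per-run counts are a free parameter, not calibrated
  to any real acquisition.

**What passing tests show.** With the defaults (150 residues, 2000 true /
600 false events), the realized false fraction among residue pairs accepted
at nominal 5% FDR averages ≈3.5–4% over 20 seeds — honest, slightly
conservative (second-order entity-collision effects and all-in tie handling
both push downward). This validates the estimator's logic, not its behaviour
on real spectra, where score distributions are neither Gaussian nor
homogeneous and site-assignment ambiguity (not modelled — each reported
position pair is taken literally) may split or merge entities.

## Distance validation

Observed links are interpreted as Cα–Cα ≤ 25 Å (configurable), the distance
at which observed cross-link distance distributions merge with decoy-match
distributions. Pairs with an unresolved end are a separate *unverifiable*
class and are excluded from the violation-percentage denominator. The random
reference distribution samples linkable resolved pairs uniformly with
replacement; whether the original analysis used sampled pairs or decoy
matches is not determinable, and sampled pairs were chosen as the cleaner
null. PDB input is parsed with gemmi; the first chain is used unless named;
alternate locations keep the highest-occupancy CA (ties: first); insertion
codes are rejected rather than silently renumbered; author numbering is
aligned to a supplied sequence by the unique constant offset under which all
resolved residues match exactly (no gapped alignment — single-domain
targets).

## Digestion and observability

Trypsin cuts after K/R (blocked before proline by default, configurable);
Glu-C after E (optionally D). Co-digestion unions cleavage sites. Digestion
with up to `max_missed` internal sites (default 4) yields peptides; a residue
is *observable* if it lies on at least one peptide with length in
[len_min, len_max] (default 5–45 residues — the length band ordinary LC-MS
handles; the exact cutoff behind any published inaccessible-residue count is
unstated, so the window is a parameter). Link densities are reported per
residue to 2 decimals; a pair counts toward a region if either end lies in it
(both-ends mode available); "long range" means strictly more than 11
residues' separation.

## Secondary-structure and RSA bias

External DSSP-style annotations are canonical (E,B → E; H,G,I → H; else C).
A geometry-only fallback labels residues from i→i+3 Cα distances (5.0–6.5 Å
helix, 9.0–11.0 Å strand), letting any structured evidence beat coil;
extended loops are strand-like at this resolution, so the fallback over-calls
E in loops — adequate for recovering a toy fold's strand content to ±10
points, not a DSSP replacement.

The expected fraction of pairs touching a strand under unbiased linking is
the exact combinatorial fraction over unordered distinct pairs
(1 − C(n−b,2)/C(n,2) for the at-least-one mode), or an enumeration over
sulfo-SDA-linkable pairs when that universe is selected; both modes exist
because the published comparison's universe is ambiguous, and all-pairs is
the default (it reproduces the ≈80%-from-54% arithmetic).

RSA is Shrake–Rupley: ≥960 Fibonacci dots per atom, probe 1.4 Å, element
van-der-Waals radii, normalized by theoretical Gly-X-Gly maxima (Tien et al.
2013 values, shipped as `data/max_asa.csv` so the table is auditable and
swappable), capped at 1.5. Cα-only structures fall back to one sphere per
residue whose radius is chosen so an isolated residue scores RSA = 1 — a
coarse approximation good for buried-vs-exposed contrasts only. The toy
folds do not reproduce the real-data observation that strand residues are
systematically more buried than others; that contrast depends on genuine
side-chain packing which ideal Cα geometry lacks.

## Saturation

For each of 100 (default) run-order permutations the cumulative count of
unique residue pairs is recorded; with ≤7 runs all orders are enumerated,
removing Monte-Carlo noise. An analytic inclusion–exclusion expectation
(E[|∪ first r|] via hypergeometric missing-probabilities) provides an
independent cross-check. The curve's final marginal gain below 1% of the
total flags saturation.

## Rounding and reporting

All reported percentages are integers and densities 2-decimal, rounded half
away from zero — the convention that reproduces the published tables'
arithmetic. Two published values are inconsistent with their own printed
counts under any standard rounding (one long-range percentage, one
links-per-residue entry) and are not asserted anywhere.

## Known limitations

- Single-protein (within-protein) analysis only; no between-protein links,
  no multi-chain assemblies, no solvent-accessible-surface-distance paths.
- The spectrum-level search (mass tolerances, modifications, site-assignment
  scoring) is upstream and out of scope; the pipeline starts at PSM tables.
- Synthetic score distributions are truncated Gaussians; real score
  distributions are heavier-tailed and score-rank dependent.
- The ideal-geometry backbone mode approximates N/C/O/Cβ placement; it is
  sufficient for surface-area tests, not for stereochemistry.
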