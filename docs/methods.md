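# Methods

This note documents the models and procedures implemented in `qcprof`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions taken where the underlying
published analyses leave latitude.

## SILAC differential abundance (`qcprof.silac`)

**Model.** Peptide-level log2(H/L) ratios (heavy = wild type, light =
mutant) are treated as noisy observations of a per-protein shift.  The
peptide → protein reduction is the median per (protein, replicate) —
robust to single aberrant peptides; the mean is available via
`aggregate_method="mean"`.  A protein enters testing only with ≥ 2
distinct peptides and quantification in ≥ 2 replicates.

**Background test.** Unregulated proteins dominate a whole-proteome SILAC
experiment, so a protein is tested against the empirical distribution of
protein-level log ratios.  Three policies are implemented
(`background_policy`):

- `background` (default): t statistic of the protein's mean −log2(H/L)
  against the mean of the background distribution, scaled by the background
  SD, df = n_background − 1.  Because each background entry is itself a
  protein-level mean, the background spread *is* the null sampling spread
  of the tested quantity; a global-null simulation (2 000 proteins, 3
  replicates, peptide SD 0.2) gives empirical type-I error 0.051 at
  p ≤ 0.05.
- `target_only`: one-sample t of the replicate values against the
  background mean (df = n − 1); approximately calibrated but noisy at
  n = 3.
- `pooled`: one-sample t with scale max(target SD, background SD) and
  df = n − 1.  This policy is deliberately, heavily conservative (measured
  type-I error ≈ 0 at n = 3 because a wide scale is combined with
  fat-tailed df = 2 reference); it is retained as an option, not the
  default, precisely because it cannot be calibrated.

**Calling.** Significance uses the raw p (≤ 0.05, inclusive) together with
the effect threshold −log2(H/L) ≥ 0.3 (inclusive); BH-adjusted p-values
are computed (statsmodels step-up) and emitted alongside but do not gate
the call, matching the convention of reporting both.  Two contrasts are
overlapped on the intersection of quantified membrane proteins into
{both, A-only, B-only, neither}; the −log2 > −1 floor affects only the
scatter/display column, never classification.  GO tabulation counts
slim-term hits over the set, drops single-hit terms, applies optional
term-fusion rules (global or per-protein), and reports dataset/genome
frequency ratios as enrichment.

## TMD signatures (`qcprof.tmd`, `qcprof.topology`)

Topology annotations must tile [1, length] with 1-based inclusive
segments; violations are rejected with the protein and residue position.
Both supported dialects (GFF3-like blocks; three-line records with a
per-residue I/O/M/S string) round-trip losslessly.

Each TMhelix becomes a segment of length end − start + 1.  Orientation is
derived from the nearest sided flank: preceding `inside` ⇒ the helix runs
cytosol → lumen (`in->out`); otherwise `out->in`, and the extracted
sequence is reversed so it always reads from the cytosolic side (an
involution — re-orienting twice is the identity).  Signal peptides count
as luminal flanks; a helix with no sided flank at all is an error.  The
`inside` label is equated with the cytosol — a documented simplification
that is correct for single-membrane topologies but not for exotic
multi-organelle arrangements.

Set signatures report: all TMD lengths with median and quartiles (linear
interpolation on sorted values), per-protein shortest TMD, per-protein
counts, and threshold fractions (≤ 16, ≤ 18 residues; counts ≤ 10 / > 10,
all inclusive and config-overridable).  Proteins with zero TMDs are
tallied separately and excluded from length statistics, never silently
dropped.  `compare_signatures` adds per-statistic deltas and a
Mann–Whitney rank-sum p, labeled an extension (the underlying figures
juxtapose distributions without a printed test).

The hydropathy fallback slides a 19-residue window of mean Kyte–Doolittle
score and keeps maximal runs of above-cutoff (≥ 1.6) window centers.  It
is a labeled heuristic for sequences lacking predictor output; on the
synthetic proteome (strongly hydrophobic TMD alphabet, polar linkers) it
recalls ≥ 90% of planted TMD midpoints, which says nothing about its
accuracy on real proteomes.  `helix_extension_rise` converts added
residues to added helical span at the ideal α-helix rise of 1.5 Å/residue
(3 → 4.5 Å, 6 → 9 Å).

## Lipid asymmetry (`qcprof.lipids`)

Values are renormalized within each (sample, class) block to sum to 100
(mol%/class; idempotent, conserving to 1e-9).  Total-acyl labels sum chain
carbons (10:0 + 16:0 → C-26).  A species is *asymmetric* when its chains
differ by ≥ Δ_min = 6 carbons — chosen to cover the characteristic
10:0/16:0 and 10:0/18:x pairings while excluding ubiquitous 16/18
combinations — and its saturation profile distinguishes two saturated
chains from a mono-unsaturated long chain.  Unknown chains propagate as
`unknown` and are excluded from asymmetry panels while remaining available
for total-acyl panels.

Group comparisons use the unpaired Student t-test with pooled variance
(reading "without assuming individual variance for each sample" as the
classical equal-variance option, not Welch).  Discovery control is the
two-stage linear step-up procedure: stage 1 is a BH pass at
q′ = Q/(1 + Q); with r₁ rejections the true-null count is estimated as
m₀ = m − r₁ and stage 2 reruns the step-up at q′·m/m₀.  The
implementation is cross-checked in the tests against the independent
statsmodels two-stage routine and against a literal step-by-step oracle,
and an all-null simulation confirms realized FDR ≤ Q within Monte-Carlo
error.  The correction family is each lipid class's species set
(mirroring per-class figure panels); a global family is available by
config.

## Bilayer thinning (`qcprof.thinning`)

A frame is a set of (x, y, z) reference points, one per lipid, tagged
upper/lower.  Untagged frames are split at the median z (exact-median
points go to the lower leaflet with a warning); with thermal noise well
below the leaflet separation this recovers generator tags exactly.  The
thickness map bins points on an x–y grid (default 2 Å); per bin and frame
the distance is mean(upper z) − mean(lower z), averaged over frames where
both leaflets appear in the bin (empty bins are flagged, never
zero-filled).  The default averaging window is the trailing 40% of frames,
mirroring analysis of the final converged stretch of an equilibrated run;
x–y periodic wrapping applies when box extents are present.  Thinning
summary: bulk = mean over populated bins farther than 25 Å from the map
minimum; max thinning = bulk − minimum.  Difference maps subtract
per-bin values over bins populated in both (nearest-bin resampling if the
grids disagree) and report the difference in max thinning.

For PDB input one point per atom record is read with the leaflet encoded
in the chain id (U/L); for real membranes the natural reference is the
phosphorus atom per lipid, and the choice of reference point is the main
source of approximation when comparing to published density maps.

## Synthetic generators (`qcprof.synthetic`)

All generators take frozen specs carrying their own seed, draw from
`numpy.random.default_rng` generator objects (no global state), and are
byte-deterministic given the spec.

- **Proteome**: TMD residues from a strongly hydrophobic alphabet
  (L/I/V/F/A/M/C, mean hydropathy ≈ +3.5), linkers from a polar/charged
  alphabet; TMD counts, lengths (support within 10–30 residues) and linker
  lengths are drawn from user samplers; loops alternate inside/outside so
  orientations are well defined.  Emulated: length/count structure and
  sided topology.  Not emulated: real amino-acid composition, signal
  peptides, re-entrant helices — so fallback-caller recall on this data is
  an upper bound.
- **SILAC**: per-protein planted −log2(H/L) shifts; Gaussian peptide noise
  in log2 space (the standard error model for isotope-ratio data); uniform
  at-random peptide × replicate missingness.  Defaults: 3 replicates,
  2–8 peptides/protein, SD 0.2 log2 units, 10% missingness.  Not
  emulated: intensity-dependent missingness, shared peptides, ratio
  compression.
- **Lipidome**: a yeast-like five-class glycerophospholipid catalog whose
  classes each carry common symmetric species plus minor asymmetric
  C-26 (10:0;16:0) and C-28 (10:0;18:1) species; the mutant group doubles
  C-26 and raises C-28 by 50% — the planted truth mirroring the reported
  enrichment —  with n = 4 replicates/group and lognormal noise of
  CV 0.1 applied before per-class renormalization.
- **Bilayer**: two flat sheets at ±separation/2 (default 40 Å, a typical
  phosphate–phosphate distance) with a Gaussian dimple of depth 5 Å and
  σ = 8 Å split symmetrically across leaflets, thermal z-noise of 1 Å, and
  lateral positions re-drawn each frame (fast in-plane diffusion).  The
  default density (2 500 points per leaflet in a 50 × 50 Å box) is a
  Monte-Carlo resolution choice — it over-samples physical area-per-lipid
  so that a 2 Å grid over 100 frames resolves the dimple minimum to
  ±0.3 Å; the generator is a geometry model of the analysis contract, not
  of lipid physics.

## Pipeline (`qcprof.pipeline`) and interfaces

Configs are YAML, schema-validated with unknown keys rejected and the
documented defaults (ratio ≥ 0.3, p ≤ 0.05, Q = 0.01, bin 2 Å, trailing
40% window); the resolved config and a report (seed, parameter hash,
per-stage summaries) are persisted with every run, and identical
config + seed reproduces byte-identical outputs.  Stage seeds are derived
from the run seed via `numpy.random.SeedSequence`.  The public surface is
the library plus the numbered scripts under `analysis/`; the package
deliberately ships no console entry point, since every use is either a
library call or a scripted, reproducible run.

## Known limitations

- The background-test policy of the original processing software is not
  public; the calibrated default documented above is this package's own
  definition, and conclusions sensitive to that choice should be checked
  under `target_only` as well.
- "Cytosolic = inside" breaks for proteins whose topology predictor
  labels do not correspond to the cytosol (e.g. dual-topology proteins).
- Thinning magnitudes from real trajectories depend on the per-lipid
  reference point (phosphorus vs. centroid) and on map smoothing; ±0.5 Å
  disagreement with published density maps is expected.
- Test problem sizes (hundreds of proteins, 100-frame point clouds,
  4 000-replicate null simulations) were chosen so the full suite runs in
  seconds while keeping Monte-Carlo error well inside every asserted
  tolerance.
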