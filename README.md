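# qcprof — membrane-protein quality-control profiling

`qcprof` reimplements, as a tested analysis pipeline, the computational
stages used to characterize how a Golgi-localized ubiquitin-ligase (Dsc)
complex recognizes short transmembrane domains (TMDs) as degradation
signals in yeast:

1. **SILAC differential membrane proteomics** (`qcprof.silac`) — peptide
   heavy/light (H/L) log2 ratios from wild-type (heavy) vs. mutant (light)
   cells are reduced per protein and replicate (median), filtered for
   evidence (≥ 2 distinct peptides quantified in ≥ 2 of 3 replicates),
   tested against the background distribution of unregulated proteins, and
   called significantly upregulated at mean −log2(H/L) ≥ 0.3 with
   p ≤ 0.05 (Benjamini–Hochberg adjusted p reported alongside).  Two
   contrasts are overlapped on shared quantified membrane proteins, and GO
   cellular-component frequencies tabulated.
2. **TMD hydrophobic-length signatures** (`qcprof.tmd`) — topology
   predictions (DeepTMHMM-style GFF3 or three-line dialects) are parsed
   and validated, each TMhelix extracted with its length
   (end − start + 1 residues) and written cytosolic-side first; protein
   sets are summarized by length median/quartiles, fraction of TMDs
   ≤ 16/≤ 18 residues, shortest TMD per protein, and TMD counts — the
   statistics that separate short-TMD substrates from ordinary polytopic
   membrane proteins.  A Kyte–Doolittle sliding-window caller is included
   as a labeled, non-authoritative fallback.
3. **Lipid acyl-chain asymmetry** (`qcprof.lipids`) — species tables are
   normalized to mol% per lipid class, labeled by total acyl carbons
   (C-26, C-28 …), and classified asymmetric when the paired chains differ
   by ≥ 6 carbons (e.g. 10:0 with 16:0).  Group differences use per-species
   unpaired pooled-variance t-tests with the two-stage linear step-up FDR
   procedure of Benjamini, Krieger & Yekutieli at Q = 1%, per class.
4. **Bilayer thinning maps** (`qcprof.thinning`) — trajectory frames (one
   reference point per lipid; multi-MODEL PDB or a plain XYZ-like format)
   are leaflet-assigned by a median-z split, binned on a 2 Å x–y grid, and
   averaged over the trailing converged window into a map of inter-leaflet
   distance; local thinning = bulk thickness − map minimum, and two
   conditions can be differenced.

Every stage is exercisable without downloads through seeded generators
(`qcprof.synthetic`) that plant known truths: SILAC effect sets with
Gaussian log2 peptide noise, proteomes with controlled TMD counts/lengths,
lipidomes with enriched asymmetric species, and two-leaflet point clouds
with Gaussian dimples.  `qcprof.pipeline` ties the stages into
reproducible, config-driven runs.

## Worked example

```sh
cd analysis
python 01_simulate.py --seed 1 --out results/analysis
python 02_silac_diff.py --seed 1 --out results/analysis
python 03_tmd_signatures.py --seed 1 --out results/analysis
python 04_lipid_asymmetry.py --seed 1 --out results/analysis
python 05_membrane_thinning.py --seed 1 --out results/analysis
```

prints (seed 1):

```
planted SILAC effects: 25 in contrast A, 25 in contrast B, 5 shared
contrast A: 25 significant proteins
contrast B: 25 significant proteins
overlap classes: {'both': 5, 'contrastA_only': 20, 'contrastB_only': 20, 'neither': 355}
short-TMD set: 82 TMDs in 40 proteins, median 16 aa, frac ≤18 aa 1.00, frac shortest ≤16 0.75
long-TMD set: 356 TMDs in 40 proteins, median 22 aa, frac ≤18 aa 0.00, frac shortest ≤16 0.00
9 of 35 species discovered at Q=1%; 9 are asymmetric (Δchain ≥ 6 C)
wt: bulk 40.00 Å, min 35.04 Å, max thinning 4.95 Å
Δ max-thinning (wt − mut): 2.48 Å
```

The differential calling recovers exactly the 25 planted effects per
contrast and the 5 proteins planted in both; the short- and long-TMD sets
separate cleanly in every signature statistic; the Q = 1% discoveries are
all planted asymmetric species; and the 5 Å dimple planted in the wild-type
bilayer (vs. 2.5 Å in the mutant) is recovered to within 0.05 Å.

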