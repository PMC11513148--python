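"""Seeded synthetic-data generators for every pipeline stage.

Each generator takes a frozen parameter spec carrying its own seed and
returns data with the statistical structure the corresponding analysis
stage assumes:

* membrane proteomes with controlled transmembrane-domain (TMD) counts,
  length distributions and inside/outside orientation;
* SILAC peptide heavy/light ratio tables with planted per-protein effects,
  Gaussian log2-space peptide noise and uniform missingness across
  replicates;
* lipidomes with class-structured species and planted multiplicative
  group effects (e.g. asymmetric C-26/C-28 species enrichment) applied
  before per-class renormalization;
* flat two-leaflet point-cloud bilayers with a localized Gaussian thinning
  deformation split symmetrically across leaflets, plus thermal noise.

All randomness flows through ``numpy.random.default_rng(seed)`` generator
objects; no global RNG state is touched, and identical specs produce
byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .thinning import LOWER, UPPER, BilayerFrame
from .topology import Segment, TopologyAnnotation

__all__ = [
    "IntSampler",
    "constant",
    "uniform_int",
    "SyntheticProteomeSpec",
    "SyntheticSilacSpec",
    "SyntheticBilayerSpec",
    "SyntheticLipidomeSpec",
    "generate_proteome",
    "generate_silac_table",
    "generate_bilayer_trajectory",
    "generate_lipidome",
    "write_fasta",
    "default_lipidome_spec",
]

# An integer sampler is a constant, a finite support to draw uniformly from,
# or a callable taking the RNG.
IntSampler = "int | Sequence[int] | Callable[[np.random.Generator], int]"


def constant(k: int) -> Callable[[np.random.Generator], int]:
    return lambda rng: k


def uniform_int(lo: int, hi: int) -> Callable[[np.random.Generator], int]:
    """Uniform over the inclusive range [lo, hi]."""
    return lambda rng: int(rng.integers(lo, hi + 1))


def _draw(sampler, rng: np.random.Generator) -> int:
    if isinstance(sampler, (int, np.integer)):
        return int(sampler)
    if callable(sampler):
        return int(sampler(rng))
    return int(rng.choice(np.asarray(sampler)))


# Strongly hydrophobic residues for TMD cores (Kyte–Doolittle mean ≈ +3.5)
# versus a polar/charged linker alphabet, so a hydropathy-window scan can
# recover planted TMDs.
_TMD_RESIDUES = np.array(list("LIVFAMC"))
_TMD_WEIGHTS = np.array([0.28, 0.20, 0.20, 0.10, 0.12, 0.05, 0.05])
_LINKER_RESIDUES = np.array(list("DEKRNQSTGPHY"))
_LINKER_WEIGHTS = np.array([0.10, 0.10, 0.11, 0.09, 0.09, 0.09, 0.12, 0.10, 0.09, 0.05, 0.03, 0.03])


# ---------------------------------------------------------------------------
# proteome


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Parameters of a synthetic membrane proteome.

    ``tmd_count_sampler`` draws the number of TMDs per membrane protein,
    ``tmd_length_sampler`` each TMD's residue count (support within
    [10, 30]), and ``linker_length_sampler`` the inter-TMD loop lengths
    (≥ 1 residue, so consecutive TMDs never touch).  ``start_side`` sets
    the N-terminal compartment: ``inside``, ``outside`` or ``alternate``.
    """

    n_proteins: int = 200
    membrane_fraction: float = 1.0
    tmd_count_sampler: object = field(default_factory=lambda: uniform_int(1, 4))
    tmd_length_sampler: object = field(default_factory=lambda: uniform_int(14, 24))
    linker_length_sampler: object = field(default_factory=lambda: uniform_int(10, 60))
    start_side: str = "alternate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not (0.0 <= self.membrane_fraction <= 1.0):
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if self.start_side not in ("inside", "outside", "alternate"):
            raise ValueError("start_side must be inside, outside or alternate")


def _random_seq(alphabet: np.ndarray, weights: np.ndarray, n: int, rng) -> str:
    return "".join(rng.choice(alphabet, size=n, p=weights))


def generate_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[dict[str, str], list[TopologyAnnotation]]:
    """Generate sequences and matching topology annotations.

    Membrane proteins alternate ``inside``/``outside`` loops across each
    TMhelix; TMD residues are drawn from the hydrophobic alphabet, loops
    from the polar alphabet.  Soluble proteins are a single one-sided
    segment.  Returns ``(id → sequence, annotations)`` in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, str] = {}
    anns: list[TopologyAnnotation] = []
    for i in range(spec.n_proteins):
        pid = f"P{i + 1:04d}"
        is_membrane = rng.random() < spec.membrane_fraction
        n_tmds = _draw(spec.tmd_count_sampler, rng) if is_membrane else 0
        if n_tmds < 0:
            raise ValueError(f"{pid}: negative TMD count drawn")
        if spec.start_side == "alternate":
            side = "inside" if i % 2 == 0 else "outside"
        else:
            side = spec.start_side
        parts: list[str] = []
        segs: list[Segment] = []
        pos = 1
        for t in range(n_tmds):
            lk = _draw(spec.linker_length_sampler, rng)
            if lk < 1:
                raise ValueError(f"{pid}: linker length {lk} < 1")
            parts.append(_random_seq(_LINKER_RESIDUES, _LINKER_WEIGHTS, lk, rng))
            segs.append(Segment(side, pos, pos + lk - 1))
            pos += lk
            tl = _draw(spec.tmd_length_sampler, rng)
            if not (1 <= tl):
                raise ValueError(f"{pid}: TMD length {tl} outside valid range")
            parts.append(_random_seq(_TMD_RESIDUES, _TMD_WEIGHTS, tl, rng))
            segs.append(Segment("TMhelix", pos, pos + tl - 1))
            pos += tl
            side = "outside" if side == "inside" else "inside"
        lk = _draw(spec.linker_length_sampler, rng)
        if lk < 1:
            raise ValueError(f"{pid}: linker length {lk} < 1")
        parts.append(_random_seq(_LINKER_RESIDUES, _LINKER_WEIGHTS, lk, rng))
        segs.append(Segment(side, pos, pos + lk - 1))
        seq = "".join(parts)
        if not seq:
            raise ValueError(f"{pid}: zero-length protein generated")
        seqs[pid] = seq
        anns.append(TopologyAnnotation(pid, segs))
    return seqs, anns


def write_fasta(sequences: dict[str, str]) -> str:
    from io import StringIO

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    buf = StringIO()
    seqio_write(records, buf, "fasta")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# SILAC


@dataclass(frozen=True)
class SyntheticSilacSpec:
    """Planted-effect SILAC peptide table parameters.

    ``effect_map`` holds each regulated protein's true −log2(H/L) shift
    (positive = upregulated in the light/mutant channel); proteins absent
    from it have true shift 0.  Peptide-level noise is Gaussian in log2
    space with SD ``peptide_noise_sd``, applied independently per peptide
    per replicate; peptide × replicate cells drop out uniformly at random
    at ``missingness_rate``.
    """

    n_proteins: int = 1000
    n_replicates: int = 3
    effect_map: dict = field(default_factory=dict)
    peptides_per_protein_sampler: object = field(default_factory=lambda: uniform_int(2, 8))
    peptide_noise_sd: float = 0.2
    missingness_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_noise_sd < 0:
            raise ValueError("peptide_noise_sd must be non-negative")
        if not (0.0 <= self.missingness_rate < 1.0):
            raise ValueError("missingness_rate must lie in [0, 1)")
        if self.n_proteins <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")


def silac_protein_ids(spec: SyntheticSilacSpec) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(spec.n_proteins)]


def generate_silac_table(spec: SyntheticSilacSpec) -> pd.DataFrame:
    """Long-format peptide table: protein_id, replicate, peptide_id, log2_hl.

    A protein with planted −log2(H/L) shift ``e`` has peptide log2(H/L)
    ratios centered on ``−e``.
    """
    ids = silac_protein_ids(spec)
    unknown = set(spec.effect_map) - set(ids)
    if unknown:
        raise ValueError(f"effect_map keys not among generated proteins: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, int, str, float]] = []
    for pid in ids:
        n_pep = _draw(spec.peptides_per_protein_sampler, rng)
        true_log2_hl = -float(spec.effect_map.get(pid, 0.0))
        for j in range(n_pep):
            pep = f"{pid}_pep{j + 1}"
            for rep in range(1, spec.n_replicates + 1):
                if rng.random() < spec.missingness_rate:
                    continue
                noise = rng.normal(0.0, spec.peptide_noise_sd) if spec.peptide_noise_sd else 0.0
                rows.append((pid, rep, pep, true_log2_hl + noise))
    return pd.DataFrame(rows, columns=["protein_id", "replicate", "peptide_id", "log2_hl"])


# ---------------------------------------------------------------------------
# bilayer


@dataclass(frozen=True)
class SyntheticBilayerSpec:
    """Two-leaflet point-cloud bilayer with a Gaussian dimple.

    Reference points (one per lipid) sit at z = ±``bulk_separation``/2.
    A dimple at ``dimple_center`` pulls the leaflets together by
    ``dimple_depth``·exp(−r²/2σ²), split symmetrically (each leaflet moves
    depth/2 toward the midplane); isotropic thermal noise with SD
    ``thermal_sd`` is added to z.  Lateral positions are re-drawn uniformly
    each frame (fast in-plane diffusion).  The point density is chosen for
    Monte-Carlo resolution at 2 Å binning rather than physical
    area-per-lipid realism.
    """

    box_xy: tuple[float, float] = (50.0, 50.0)
    n_lipids_per_leaflet: int = 2500
    bulk_separation: float = 40.0
    dimple_center: tuple[float, float] = (25.0, 25.0)
    dimple_depth: float = 5.0
    dimple_sigma: float = 8.0
    thermal_sd: float = 1.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimple_sigma <= 0:
            raise ValueError("dimple_sigma must be positive")
        if self.dimple_depth >= self.bulk_separation:
            raise ValueError("dimple_depth must be smaller than bulk_separation")
        if self.thermal_sd < 0:
            raise ValueError("thermal_sd must be non-negative")
        if self.n_lipids_per_leaflet < 1 or self.n_frames < 1:
            raise ValueError("counts must be positive")


def dimple_profile(spec: SyntheticBilayerSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form local separation reduction d·exp(−r²/2σ²) at (x, y)."""
    r2 = (x - spec.dimple_center[0]) ** 2 + (y - spec.dimple_center[1]) ** 2
    return spec.dimple_depth * np.exp(-r2 / (2.0 * spec.dimple_sigma**2))


def generate_bilayer_trajectory(
    spec: SyntheticBilayerSpec, withhold_tags: bool = False
) -> list[BilayerFrame]:
    """Generate frames; ``withhold_tags`` emits every point as unassigned."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lipids_per_leaflet
    lx, ly = spec.box_xy
    half = spec.bulk_separation / 2.0
    frames: list[BilayerFrame] = []
    tags = np.array([UPPER] * n + [LOWER] * n, dtype="U10")
    for k in range(spec.n_frames):
        x = rng.uniform(0.0, lx, size=2 * n)
        y = rng.uniform(0.0, ly, size=2 * n)
        defl = 0.5 * dimple_profile(spec, x, y)
        z = np.where(tags == UPPER, half - defl, -half + defl)
        if spec.thermal_sd > 0:
            z = z + rng.normal(0.0, spec.thermal_sd, size=2 * n)
        frame_tags = np.full(2 * n, "unassigned", dtype="U10") if withhold_tags else tags.copy()
        frames.append(
            BilayerFrame(
                index=k,
                xyz=np.column_stack([x, y, z]),
                leaflet=frame_tags,
                lipid_id=np.arange(2 * n),
                box_xy=spec.box_xy,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# lipidome

SpeciesKey = tuple  # (class, chain1 "C:D" or None, chain2 "C:D" or None)


@dataclass(frozen=True)
class SyntheticLipidomeSpec:
    """Class-structured lipidome with planted group effects.

    ``species_catalog`` lists (class, chain1, chain2) with chains as
    ``"carbons:double_bonds"`` strings (or None for sum-composition-only
    species); ``baseline_molpct`` is parallel to the catalog.
    ``group_effects`` maps group → species key → multiplicative factor,
    applied to the baseline before per-class renormalization to
    100 mol%/class.  Replicate noise is multiplicative lognormal with
    coefficient of variation ``noise_cv``.
    """

    species_catalog: tuple = ()
    baseline_molpct: tuple = ()
    group_effects: dict = field(default_factory=dict)
    n_replicates_per_group: int = 4
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_catalog) != len(self.baseline_molpct):
            raise ValueError("species_catalog and baseline_molpct lengths differ")
        if any(b <= 0 for b in self.baseline_molpct):
            raise ValueError("baseline mol% must be positive for every catalog species")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        catalog = set(self.species_catalog)
        for grp, eff in self.group_effects.items():
            unknown = set(eff) - catalog
            if unknown:
                raise ValueError(f"group {grp!r}: unknown species in group_effects: {unknown}")


def generate_lipidome(spec: SyntheticLipidomeSpec) -> pd.DataFrame:
    """Tidy table: class, chain1, chain2, sample, group, mol_percent.

    Group effects multiply the baseline, lognormal noise multiplies each
    replicate value, then every (sample, class) block is renormalized to
    sum to 100.
    """
    if not spec.species_catalog:
        raise ValueError("empty species catalog")
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_effects) or ["WT"]
    if "WT" not in groups:
        groups = ["WT"] + groups
    base = np.asarray(spec.baseline_molpct, dtype=float)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))  # lognormal sd matching the CV
    rows = []
    for grp in groups:
        eff = spec.group_effects.get(grp, {})
        factors = np.array([eff.get(sp, 1.0) for sp in spec.species_catalog])
        for rep in range(1, spec.n_replicates_per_group + 1):
            sample = f"{grp}_r{rep}"
            vals = base * factors
            if spec.noise_cv > 0:
                vals = vals * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(vals)))
            for (cls, c1, c2), v in zip(spec.species_catalog, vals):
                rows.append((cls, c1, c2, sample, grp, v))
    df = pd.DataFrame(rows, columns=["class", "chain1", "chain2", "sample", "group", "mol_percent"])
    total = df.groupby(["sample", "class"])["mol_percent"].transform("sum")
    df["mol_percent"] = 100.0 * df["mol_percent"] / total
    return df


def default_lipidome_spec(seed: int = 0, noise_cv: float = 0.1) -> SyntheticLipidomeSpec:
    """A yeast-like glycerophospholipid catalog with planted asymmetric-species
    enrichment in the mutant group.

    Each class carries common symmetric species (32:x / 34:x) plus minor
    asymmetric C-26/C-28 species pairing a 10:0 chain with a 16–18-carbon
    chain.  The ``tul1`` group doubles the C-26 species and raises the C-28
    species by 50% — the planted truth the asymmetry analysis should
    recover.
    """
    catalog: list[SpeciesKey] = []
    baseline: list[float] = []
    mutant_eff: dict[SpeciesKey, float] = {}
    for cls in ("PI", "PS", "PA", "PC", "PE"):
        common = [
            (("10:0", "16:0"), 1.0, 2.0),   # C-26 asymmetric, both saturated
            (("10:0", "18:1"), 0.8, 1.5),   # C-28 asymmetric, long chain mono-unsat.
            (("16:0", "16:1"), 30.0, 1.0),
            (("16:0", "18:1"), 28.0, 1.0),
            (("16:1", "18:1"), 22.0, 1.0),
            (("18:0", "18:1"), 12.0, 1.0),
            (("14:0", "16:1"), 6.2, 1.0),
        ]
        for (c1, c2), b, f in common:
            key = (cls, c1, c2)
            catalog.append(key)
            baseline.append(b)
            if f != 1.0:
                mutant_eff[key] = f
    return SyntheticLipidomeSpec(
        species_catalog=tuple(catalog),
        baseline_molpct=tuple(baseline),
        group_effects={"WT": {}, "tul1": mutant_eff},
        n_replicates_per_group=4,
        noise_cv=noise_cv,
        seed=seed,
    )
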