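"""Run orchestration: validated configs, staged execution, provenance.

A run is described by a YAML config (schema-validated, unknown keys
rejected) selecting stages out of ``simulate → silac / tmd / lipids /
thickness → report``.  Stages communicate only through files under the
output directory; the resolved config and a JSON report with per-stage
summaries, the seed, and a config hash are written next to the outputs, so
an identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import lipids as lip
from . import silac as sil
from . import synthetic as syn
from . import thinning as thin
from . import tmd as tmdmod
from .topology import parse_topology, write_topology

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "validate_config", "run"]

CONFIG_ERROR_EXIT = 2
DATA_ERROR_EXIT = 3


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2)."""

    exit_code = CONFIG_ERROR_EXIT


class DataError(RuntimeError):
    """Stage failure on data (exit code 3)."""

    exit_code = DATA_ERROR_EXIT


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SilacSimConfig(_Block):
    n_proteins: int = Field(400, gt=0)
    n_replicates: int = Field(3, gt=0)
    n_effect_a: int = Field(25, ge=0)
    n_effect_b: int = Field(25, ge=0)
    n_overlap: int = Field(5, ge=0)
    effect_size: float = Field(1.0, gt=0)
    peptide_noise_sd: float = Field(0.2, ge=0)
    missingness_rate: float = Field(0.1, ge=0, lt=1)


class ProteomeSimConfig(_Block):
    n_proteins: int = Field(40, gt=0)
    tmd_count_lo: int = Field(1, ge=0)
    tmd_count_hi: int = Field(3, ge=0)
    tmd_length_lo: int = Field(14, ge=10)
    tmd_length_hi: int = Field(18, le=30)
    start_side: Literal["inside", "outside", "alternate"] = "alternate"


class BilayerSimConfig(_Block):
    box_xy: tuple[float, float] = (50.0, 50.0)
    n_lipids_per_leaflet: int = Field(2500, gt=0)
    bulk_separation: float = Field(40.0, gt=0)
    dimple_depth_a: float = Field(5.0, ge=0)
    dimple_depth_b: float = Field(2.5, ge=0)
    dimple_sigma: float = Field(8.0, gt=0)
    thermal_sd: float = Field(1.0, ge=0)
    n_frames: int = Field(100, gt=0)


class LipidomeSimConfig(_Block):
    noise_cv: float = Field(0.1, ge=0)
    n_replicates_per_group: int = Field(4, gt=1)


class SimulateConfig(_Block):
    silac: SilacSimConfig = SilacSimConfig()
    proteome_short: ProteomeSimConfig = ProteomeSimConfig()
    proteome_long: ProteomeSimConfig = ProteomeSimConfig(
        n_proteins=40, tmd_count_lo=4, tmd_count_hi=14, tmd_length_lo=20, tmd_length_hi=24
    )
    bilayer: BilayerSimConfig = BilayerSimConfig()
    lipidome: LipidomeSimConfig = LipidomeSimConfig()


class SilacConfig(_Block):
    ratio_min: float = Field(0.3, ge=0)
    p_max: float = Field(0.05, gt=0, le=1)
    min_peptides: int = Field(2, ge=1)
    min_replicates: int = Field(2, ge=1)
    background_policy: Literal["background", "target_only", "pooled"] = "background"
    aggregate_method: Literal["median", "mean"] = "median"
    display_floor: float = -1.0


class TmdConfig(_Block):
    l_thresholds: list[int] = Field(default_factory=lambda: [16, 18])
    count_threshold: int = Field(10, ge=1)


class LipidsConfig(_Block):
    q: float = Field(0.01, gt=0, lt=1)
    groups: tuple[str, str] = ("WT", "tul1")
    family: Literal["class", "global"] = "class"
    delta_min: int = Field(6, ge=1)


class ThicknessConfig(_Block):
    bin_size: float = Field(2.0, gt=0)
    window: tuple[float, float] = (0.6, 1.0)
    bulk_radius: float = Field(25.0, gt=0)


STAGES = ("simulate", "silac", "tmd", "lipids", "thickness", "report")


class RunConfig(_Block):
    seed: int = 0
    out_dir: str = "results/run"
    stages: list[Literal["simulate", "silac", "tmd", "lipids", "thickness", "report"]] = Field(
        default_factory=lambda: list(STAGES)
    )
    log_level: str = "INFO"
    simulate: SimulateConfig = SimulateConfig()
    silac: SilacConfig = SilacConfig()
    tmd: TmdConfig = TmdConfig()
    lipids: LipidsConfig = LipidsConfig()
    thickness: ThicknessConfig = ThicknessConfig()


def validate_config(text: str) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _proteome_spec(cfg: ProteomeSimConfig, seed: int) -> syn.SyntheticProteomeSpec:
    return syn.SyntheticProteomeSpec(
        n_proteins=cfg.n_proteins,
        tmd_count_sampler=syn.uniform_int(cfg.tmd_count_lo, cfg.tmd_count_hi),
        tmd_length_sampler=syn.uniform_int(cfg.tmd_length_lo, cfg.tmd_length_hi),
        start_side=cfg.start_side,
        seed=seed,
    )


def _df_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    seeds = _sub_seeds(cfg.seed, 6)
    s = cfg.simulate

    # SILAC: two contrasts with planted effect sets sharing n_overlap proteins
    ids = [f"P{i + 1:04d}" for i in range(s.silac.n_proteins)]
    set_a = ids[: s.silac.n_effect_a]
    start_b = max(s.silac.n_effect_a - s.silac.n_overlap, 0)
    set_b = ids[start_b : start_b + s.silac.n_effect_b]
    for name, planted, seed in (("A", set_a, seeds[0]), ("B", set_b, seeds[1])):
        spec = syn.SyntheticSilacSpec(
            n_proteins=s.silac.n_proteins,
            n_replicates=s.silac.n_replicates,
            effect_map={p: s.silac.effect_size for p in planted},
            peptide_noise_sd=s.silac.peptide_noise_sd,
            missingness_rate=s.silac.missingness_rate,
            seed=seed,
        )
        _df_tsv(syn.generate_silac_table(spec), out / f"silac_{name}.tsv")
        (out / f"planted_{name}.txt").write_text("\n".join(planted) + "\n")
    (out / "membrane.txt").write_text("\n".join(ids) + "\n")

    # proteomes: a short-TMD set and a long/multi-pass set
    for name, pcfg, seed in (
        ("short", s.proteome_short, seeds[2]),
        ("long", s.proteome_long, seeds[3]),
    ):
        seqs, anns = syn.generate_proteome(_proteome_spec(pcfg, seed))
        (out / f"proteome_{name}.fasta").write_text(syn.write_fasta(seqs))
        (out / f"topology_{name}.gff3").write_text(write_topology(anns, "gff3"))
        (out / f"topology_{name}.3line").write_text(
            write_topology(anns, "three_line", sequences=seqs)
        )

    # lipidome with planted asymmetric-species enrichment
    lspec = syn.default_lipidome_spec(seed=seeds[4], noise_cv=s.lipidome.noise_cv)
    lspec = syn.SyntheticLipidomeSpec(
        species_catalog=lspec.species_catalog,
        baseline_molpct=lspec.baseline_molpct,
        group_effects=lspec.group_effects,
        n_replicates_per_group=s.lipidome.n_replicates_per_group,
        noise_cv=s.lipidome.noise_cv,
        seed=seeds[4],
    )
    _df_tsv(syn.generate_lipidome(lspec), out / "lipidome.tsv")

    # bilayer trajectories, two dimple depths
    for name, depth, seed in (("wt", s.bilayer.dimple_depth_a, seeds[5]),
                              ("mut", s.bilayer.dimple_depth_b, seeds[5])):
        bspec = syn.SyntheticBilayerSpec(
            box_xy=s.bilayer.box_xy,
            n_lipids_per_leaflet=s.bilayer.n_lipids_per_leaflet,
            bulk_separation=s.bilayer.bulk_separation,
            dimple_center=(s.bilayer.box_xy[0] / 2, s.bilayer.box_xy[1] / 2),
            dimple_depth=depth,
            dimple_sigma=s.bilayer.dimple_sigma,
            thermal_sd=s.bilayer.thermal_sd,
            n_frames=s.bilayer.n_frames,
            seed=seed,
        )
        frames = syn.generate_bilayer_trajectory(bspec)
        (out / f"bilayer_{name}.xyz").write_text(thin.write_xyz_frames(frames))
    return {
        "planted_A": len(set_a),
        "planted_B": len(set_b),
        "planted_overlap": len(set(set_a) & set(set_b)),
    }


def _stage_silac(cfg: RunConfig, out: Path) -> dict:
    sc = cfg.silac
    membrane = (out / "membrane.txt").read_text().split()
    results = {}
    for name in ("A", "B"):
        path = out / f"silac_{name}.tsv"
        if not path.exists():
            raise DataError(f"missing input {path}")
        peptides = pd.read_csv(path, sep="\t")
        res = sil.diff_analysis(
            peptides,
            membrane_proteins=membrane,
            min_peptides=sc.min_peptides,
            min_replicates=sc.min_replicates,
            ratio_min=sc.ratio_min,
            p_max=sc.p_max,
            background_policy=sc.background_policy,
            aggregate_method=sc.aggregate_method,
        )
        _df_tsv(res, out / f"volcano_{name}.tsv")
        results[name] = res
    overlap = sil.overlap_contrasts(results["A"], results["B"], display_floor=sc.display_floor)
    _df_tsv(overlap, out / "overlap.tsv")
    counts = overlap["class"].value_counts().to_dict()
    return {
        "n_significant_A": int(results["A"]["significant"].sum()),
        "n_significant_B": int(results["B"]["significant"].sum()),
        "overlap_classes": {k: int(v) for k, v in sorted(counts.items())},
    }


def _stage_tmd(cfg: RunConfig, out: Path) -> dict:
    summaries = {}
    sigs = {}
    for name in ("short", "long"):
        topo_path = out / f"topology_{name}.gff3"
        if not topo_path.exists():
            raise DataError(f"missing input {topo_path}")
        anns = parse_topology(topo_path.read_text())
        seqs = _read_fasta(out / f"proteome_{name}.fasta")
        tmds = {a.protein_id: tmdmod.extract_tmds(a, seqs.get(a.protein_id)) for a in anns}
        rows = [
            (t.protein_id, t.index, t.start, t.end, t.length, t.orientation, t.oriented_sequence)
            for ts in tmds.values()
            for t in ts
        ]
        _df_tsv(
            pd.DataFrame(
                rows,
                columns=["protein", "index", "start", "end", "length", "orientation",
                         "oriented_seq"],
            ),
            out / f"tmds_{name}.tsv",
        )
        sig = tmdmod.signature_stats(tmds)
        sigs[name] = sig
        summary = sig.summary(cfg.tmd.l_thresholds, cfg.tmd.count_threshold)
        (out / f"signature_{name}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        summaries[name] = summary
    comparison = tmdmod.compare_signatures(sigs["short"], sigs["long"])
    (out / "signature_comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True)
    )
    summaries["comparison"] = comparison
    return summaries


def _stage_lipids(cfg: RunConfig, out: Path) -> dict:
    path = out / "lipidome.tsv"
    if not path.exists():
        raise DataError(f"missing input {path}")
    table = pd.read_csv(path, sep="\t")
    table = lip.normalize_per_class(table)
    res = lip.compare_groups(
        table, cfg.lipids.groups, q=cfg.lipids.q, family=cfg.lipids.family
    )
    calls = [
        lip.classify_asymmetry(r["chain1"], r["chain2"], delta_min=cfg.lipids.delta_min)
        for _, r in res.iterrows()
    ]
    res["total_acyl"] = [
        lip.total_acyl_label(r["chain1"], r["chain2"]) for _, r in res.iterrows()
    ]
    res["asymmetry"] = [c.call for c in calls]
    res["saturation_profile"] = [c.saturation_profile for c in calls]
    _df_tsv(res, out / "lipid_comparison.tsv")
    disc = res[res["discovery"]]
    return {
        "n_species": len(res),
        "n_discoveries": int(res["discovery"].sum()),
        "n_asymmetric_discoveries": int((disc["asymmetry"] == "asymmetric").sum()),
    }


def _stage_thickness(cfg: RunConfig, out: Path) -> dict:
    tc = cfg.thickness
    maps = {}
    summaries = {}
    for name in ("wt", "mut"):
        path = out / f"bilayer_{name}.xyz"
        if not path.exists():
            raise DataError(f"missing input {path}")
        frames = thin.read_xyz_frames(path.read_text())
        tmap = thin.thickness_map(frames, bin_size=tc.bin_size, window=tuple(tc.window))
        (out / f"thickness_map_{name}.tsv").write_text(tmap.to_tsv())
        summ = thin.thinning_summary(tmap, bulk_radius=tc.bulk_radius)
        maps[name] = tmap
        summaries[name] = {
            "bulk_thickness": summ.bulk_thickness,
            "min_thickness": summ.min_thickness,
            "max_thinning": summ.max_thinning,
        }
    diff = thin.difference_map(maps["wt"], maps["mut"], bulk_radius=tc.bulk_radius)
    summaries["delta_max_thinning"] = diff.delta_max_thinning
    (out / "thinning_summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))
    return summaries


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    if not path.exists():
        return {}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the report.

    Every stage reads only files under ``config.out_dir`` written by earlier
    stages (or present beforehand) and writes its outputs there.  The
    resolved config and the report JSON are always persisted.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    (out / "resolved_config.yaml").write_text(resolved)
    # hash the scientific parameters only, not where the run lives
    hashed = config.model_dump(mode="json", exclude={"out_dir", "log_level"})
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]

    runners = {
        "simulate": _stage_simulate,
        "silac": _stage_silac,
        "tmd": _stage_tmd,
        "lipids": _stage_lipids,
        "thickness": _stage_thickness,
    }
    report: dict = {"seed": config.seed, "config_hash": cfg_hash, "stages": {}}
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        if stage == "report":
            continue
        logger.info("running stage %s", stage)
        try:
            report["stages"][stage] = runners[stage](config, out)
        except (ConfigError, DataError):
            raise
        except (OSError, ValueError, KeyError) as exc:
            raise DataError(f"stage {stage!r} failed: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
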