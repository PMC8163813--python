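"""End-to-end pipeline: synthesize tables, reconstruct cell numbers,
summarize phases, fit rates, predict EdU fractions, compare orientations."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .edu_model import PulseParams, pulse_chase_fraction, short_pulse_fraction
from .inference import fit_two_phase
from .lineage_model import LineageParams, two_phase_trajectory
from .orientation_stats import bin_angles, chi_squared_bins, ks_two_sample, proportions_anova
from .synthetic_data import GeneratorConfig, default_config, generate_all_tables
from .tissue_growth import build_cell_number_series, summarize_phase

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("epistrat")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=default_config)
    lineage: LineageParams = field(default_factory=LineageParams)
    pulse: PulseParams = field(default_factory=PulseParams)
    outdir: Path = Path("results/pipeline")
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Load a YAML or JSON config document; flat overrides per section."""
        path = Path(path)
        doc = yaml.safe_load(path.read_text()) or {}
        lineage = LineageParams(**doc.get("lineage", {}))
        gen_doc = dict(doc.get("generator", {}))
        if seed is not None:
            gen_doc["seed"] = seed
        base = default_config(seed=gen_doc.pop("seed", 0), params=lineage)
        allowed = {
            "stages", "embryos_per_stage", "animals_per_stage",
            "edu_cells_per_animal", "angles_per_animal",
        }
        unknown = set(gen_doc) - allowed
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        if "stages" in gen_doc:
            gen_doc["stages"] = tuple(float(s) for s in gen_doc["stages"])
        generator = dataclasses.replace(base, **gen_doc)
        pulse = PulseParams(**doc.get("pulse", {}))
        return cls(
            generator=generator,
            lineage=lineage,
            pulse=pulse,
            outdir=Path(doc.get("outdir", "results/pipeline")),
            log_level=str(doc.get("log_level", "INFO")),
        )


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tables plus a JSON run report.

    Stages: synthetic tables -> cell-number series -> phase summaries ->
    rate fits -> EdU predictions -> orientation comparisons.  Each stage logs
    its seed/parameters; any failure is re-raised naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.generator.seed,
        "lineage": _to_jsonable(config.lineage),
        "pulse": _to_jsonable(config.pulse),
    }
    stage = "synthetic tables"
    try:
        log.info("generating synthetic tables (seed=%d)", config.generator.seed)
        tables = generate_all_tables(config.generator)
        for name, df in tables.items():
            tio.write_table(df, out / f"{name}.csv", schema=name)

        stage = "cell-number series"
        series = build_cell_number_series(tables["density"], tables["growth"])
        tio.write_table(series, out / "cellnumber.csv", schema="cellnumber")

        stage = "phase summaries"
        p = config.lineage
        phases = [
            summarize_phase(series, "total", p.t_start, p.t_switch),
            summarize_phase(series, "total", p.t_switch, p.t_end),
        ]
        report["phases"] = [_to_jsonable(ph) for ph in phases]

        stage = "rate fit"
        fits = fit_two_phase(
            series,
            t_switch=p.t_switch,
            n_bootstrap=200,
            seed=np.random.SeedSequence(config.generator.seed, spawn_key=(100,)),
            density_table=tables["density"],
            growth_table=tables["growth"],
        )
        report["fits"] = [_to_jsonable(f) for f in fits]

        stage = "model trajectory"
        traj = two_phase_trajectory(p)
        traj_out = traj.assign(replicate=0)[["replicate", "time", "b", "s", "total"]]
        tio.write_table(traj_out, out / "trajectory.csv", schema="trajectory")

        stage = "EdU predictions"
        report["edu"] = {
            "short_pulse_fraction": short_pulse_fraction(
                config.pulse.lam, config.pulse.t_s
            ),
            "pulse_chase_fraction": pulse_chase_fraction(config.pulse),
        }

        stage = "orientation analyses"
        angles = tables["angles"]
        orient: dict = {}
        stages_present = sorted(angles["stage"].unique())
        genos = sorted(angles["genotype"].unique())
        for st in stages_present:
            sub = angles[angles["stage"] == st]
            if len(genos) != 2:
                break
            a = sub[sub["genotype"] == genos[0]]["angle_deg"].to_numpy()
            b = sub[sub["genotype"] == genos[1]]["angle_deg"].to_numpy()
            bp_a = bin_angles(a, group=genos[0])
            bp_b = bin_angles(b, group=genos[1])
            per_animal = [
                (g, an, bin_angles(gr["angle_deg"].to_numpy(), group=an))
                for (g, an), gr in sub.groupby(["genotype", "animal_id"])
            ]
            orient[f"E{st}"] = {
                "proportions": {
                    genos[0]: bp_a.proportions,
                    genos[1]: bp_b.proportions,
                },
                "chi_squared": _to_jsonable(chi_squared_bins(bp_a.counts, bp_b.counts)),
                "ks": _to_jsonable(ks_two_sample(a, b)),
                "anova_interaction": _to_jsonable(proportions_anova(per_animal)),
            }
        report["orientation"] = orient
    except Exception as exc:
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(_to_jsonable(report), indent=2))
    log.info("pipeline complete; outputs in %s", out)
    return report
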