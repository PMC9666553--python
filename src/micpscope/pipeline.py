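"""End-to-end pipeline: synthetic generation → segmentation → quantification.

For every replicate and sampled position the pipeline

1. generates the ground-truth scene (settled bacteria at t = 0, crystals
   grown to the final time),
2. renders the brightfield t = 0, phase-contrast t = 0 and brightfield
   t = final images,
3. segments grains, bacteria and crystals and composes the phase map,
4. derives the position quantities (bacterial concentration, crystal
   records, CaCO3 mass, local efficiency),

then aggregates replicates (mean and mean absolute deviation per position)
and, if a pressure series is supplied, computes the permeability trace.
Everything is deterministic under the configured seed; per-(replicate,
position) streams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chip_geometry import ChipDesign, make_heterogeneous_design, make_homogeneous_design
from .config import RunConfig
from .hydraulics import PressureSeries, permeability_trace
from .io import (
    QUANT_COLUMNS,
    write_aggregate_csv,
    write_mask,
    write_phase_map,
    write_quant_csv,
)
from .quantify import (
    PositionQuant,
    bacterial_stats,
    crystal_records,
    local_efficiency,
    position_mass,
    theoretical_mass,
)
from .segmentation import (
    compose_phase_map,
    segment_bacteria,
    segment_crystals,
    segment_grains,
)
from .synth_imaging import (
    GrowthParams,
    NoiseParams,
    evolve_scene,
    render_brightfield,
    render_phase_contrast,
    seed_bacteria,
)

__all__ = ["build_design", "process_position", "run_pipeline"]

log = logging.getLogger("micpscope")

AGGREGATE_METRICS = [
    "bact_conc_per_mL",
    "n_crystals",
    "mean_D_um",
    "mass_g",
    "efficiency_pct",
]


def _derived_seed(*keys: int) -> int:
    """Deterministic 31-bit seed from a tuple of integers."""
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1)[0] % (2**31))


def build_design(config: RunConfig, replicate: int = 0) -> ChipDesign:
    """Chip design for one replicate (heterogeneous packings differ by seed)."""
    if config.chip_kind == "homogeneous":
        return make_homogeneous_design(
            config.throat_um,
            config.porosity,
            config.length_um,
            config.width_um,
            config.depth_um,
        )
    if config.chip_kind == "heterogeneous":
        return make_heterogeneous_design(
            config.throat_min_um,
            config.throat_max_um,
            config.throat_um,
            config.porosity,
            config.length_um,
            config.width_um,
            seed=_derived_seed(config.seed, 977, replicate),
            depth_um=config.depth_um,
        )
    raise ValueError(f"unknown chip kind {config.chip_kind!r}")


def process_position(
    config: RunConfig,
    design: ChipDesign,
    replicate: int,
    position: int,
    out_dir: Path | None = None,
) -> PositionQuant:
    """Generate, segment and quantify one position of one replicate."""
    field = config.field_for_position(position)
    seed = _derived_seed(config.seed, replicate, position)
    ps = config.pixel_size_um
    scene0 = seed_bacteria(design, config.bacteria_concentration_per_ml, field, seed)
    growth = GrowthParams()
    scene_t = evolve_scene(scene0, config.t_final_h, growth, seed=seed + 1)
    noise0 = NoiseParams(config.noise_sigma, config.illumination_gradient, seed + 2)
    noise_t = NoiseParams(config.noise_sigma, config.illumination_gradient, seed + 3)
    bf0 = render_brightfield(scene0, ps, noise0)
    pc0 = render_phase_contrast(scene0, ps, noise0)
    bft = render_brightfield(scene_t, ps, noise_t)

    grain = segment_grains(
        bf0, config.sensitivity_grain, (config.grain_min_area_px, np.inf)
    )
    bact = segment_bacteria(
        pc0, grain, config.sensitivity_bacteria, config.bacteria_area_px
    )
    cryst = segment_crystals(
        bft,
        grain,
        config.sensitivity_crystal,
        config.closing_radius_px,
        config.thinness_cutoff,
    )
    phase_map = compose_phase_map(grain, bact, cryst)

    stats = bacterial_stats(bact, grain, ps, config.depth_um)
    records = crystal_records(cryst, ps)
    mass = position_mass(records)
    pv_local = (grain.size - int(grain.sum())) * ps**2 * config.depth_um * 1e-9
    m_theor = theoretical_mass(config.flow, config.cs_duration_s)
    eff = local_efficiency(mass, pv_local, config.flow.pv_tot_ul, m_theor)
    quant = PositionQuant(
        position=position,
        x_mm=(config.position_x_um(position) + config.field_x_um / 2.0) * 1e-3,
        bacteria=stats,
        crystals=tuple(records),
        pore_volume_ul=pv_local,
        mass_g=mass,
        efficiency_pct=eff,
    )
    if out_dir is not None:
        stem = out_dir / f"rep{replicate}_pos{position:02d}"
        write_mask(f"{stem}_grain.png", grain)
        write_mask(f"{stem}_bacteria.png", bact)
        write_mask(f"{stem}_crystal.png", cryst)
        write_phase_map(f"{stem}_phasemap.png", phase_map)
    return quant


def _quant_row(q: PositionQuant) -> dict:
    return {
        "position": q.position,
        "x_mm": q.x_mm,
        "bact_coverage_um2": q.bacteria.coverage_um2,
        "bact_count": q.bacteria.count,
        "bact_conc_per_mL": q.bacteria.concentration_per_ml,
        "n_crystals": q.n_crystals,
        "mean_D_um": q.mean_diameter_um,
        "mass_g": q.mass_g,
        "PV_l_uL": q.pore_volume_ul,
        "efficiency_pct": q.efficiency_pct,
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    pressure: PressureSeries | None = None,
    write_masks: bool = True,
) -> dict:
    """Run the full pipeline; returns the JSON-serializable run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    positions = config.active_positions()
    log.info(
        "pipeline start: %d replicates x %d positions", config.replicates, len(positions)
    )
    per_rep_frames: list[pd.DataFrame] = []
    outputs: list[str] = []
    for rep in range(1, config.replicates + 1):
        try:
            design = build_design(config, rep)
        except Exception as exc:
            raise RuntimeError(f"[design] replicate {rep}: {exc}") from exc
        rows = []
        for pos in positions:
            log.info("replicate %d position %d", rep, pos)
            try:
                q = process_position(
                    config, design, rep, pos, out if write_masks else None
                )
            except Exception as exc:
                raise RuntimeError(
                    f"[position] replicate {rep} position {pos}: {exc}"
                ) from exc
            rows.append(_quant_row(q))
        path = out / f"quant_rep{rep}.csv"
        write_quant_csv(path, rows)
        outputs.append(path.name)
        per_rep_frames.append(pd.DataFrame(rows, columns=QUANT_COLUMNS))

    agg = {"position": positions, "x_mm": per_rep_frames[0]["x_mm"].to_numpy()}
    for metric in AGGREGATE_METRICS:
        stack = np.vstack([df[metric].to_numpy(dtype=float) for df in per_rep_frames])
        agg[f"{metric}_mean"] = stack.mean(axis=0)
        agg[f"{metric}_mad"] = np.abs(stack - stack.mean(axis=0)).mean(axis=0)
    agg_path = out / "quant_aggregate.csv"
    write_aggregate_csv(agg_path, pd.DataFrame(agg))
    outputs.append(agg_path.name)

    if pressure is not None:
        try:
            trace = permeability_trace(pressure, config.flow)
        except Exception as exc:
            raise RuntimeError(f"[permeability] {exc}") from exc
        perm_path = out / "permeability.csv"
        pd.DataFrame(
            {
                "time_s": trace.time_s,
                "dp_Pa_smooth": trace.dp_pa_smooth,
                "k_m2": trace.k_m2,
                "reduction_pct": trace.reduction_pct,
            }
        ).to_csv(perm_path, index=False)
        outputs.append(perm_path.name)

    config_json = json.dumps(asdict(config), sort_keys=True, default=list)
    manifest = {
        "package": "micpscope",
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "replicates": config.replicates,
        "positions": positions,
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline done: %d outputs in %s", len(outputs), out)
    return manifest
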