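"""End-to-end processing driver: classify -> size -> distributions -> profiles.

``run_pipeline`` executes the full chain on a validated configuration, in
the same stage order the measurement analysis uses, and echoes every
stage's parameters and event counts (with discard reasons) into the result
bundle so the filtering chain is auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as caspm_io
from .classification import (
    Channel,
    ParticleType,
    TypeBoundaries,
    classify_arrays,
)
from .concentration import ChannelCalibration, A_S_CHANNEL_M2, A_L_CHANNEL_M2
from .mie_optics import (
    OpticalConfig,
    PURE_WATER_INDEX,
    SEAWATER_INDEX,
    SLookupTable,
    build_lookup_table,
)
from .profiles import depth_profile, regress_vs_covariate
from .size_distribution import (
    ChannelRegion,
    SizeGrid,
    build_size_distribution,
    integrate,
    volume_distribution,
)
from .sizing import BCCalibration, size_events, synthetic_bc_calibration
from .synthetic import InstrumentModel, StationSpec, simulate_cruise

__all__ = ["PipelineResult", "run_pipeline", "process_sample", "medium_index"]


def medium_index(medium: str) -> float:
    if medium == "seawater":
        return SEAWATER_INDEX
    if medium in ("pure_water", "water"):
        return PURE_WATER_INDEX
    raise ValueError(f"unknown medium {medium!r}")


@dataclass
class PipelineResult:
    """Everything the chain produced, plus an auditable stage log."""

    typed_events: dict                    # sample_id -> DataFrame
    distributions: dict                   # sample_id -> SizeResolvedConcentration
    sample_table: pd.DataFrame            # per-sample integrated concentrations
    station_profiles: dict                # station -> depth profile DataFrame
    regressions: pd.DataFrame             # per-type OLS vs covariates
    parameters: dict
    log: list = field(default_factory=list)


def process_sample(
    events: pd.DataFrame,
    boundaries: TypeBoundaries,
    region: ChannelRegion,
    table: SLookupTable,
    bc_cal: BCCalibration | None,
    grid: SizeGrid,
    sampled_volume_ml: dict,
    log: list | None = None,
    sample_id: str = "?",
):
    """Classify, size and histogram one sample's events."""
    ev = events.copy().reset_index(drop=True)
    ev["region"] = region.assign(
        ev["channel"].to_numpy(), ev["re_s_um"].to_numpy(), ev["im_s_um"].to_numpy()
    )
    ev["type"] = int(ParticleType.UNCLASSIFIED)
    for channel in Channel:
        use = (ev["channel"] == channel.value) & (ev["region"] != "discard")
        if use.any():
            ev.loc[use, "type"] = classify_arrays(
                ev.loc[use, "re_s_um"].to_numpy(),
                ev.loc[use, "im_s_um"].to_numpy(),
                channel,
                boundaries,
            )
    diam, m_ml, resid = size_events(
        ev["type"].to_numpy(),
        ev["re_s_um"].to_numpy(),
        ev["im_s_um"].to_numpy(),
        table,
        bc_cal,
    )
    ev["diameter_um"] = diam
    ev["m_ml"] = m_ml
    ev["residual_um"] = resid
    dist = build_size_distribution(
        diam,
        ev["type"].to_numpy(),
        ev["region"].to_numpy(),
        grid,
        sampled_volume_ml,
        metadata={"sample_id": sample_id},
    )
    dist = volume_distribution(dist)
    if log is not None:
        n_disc = int((ev["region"] == "discard").sum())
        n_excl = int((ev["type"] == int(ParticleType.EXCLUDED)).sum())
        log.append(
            f"sample {sample_id}: {len(ev)} events in, {n_disc} discarded by window, "
            f"{n_excl} excluded by ellipse"
        )
    return ev, dist


def _build_runtime(cfg: dict):
    medium = cfg.get("medium", "seawater")
    wavelength = float(cfg.get("optics", {}).get("wavelength_um", 0.6328))
    optics = OpticalConfig(wavelength_vacuum=wavelength, medium_index=medium_index(medium))

    bnd_cfg = cfg.get("boundaries", {})
    curve_m = tuple(bnd_cfg.get("curve_m", (1.38, 1.43, 1.60)))
    boundaries = TypeBoundaries.from_optics(
        optics,
        curve_m=curve_m,
        line_a=tuple(bnd_cfg.get("line_a", (-5.5, 0.6))),
        line_b=tuple(bnd_cfg.get("line_b", (0.72, -0.0072))),
        ellipse_a=float(bnd_cfg.get("ellipse", (0.2, 0.025))[0]),
        ellipse_b=float(bnd_cfg.get("ellipse", (0.2, 0.025))[1]),
    )

    lk = cfg.get("lookup", {})
    table = build_lookup_table(
        optics,
        m_range=(float(lk.get("m_min", 1.34)), float(lk.get("m_max", 2.40))),
        d_range=(float(lk.get("d_min", 0.1)), float(lk.get("d_max", 10.0))),
        m_step=float(lk.get("m_step", 0.005)),
        n_diameters=int(lk.get("n_diameters", 2000)),
    )

    cal_cfg = cfg.get("calibration", {})
    if "flow_velocity_m_s" not in cal_cfg and "simulate" not in cfg:
        raise caspm_io.FormatError(
            "calibration.flow_velocity_m_s is required (no published default exists)"
        )
    u = float(cal_cfg.get("flow_velocity_m_s", 0.5))
    duty = float(cal_cfg.get("duty_cycle", 1.0))
    cals = {
        "s": ChannelCalibration(
            float(cal_cfg.get("effective_area_s_m2", A_S_CHANNEL_M2)), u, duty
        ),
        "l": ChannelCalibration(
            float(cal_cfg.get("effective_area_l_m2", A_L_CHANNEL_M2)), u, duty
        ),
    }

    bc_setting = cfg.get("bc_calibration", "synthetic")
    bc_cal = (
        synthetic_bc_calibration(optics)
        if bc_setting == "synthetic"
        else BCCalibration.from_file(bc_setting)
    )

    g = cfg.get("grid", {})
    grid = SizeGrid.from_range(
        float(g.get("d_min", 0.1)),
        float(g.get("d_max", 10.0)),
        int(g.get("bins_per_decade", 16)),
    )
    return optics, boundaries, table, cals, bc_cal, grid


def run_pipeline(cfg: dict, output_dir=None) -> PipelineResult:
    """Run the full chain from a validated config mapping.

    With a ``simulate`` section, a synthetic cruise is generated first and
    then processed exactly like measured data.  Deterministic given the
    config (all randomness flows from ``seed``).
    """
    log: list = []
    seed = int(cfg.get("seed", 0))
    if "simulate" not in cfg and not cfg.get("events"):
        raise caspm_io.FormatError(
            "no events: provide 'events' paths or a 'simulate' section"
        )
    optics, boundaries, table, cals, bc_cal, grid = _build_runtime(cfg)
    log.append(
        f"runtime: medium_index={optics.medium_index}, lookup {table.shape}, "
        f"grid {grid.n_bins} bins"
    )

    # ---- acquire events -------------------------------------------------
    samples: dict[str, pd.DataFrame] = {}
    durations: dict[str, float] = {}
    duty: dict[str, float] = {}
    metadata = None
    if "simulate" in cfg:
        sim = cfg.get("simulate") or {}
        n_st = int(sim.get("stations", 2))
        instrument = InstrumentModel.default(
            medium_index=optics.medium_index,
            flow_velocity=float(sim.get("flow_velocity_m_s", 0.5)),
            noise_sigma_um=float(sim.get("noise_sigma_um", 0.005)),
        )
        specs = [
            StationSpec(
                station=f"C{i + 1:03d}",
                depths_m=tuple(sim.get("depths_m", (0.0, 10.0, 20.0, 30.0, 50.0, 100.0))),
                chl_coupling=float(sim.get("chl_coupling", 0.8)),
                duration_s=float(sim.get("duration_s", 120.0)),
            )
            for i in range(n_st)
        ]
        events_by_sample, metadata, _truth = simulate_cruise(specs, instrument, seed)
        for sid, ev in events_by_sample.items():
            samples[sid] = ev
            durations[sid] = float(specs[0].duration_s)
            duty[sid] = instrument.s_cal.duty_cycle
        cals = {"s": instrument.s_cal, "l": instrument.l_cal}
        log.append(f"simulated {n_st} stations, {len(samples)} samples, seed {seed}")
    else:
        for p in cfg.get("events") or []:
            ef = caspm_io.read_events(p)
            sid = ef.header.get("sample_id", Path(p).stem)
            samples[sid] = ef.events
            durations[sid] = ef.duration_s
            duty[sid] = ef.duty_cycle
            for ln, reason in ef.rejected:
                log.append(f"{p}:{ln}: rejected row ({reason})")
        if "metadata" in cfg:
            metadata = pd.read_csv(cfg["metadata"])
    if not samples:
        raise caspm_io.FormatError("no events: provide 'events' paths or a 'simulate' section")

    # ---- per-sample processing -----------------------------------------
    typed, dists, rows = {}, {}, []
    for sid, ev in samples.items():
        t = durations[sid]
        if t <= 0:
            raise caspm_io.FormatError(f"sample {sid}: non-positive duration")
        vols = {
            ch: cals[ch].sampled_volume_m3(t) * 1e6 for ch in ("s", "l")
        }  # mL
        ev_t, dist = process_sample(
            ev, boundaries, ChannelRegion(), table, bc_cal, grid, vols, log, sid
        )
        typed[sid] = ev_t
        dists[sid] = dist
        row = {"sample_id": sid}
        n_int = integrate(dist, grid.edges[0], grid.edges[-1], "number")
        v_int = integrate(dist, grid.edges[0], grid.edges[-1], "volume")
        for t_enum in n_int:
            row[f"N_{t_enum.name}_per_mL"] = n_int[t_enum]
            row[f"V_{t_enum.name}_um3_per_mL"] = v_int[t_enum]
        row["N_total_per_mL"] = float(sum(n_int.values()))
        row["V_total_um3_per_mL"] = float(sum(v_int.values()))
        rows.append(row)
    sample_table = pd.DataFrame(rows)

    # ---- profiles and regressions ---------------------------------------
    station_profiles: dict = {}
    regress_rows = []
    if metadata is not None:
        merged = metadata.merge(sample_table, on="sample_id", how="inner")
        for station, grp in merged.groupby("station"):
            station_profiles[station] = depth_profile(grp)
        for cov in ("chl_a_ug_L", "turbidity"):
            if cov not in merged.columns:
                continue
            for t_enum in ParticleType:
                col = f"V_{t_enum.name}_um3_per_mL"
                if col not in merged.columns:
                    continue
                try:
                    s = regress_vs_covariate(merged[cov], merged[col])
                except ValueError:
                    continue
                regress_rows.append(
                    {
                        "covariate": cov,
                        "type": t_enum.name,
                        "slope": s.slope,
                        "intercept": s.intercept,
                        "r_squared": s.r_squared,
                        "p_value": s.p_value,
                        "n": s.n,
                    }
                )
        log.append(f"profiles for {len(station_profiles)} stations")
    regressions = pd.DataFrame(regress_rows)

    result = PipelineResult(
        typed_events=typed,
        distributions=dists,
        sample_table=sample_table,
        station_profiles=station_profiles,
        regressions=regressions,
        parameters={
            "seed": seed,
            "medium_index": optics.medium_index,
            "wavelength_um": optics.wavelength_vacuum,
            "grid_bins": grid.n_bins,
            "lookup_shape": list(table.shape),
            "duty_cycle": {sid: duty[sid] for sid in duty},
            "bc_calibration": getattr(bc_cal, "provenance", None),
        },
        log=log,
    )
    if output_dir is None:
        output_dir = cfg.get("output_dir")
    if output_dir:
        _write_results(result, Path(output_dir))
    return result


def _write_results(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.sample_table.to_csv(outdir / "samples.csv", index=False)
    if len(result.regressions):
        result.regressions.to_csv(outdir / "regressions.csv", index=False)
    ddir = outdir / "distributions"
    ddir.mkdir(exist_ok=True)
    for sid, dist in result.distributions.items():
        dist.to_frame().to_csv(ddir / f"{sid}.csv", index=False)
    for station, prof in result.station_profiles.items():
        prof.to_csv(outdir / f"profile_{station}.csv", index=False)
    with open(outdir / "parameters.json", "w") as f:
        json.dump(result.parameters, f, indent=2, default=str)
    with open(outdir / "pipeline.log", "w") as f:
        f.write("\n".join(result.log) + "\n")
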