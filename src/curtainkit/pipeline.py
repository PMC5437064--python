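"""Scenario orchestration: preset -> simulate -> analyze -> report.

A scenario names a preset, a master seed and an output directory.  The
stage chain follows the preset kind: binding presets produce positions,
a peak fit and (when a reference preset is given) window enrichment;
dwell presets produce censored dwell samples and a survival fit;
diffusion and salt-series presets produce trajectories, per-molecule D
estimates and (for the series) the salt slope; behavior presets produce
deterministic fixtures and classification percentages.

Per-stage seeds are derived from the master seed with
``numpy.random.SeedSequence`` keyed by a stable stage-name hash, so any
stage can be re-run in isolation.  Reports embed the full parameter set
and are byte-identical for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binding import BindingSet, fit_peaks, window_enrichment
from .dynamics import (
    classify_behaviors,
    compute_msd,
    estimate_d,
    fit_survival,
    salt_slope,
)
from .presets import PRESETS, get_preset
from .simulate import (
    make_behavior_fixtures,
    simulate_binding_positions,
    simulate_dwell_times,
    simulate_trajectory,
    trajectories_to_frame,
)

__all__ = ["ScenarioConfig", "run_scenario", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Uses a CRC32 of the stage name as a spawn key; the result is kept
    below 2**31.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ScenarioConfig:
    preset: str
    seed: int
    outdir: str | Path | None = None
    overrides: dict = field(default_factory=dict)
    reference_preset: str | None = None
    n_molecules: int | None = None
    n_frames: int = 1200

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.reference_preset is not None and self.reference_preset not in PRESETS:
            raise ValueError(f"unknown reference preset {self.reference_preset!r}")
        bad = set(self.overrides) - {
            f.name for f in dataclasses.fields(PRESETS[self.preset])
        }
        if bad:
            raise ValueError(f"unknown override keys: {sorted(bad)}")


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute the stage chain for a preset and return the report dict.

    If ``config.outdir`` is set, writes ``report.json`` plus stage CSVs
    there.  The report carries the package version, all derived stage
    seeds, and the complete preset parameter set.
    """
    preset = get_preset(config.preset, **config.overrides)
    report: dict = {
        "version": __version__,
        "preset": preset.name,
        "kind": preset.kind,
        "seed": config.seed,
        "parameters": _round_floats(dataclasses.asdict(preset)),
        "stage_seeds": {},
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def seed_for(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        report["stage_seeds"][stage] = s
        return s

    if preset.kind == "binding":
        n = config.n_molecules or preset.n_reported
        pos = simulate_binding_positions(preset, n, seed_for("positions"))
        bset = BindingSet(preset.name, pos)
        fit = fit_peaks(bset, n_components=min(2, max(1, len(preset.sites))) if preset.sites else 1)
        report["n_molecules"] = n
        report["peak_fit"] = {
            "centers_kb": list(fit.centers_kb),
            "sds_kb": list(fit.sds_kb),
            "weights": list(fit.weights),
            "ok": fit.ok,
        }
        if config.reference_preset:
            ref_preset = get_preset(config.reference_preset)
            ref = BindingSet(
                ref_preset.name,
                simulate_binding_positions(ref_preset, n, seed_for("reference")),
            )
            site = preset.sites[0].center_kb if preset.sites else 21.3
            enr = window_enrichment(bset, ref, site_kb=site)
            report["enrichment"] = {
                "fold": enr.fold,
                "target_window": enr.target_window,
                "edges_kb": list(enr.edges_kb),
                "target_freq": list(enr.target_freq),
                "reference_freq": list(enr.reference_freq),
            }
        if outdir:
            bset.to_frame().to_csv(outdir / "positions.csv", index=False)

    elif preset.kind == "dwell":
        n = config.n_molecules or preset.n_reported
        dwells = simulate_dwell_times(
            preset.dwell_half_life_s, n, preset.observation_window_s, seed_for("dwells")
        )
        fit = fit_survival(dwells, seed=seed_for("bootstrap"))
        report["n_molecules"] = n
        report["survival_fit"] = {
            "t_half_s": fit.t_half_s,
            "ci_95_s": [fit.ci_low_s, fit.ci_high_s],
            "n_events": fit.n_events,
            "n_censored": fit.n_censored,
        }
        if outdir:
            import pandas as pd

            pd.DataFrame(
                {"dwell_s": dwells.times_s, "censored": dwells.censored}
            ).to_csv(outdir / "dwells.csv", index=False)

    elif preset.kind in ("diffusion", "salt_series"):
        n = config.n_molecules or preset.n_reported
        concs = preset.salt_series_mM or (preset.salt_c0_mM,)
        series = {}
        trajs = []
        for c in concs:
            rng = np.random.default_rng(seed_for(f"trajectories_{c:g}"))
            ds = []
            for i in range(n):
                traj = simulate_trajectory(
                    preset,
                    preset.d_at(c),
                    config.n_frames,
                    preset.geometry.tether_um / 2,
                    rng,
                    particle_id=i,
                )
                trajs.append(traj)
                ds.append(estimate_d(compute_msd(traj, 10), particle_id=i).d_um2_s)
            series[c] = np.asarray(ds)
        report["n_molecules"] = n
        report["d_mean_um2_s"] = {
            f"{c:g}": [float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))]
            for c, v in series.items()
        }
        if len(concs) >= 2:
            slope, se = salt_slope(series)
            report["salt_slope_um2_s_mM"] = [slope, se]
        if outdir:
            trajectories_to_frame(trajs).to_csv(outdir / "trajectories.csv", index=False)

    elif preset.kind == "behavior":
        fixtures = make_behavior_fixtures(preset)
        stats = classify_behaviors(
            [t for t, _ in fixtures], preset.interaction_site_kb
        )
        report["behavior"] = stats
        pct = [v for k, v in stats.items() if k.startswith("pct_")]
        report["behavior"]["pct_total"] = float(sum(pct))
    else:
        raise ValueError(f"preset kind {preset.kind!r} has no stage chain")

    report = _round_floats(report)
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
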