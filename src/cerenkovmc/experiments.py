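"""End-to-end experiment runner: velocity-change sweeps from a config.

One *run* simulates ``n_events`` photoelectric gamma interactions at a
single velocity-change limit (delta_beta): interaction depth sampling,
recoil-electron generation, stepwise transport, Cerenkov emission, optical
ray tracing, and the run-level analysis.  A *sweep* repeats the run over a
list of delta_beta values with independent sub-seeds derived from the
master seed, and writes per-run CSV/JSON outputs plus a sweep table.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    RunSummary,
    backward_fraction,
    cerenkov_count_stats,
    detection_histograms,
    order_resolved_angles,
    track_stats,
)
from .cerenkov import CerenkovSampler, assign_orders, emit_for_track, emit_scintillation
from .materials import Material, make_bgo, make_tlbr
from .optics import CrystalGeometry, trace
from .stopping import build_loss_tables
from .transport import make_photoelectron, propagate_electron, sample_interaction_depth

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "run_single",
    "run_experiment",
    "DEFAULT_DELTA_BETAS",
    "photoelectric_mu_per_mm",
]

#: Sweep grid: 0.01-0.05% in 0.01% increments, 0.1, 0.5, 1, 5%, 10-90% in 10%
#: increments, plus the unlimited default (None).
DEFAULT_DELTA_BETAS: list[float | None] = (
    [i * 1e-4 for i in range(1, 6)]
    + [1e-3, 5e-3, 1e-2, 5e-2]
    + [i * 0.1 for i in range(1, 10)]
    + [None]
)

# Photoelectric mass attenuation coefficients, cm^2/g.  The 511 keV BGO value
# is the published one; the others are representative literature-scale values
# (they only shape the interaction-depth distribution).
_MU_MASS_CM2_G = {
    ("BGO", 0.511): 0.056,
    ("BGO", 1.0): 0.008,
    ("TlBr", 0.511): 0.050,
}


class ConfigError(ValueError):
    """Malformed run configuration."""


def photoelectric_mu_per_mm(material: Material, gamma_energy_mev: float) -> float:
    """Linear photoelectric attenuation coefficient, 1/mm."""
    key = (material.name, round(gamma_energy_mev, 3))
    if key not in _MU_MASS_CM2_G:
        raise ConfigError(
            f"no photoelectric attenuation coefficient for {material.name} at "
            f"{gamma_energy_mev} MeV; set photoelectric_mu_per_mm in the config"
        )
    return _MU_MASS_CM2_G[key] * material.density / 10.0


@dataclass
class RunConfig:
    """Configuration of a sweep; defaults reproduce the BGO 511 keV study."""

    material: str | dict = "BGO"
    gamma_energy_mev: float = 0.511
    n_events: int = 1000
    delta_beta: list = field(default_factory=lambda: list(DEFAULT_DELTA_BETAS))
    seed: int = 12345
    output_dir: str | None = None
    scintillation: bool = False
    scintillation_decimation: float = 100.0
    yield_mode: str = "local"  # local | mean-beta | pre
    speed_mode: str = "group"  # group | phase
    optical_transport: bool = True
    source_distance_mm: float = 10.0
    photoelectric_mu_per_mm: float | None = None
    angular_orders: list = field(default_factory=lambda: [1, 5])
    backward_orders: list = field(default_factory=lambda: list(range(1, 12)))
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        for db in self.delta_beta:
            if db is not None and not (0.0 < db <= 1.0):
                raise ConfigError(f"delta_beta value {db} outside (0, 1]")
        if self.yield_mode not in ("local", "mean-beta", "pre"):
            raise ConfigError(f"unknown yield_mode {self.yield_mode!r}")
        if self.speed_mode not in ("group", "phase"):
            raise ConfigError(f"unknown speed_mode {self.speed_mode!r}")

    def build_material(self) -> Material:
        if isinstance(self.material, dict):
            return Material.from_dict(self.material)
        name = self.material.upper()
        if name == "BGO":
            return make_bgo()
        if name == "TLBR":
            return make_tlbr()
        raise ConfigError(f"unknown material {self.material!r}")

    def build_geometry(self) -> CrystalGeometry:
        known = {f.name for f in dataclasses.fields(CrystalGeometry)}
        bad = set(self.geometry) - known
        if bad:
            raise ConfigError(f"unknown geometry keys: {sorted(bad)}")
        return CrystalGeometry(**self.geometry)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_beta"] = ["unlimited" if v is None else v for v in self.delta_beta]
        return d


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "delta_beta" in raw:
        raw["delta_beta"] = [
            None if (isinstance(v, str) and v.lower() in ("unlimited", "none", "default")) else float(v)
            for v in raw["delta_beta"]
        ]
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class RawRunData:
    """Raw per-run records, kept for CSV export and custom analysis."""

    tracks: list
    events_photons: list  # per event: ordered OpticalPhoton list
    detected: list
    loss_counts: dict
    n_emitted: int


def run_single(
    material: Material,
    delta_beta: float | None,
    n_events: int,
    seed: int,
    gamma_energy_mev: float = 0.511,
    geometry: CrystalGeometry | None = None,
    yield_mode: str = "local",
    speed_mode: str = "group",
    optical_transport: bool = True,
    scintillation: bool = False,
    scintillation_decimation: float = 100.0,
    source_distance_mm: float = 10.0,
    mu_per_mm: float | None = None,
    tables=None,
    sampler: CerenkovSampler | None = None,
    angular_orders=(1, 5),
    backward_orders=tuple(range(1, 12)),
    keep_tracks: bool = False,
) -> tuple[RunSummary, RawRunData]:
    """Simulate one delta_beta point and summarise it."""
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = CrystalGeometry()
    if tables is None:
        tables = build_loss_tables(material)
    if sampler is None:
        sampler = CerenkovSampler(material.dispersion)
    if mu_per_mm is None:
        mu_per_mm = photoelectric_mu_per_mm(material, gamma_energy_mev)

    step_lengths: list[np.ndarray] = []
    first_steps: list[float] = []
    counts = np.empty(n_events)
    events_photons: list[list] = []
    detected: list = []
    loss_counts = {"absorbed": 0, "wrap": 0, "trapped": 0, "escaped": 0}
    n_emitted = 0
    tracks_kept: list = []

    for ev in range(n_events):
        depth = sample_interaction_depth(mu_per_mm, rng, max_depth=geometry.length)
        electron = make_photoelectron(
            gamma_energy_mev,
            material,
            rng,
            depth=depth,
            source_distance=source_distance_mm,
            event_id=ev,
        )
        track = propagate_electron(electron, delta_beta, tables, material, rng, event_id=ev)
        step_lengths.append(track.length)
        first_steps.append(float(track.length[0]))
        photons = emit_for_track(track, sampler, rng, mode=yield_mode)
        counts[ev] = len(photons)
        n_emitted += len(photons)
        if scintillation:
            for step in track.steps:
                photons.extend(
                    emit_scintillation(
                        step, rng, material.dispersion, decimation=scintillation_decimation
                    )
                )
        assign_orders(photons)
        events_photons.append(photons)
        if keep_tracks:
            tracks_kept.append(track)
        if optical_transport:
            for p in photons:
                if not geometry.contains(p.origin):
                    # emitted past the crystal boundary by an escaping electron
                    loss_counts["escaped"] += 1
                    continue
                result = trace(p, geometry, material.dispersion, rng, speed_mode=speed_mode)
                if result.status == "detected":
                    detected.append(result.detected)
                else:
                    loss_counts[result.status] += 1

    stats = track_stats(step_lengths)
    if n_events >= 50:
        fit_mean, fit_sigma = cerenkov_count_stats(counts)
    else:
        # too few events for a stable Gaussian fit: fall back to sample moments
        fit_mean, fit_sigma = float(counts.mean()), float(counts.std())

    angular = {}
    backward = {}
    for order in angular_orders:
        try:
            angular[order] = order_resolved_angles(events_photons, order)
        except ValueError:
            pass
    for order in backward_orders:
        try:
            backward[order] = backward_fraction(events_photons, order)
        except ValueError:
            pass

    summary = RunSummary(
        delta_beta=delta_beta,
        n_events=n_events,
        seed=seed,
        mean_step_length_um=stats.mean_step_length_um,
        mean_track_length_um=stats.mean_track_length_um,
        mean_steps_per_track=stats.mean_steps_per_track,
        cerenkov_fit_mean=fit_mean,
        cerenkov_fit_sigma=fit_sigma,
        cerenkov_sample_mean=float(counts.mean()),
        first_step_length_mm=float(np.mean(first_steps)),
        angular_histograms=angular,
        backward_fractions=backward,
        n_emitted=n_emitted,
        loss_counts=loss_counts,
    )
    cer_detected = [d for d in detected if d.kind == "cerenkov"]
    if cer_detected:
        hists = detection_histograms(cer_detected)
        summary.n_detected = len(cer_detected)
        summary.mean_path_mm = hists.mean_path_mm
        summary.mean_detection_time_ns = hists.mean_detection_time_ns
        summary.mean_transit_ns = hists.mean_transit_ns

    raw = RawRunData(
        tracks=tracks_kept,
        events_photons=events_photons,
        detected=detected,
        loss_counts=loss_counts,
        n_emitted=n_emitted,
    )
    return summary, raw


def _delta_beta_label(db: float | None) -> str:
    return "unlimited" if db is None else f"{db:g}"


def write_outputs(summary: RunSummary, raw: RawRunData, out_dir: Path) -> None:
    """Per-run JSON summary plus photon/detected CSV lists."""
    out_dir.mkdir(parents=True, exist_ok=True)
    label = _delta_beta_label(summary.delta_beta)
    summary.to_json(out_dir / f"summary_db_{label}.json")

    rows = []
    for ev, photons in enumerate(raw.events_photons):
        for p in photons:
            rows.append(
                {
                    "event": ev,
                    "order": p.order,
                    "kind": p.kind,
                    "x_mm": p.origin[0],
                    "y_mm": p.origin[1],
                    "z_mm": p.origin[2],
                    "time_ns": p.emission_time,
                    "energy_ev": p.energy_ev,
                    "dx": p.direction[0],
                    "dy": p.direction[1],
                    "dz": p.direction[2],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / f"photons_db_{label}.csv", index=False)

    det_rows = [
        {
            "kind": d.kind,
            "order": d.order,
            "detection_time_ns": d.detection_time,
            "transit_ns": d.transit_time,
            "path_mm": d.path_length,
            "n_reflections": d.n_reflections,
        }
        for d in raw.detected
    ]
    pd.DataFrame(det_rows).to_csv(out_dir / f"detected_db_{label}.csv", index=False)

    if raw.tracks:
        trows = []
        for t in raw.tracks:
            for i in range(t.n_steps):
                trows.append(
                    {
                        "event": t.parent_event_id,
                        "step": i,
                        "pre_ke_mev": t.pre_ke[i],
                        "length_mm": t.length[i],
                        "x_mm": t.pre_position[i][0],
                        "y_mm": t.pre_position[i][1],
                        "z_mm": t.pre_position[i][2],
                        "dx": t.pre_direction[i][0],
                        "dy": t.pre_direction[i][1],
                        "dz": t.pre_direction[i][2],
                    }
                )
        pd.DataFrame(trows).to_csv(out_dir / f"tracks_db_{label}.csv", index=False)


def run_experiment(config: RunConfig) -> list[RunSummary]:
    """Run the configured sweep; deterministic given the master seed."""
    material = config.build_material()
    geometry = config.build_geometry()
    tables = build_loss_tables(material)
    sampler = CerenkovSampler(material.dispersion)
    mu = config.photoelectric_mu_per_mm
    if mu is None:
        mu = photoelectric_mu_per_mm(material, config.gamma_energy_mev)

    master = np.random.SeedSequence(config.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(len(config.delta_beta))]

    out_dir = Path(config.output_dir) if config.output_dir else None
    summaries = []
    sweep_rows = []
    for db, sub in zip(config.delta_beta, sub_seeds):
        summary, raw = run_single(
            material,
            db,
            config.n_events,
            sub,
            gamma_energy_mev=config.gamma_energy_mev,
            geometry=geometry,
            yield_mode=config.yield_mode,
            speed_mode=config.speed_mode,
            optical_transport=config.optical_transport,
            scintillation=config.scintillation,
            scintillation_decimation=config.scintillation_decimation,
            source_distance_mm=config.source_distance_mm,
            mu_per_mm=mu,
            tables=tables,
            sampler=sampler,
            angular_orders=tuple(config.angular_orders),
            backward_orders=tuple(config.backward_orders),
            keep_tracks=out_dir is not None,
        )
        summaries.append(summary)
        sweep_rows.append(
            {
                "delta_beta": _delta_beta_label(db),
                "mean_step_length_um": summary.mean_step_length_um,
                "mean_track_length_um": summary.mean_track_length_um,
                "mean_steps_per_track": summary.mean_steps_per_track,
                "cerenkov_fit_mean": summary.cerenkov_fit_mean,
                "mean_transit_ns": summary.mean_transit_ns,
            }
        )
        if out_dir is not None:
            write_outputs(summary, raw, out_dir)

    if out_dir is not None:
        pd.DataFrame(sweep_rows).to_csv(out_dir / "sweep.csv", index=False)
        log = {
            "package_version": __version__,
            "python": platform.python_version(),
            "config": config.to_dict(),
            "sub_seeds": sub_seeds,
        }
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1)
    return summaries
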