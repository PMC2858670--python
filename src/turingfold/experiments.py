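"""Seeded initial conditions, ensemble runs, and the (F, k) phase diagram.

The stated initial condition is the homogeneous equilibrium (u, v) = (1, 0)
on a sphere, perturbed along a broad geodesic band (a "line" around a great
circle) where (u, v) = (0.5, 0.25) plus seeded white noise — the analogue of
a sulcal root seeding the first fold. Ensembles rerun the coupled simulation
from independently-noised copies of this condition and aggregate the final
binary fold maps into the reproducibility map S; the phase diagram sweeps
(F, k) over a small grid and classifies each run's pattern regime.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .mesh_core import TriangleMesh, make_icosphere, resample_field
from .dynamics import GrayScottParams, MorphogenState
from .deformation import DeformationParams, run_simulation
from .analysis import threshold_map, classify_regime, RegimeResult, main_fold_segment_count

__all__ = [
    "ExperimentConfig",
    "EnsembleResult",
    "initial_condition_line",
    "band_mask",
    "run_single",
    "run_ensemble",
    "phase_diagram",
]

logger = logging.getLogger("turingfold")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run, an ensemble, or a sweep.

    The seed fully determines a run; ensemble realization i uses seed + i.
    Scaled-down defaults (subdivisions=3, horizon 1500, ensemble 10) keep a
    full study on one CPU in minutes; the full-scale study uses horizon 4000
    and ensemble_size 50.
    """

    subdivisions: int = 3
    radius: float = 1.0
    F: float = 0.04
    k: float = 0.06
    Du: float = 2e-3
    Dv: float = 2e-3 / 6
    dt: float = 1.0
    lumped_mass: bool = False
    alpha: float = 0.00075
    driver: str = "u"
    refinement_threshold: float = 2.0
    snapshot_every: int = 100
    horizon: int = 1500
    band_half_width: float = 0.15
    noise_amplitude: float = 0.05
    seed: int = 0
    ensemble_size: int = 10
    smoothing_iterations: int = 100
    F_grid: list = field(default_factory=lambda: [0.02, 0.03, 0.04, 0.05])
    k_grid: list = field(
        default_factory=lambda: [0.035, 0.04, 0.045, 0.05, 0.055, 0.06, 0.065]
    )

    def gray_scott(self, F: float | None = None, k: float | None = None) -> GrayScottParams:
        return GrayScottParams(
            F=self.F if F is None else F,
            k=self.k if k is None else k,
            Du=self.Du,
            Dv=self.Dv,
            dt=self.dt,
            lumped_mass=self.lumped_mass,
        )

    def deformation(self) -> DeformationParams:
        return DeformationParams(
            alpha=self.alpha,
            driver=self.driver,
            refinement_threshold=self.refinement_threshold,
            snapshot_every=self.snapshot_every,
        )

    def mesh(self) -> TriangleMesh:
        return make_icosphere(self.subdivisions, self.radius)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class EnsembleResult:
    reference_mesh: TriangleMesh
    bmaps: list              # per-realization final binary fold maps on the reference
    S: np.ndarray            # reproducibility map, percent
    fold_counts: list        # final fold count per realization
    segment_counts: list     # main-fold segment count per realization
    average_surface: TriangleMesh
    failures: int = 0


def band_mask(mesh: TriangleMesh, half_width: float = 0.15) -> np.ndarray:
    """Vertices within angular half-width of the z = 0 great circle."""
    v = mesh.vertices
    r = np.linalg.norm(v, axis=1)
    lat = np.arcsin(np.clip(v[:, 2] / r, -1.0, 1.0))
    return np.abs(lat) < half_width


def initial_condition_line(
    mesh: TriangleMesh,
    noise_amplitude: float = 0.05,
    seed: int = 0,
    band_half_width: float = 0.15,
) -> MorphogenState:
    """Broad-line perturbation of the homogeneous equilibrium on a sphere.

    (u, v) = (1, 0) everywhere except within ``band_half_width`` radians of
    the z = 0 great circle, where (u, v) = (0.5, 0.25) plus independent
    uniform white noise in [-amplitude, amplitude] on each field. Seeded and
    reproducible.
    """
    n = mesh.n_vertices
    u = np.ones(n)
    v = np.zeros(n)
    mask = band_mask(mesh, band_half_width)
    u[mask] = 0.5
    v[mask] = 0.25
    if noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        nb = int(mask.sum())
        u[mask] += rng.uniform(-noise_amplitude, noise_amplitude, nb)
        v[mask] += rng.uniform(-noise_amplitude, noise_amplitude, nb)
    return MorphogenState(u=u, v=v, time=0.0)


def run_single(config: ExperimentConfig, seed: int | None = None,
               F: float | None = None, k: float | None = None):
    """One seeded coupled run from the line initial condition."""
    mesh = config.mesh()
    state = initial_condition_line(
        mesh,
        noise_amplitude=config.noise_amplitude,
        seed=config.seed if seed is None else seed,
        band_half_width=config.band_half_width,
    )
    t0 = _time.perf_counter()
    trace = run_simulation(mesh, state, config.gray_scott(F, k), config.deformation(), config.horizon)
    logger.info(
        "run seed=%s F=%s k=%s horizon=%d final_vertices=%d wall=%.1fs",
        seed if seed is not None else config.seed,
        config.F if F is None else F,
        config.k if k is None else k,
        config.horizon,
        trace.final.mesh.n_vertices,
        _time.perf_counter() - t0,
    )
    return trace


def run_ensemble(config: ExperimentConfig) -> EnsembleResult:
    """Run ``ensemble_size`` realizations with seeds seed+0 .. seed+n-1.

    Final binary fold maps are resampled to the reference sphere and summed
    into the percentage map S; the average surface is reconstructed from the
    mean resampled radial-displacement field. Individual failures are logged
    and excluded; at least two successes are required.
    """
    if config.ensemble_size < 2:
        raise ValueError("ensemble_size must be >= 2")
    reference = config.mesh()
    mask = band_mask(reference, config.band_half_width)
    bmaps, radii, fold_counts, seg_counts = [], [], [], []
    failures = 0
    from .analysis import segment_folds  # local to avoid import cycle at module load

    for i in range(config.ensemble_size):
        seed = config.seed + i
        try:
            trace = run_single(config, seed=seed)
            snap = trace.final
            b = threshold_map(snap.curvature)
            b_ref = (
                resample_field(snap.mesh, b.astype(float), reference, config.smoothing_iterations)
                > 0.5
            ).astype(np.int8)
            centred = snap.mesh.vertices - snap.mesh.vertices.mean(axis=0)
            r = np.linalg.norm(centred, axis=1)
            r_ref = resample_field(snap.mesh, r, reference, config.smoothing_iterations)
            bmaps.append(b_ref)
            radii.append(r_ref)
            fold_counts.append(segment_folds(b, snap.mesh).n_folds)
            seg_counts.append(main_fold_segment_count(b_ref, reference, mask))
            logger.info("realization %d: %d folds, %d main-fold segments",
                        i, fold_counts[-1], seg_counts[-1])
        except Exception as exc:  # per-realization robustness
            failures += 1
            logger.warning("realization %d (seed %d) failed: %s", i, seed, exc)
    if len(bmaps) < 2:
        raise RuntimeError("fewer than 2 ensemble realizations succeeded")

    S = 100.0 * np.mean(bmaps, axis=0)
    mean_r = np.mean(radii, axis=0)
    dirs = reference.vertices / np.linalg.norm(reference.vertices, axis=1)[:, None]
    average_surface = TriangleMesh(dirs * mean_r[:, None], reference.faces.copy())
    return EnsembleResult(
        reference_mesh=reference,
        bmaps=bmaps,
        S=S,
        fold_counts=fold_counts,
        segment_counts=seg_counts,
        average_surface=average_surface,
        failures=failures,
    )


def phase_diagram(config: ExperimentConfig) -> dict[tuple[float, float], RegimeResult | str]:
    """Classify the pattern regime over the (F, k) grid at a fixed seed.

    The default 4 x 7 grid yields 28 couples and contains the three
    documented regime anchors: (0.04, 0.06) stripes/normal, (0.03, 0.06)
    spots/polymicrogyria, (0.05, 0.05) homogeneous/lissencephaly.
    """
    if not config.F_grid or not config.k_grid:
        raise ValueError("empty phase-diagram grid")
    out: dict[tuple[float, float], RegimeResult | str] = {}
    for F in config.F_grid:
        for k in config.k_grid:
            try:
                trace = run_single(config, F=F, k=k)
                out[(F, k)] = classify_regime(trace)
                logger.info("(F=%g, k=%g) -> %s", F, k, out[(F, k)].label)
            except Exception as exc:
                out[(F, k)] = "failed"
                logger.warning("(F=%g, k=%g) failed: %s", F, k, exc)
    return out
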