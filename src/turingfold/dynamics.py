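"""Gray-Scott kinetics and the semi-implicit step on a (possibly growing) surface.

The two morphogens are u, a substrate fed at rate F, and v, the autocatalyst
produced by the cubic reaction u v² and removed at rate F + k:

    du/dt = Du Δu - u v² + F (1 - u) - d u
    dv/dt = Dv Δv + u v² - (F + k) v - d v

where Δ is the Laplace-Beltrami operator of the current surface and d is the
dilution rate (1/√g) ∂√g/∂t accounting for concentration thinning as local
area grows; on a static surface d ≡ 0 and the classical Gray-Scott system is
recovered. Vertices are material points (a Lagrangian frame), so no separate
convective term appears.

Time stepping is IMEX: diffusion, the linear decay rates and the lagged
nonlinear coefficient v² are implicit, the remaining sources explicit. Both
per-step system matrices are symmetric positive definite for any admissible
state, so each step amounts to two conjugate-gradient solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_core import GeometryCache
from .fem import FEMSystem, solve_spd

__all__ = [
    "GrayScottParams",
    "MorphogenState",
    "reaction_terms",
    "homogeneous_equilibria",
    "dilution_field",
    "step_fields",
]


@dataclass(frozen=True)
class GrayScottParams:
    """Kinetic and numerical parameters.

    F : feed rate of the substrate u (1/time).
    k : kill rate of the autocatalyst v, on top of F (1/time).
    Du, Dv : diffusion coefficients (length²/time). Defaults set the Turing
        wavelength to a few tenths of the unit-sphere radius so a dozen-odd
        folds fit on the sphere and remain resolvable on the default meshes;
        the substrate-dominant ratio Du/Dv = 6 keeps the spot regime (low F)
        alive at that resolution.
    dt : time step (time).
    lumped_mass : use the lumped (diagonal) mass matrix throughout the step
        instead of the consistent one.
    solver_tol : relative residual for the per-step SPD solves.
    """

    F: float = 0.04
    k: float = 0.06
    Du: float = 2e-3
    Dv: float = 2e-3 / 6
    dt: float = 1.0
    lumped_mass: bool = False
    solver_tol: float = 1e-10

    def __post_init__(self) -> None:
        if min(self.Du, self.Dv, self.dt) <= 0:
            raise ValueError("Du, Dv and dt must be positive")
        if min(self.F, self.k) < 0:
            raise ValueError("F and k must be non-negative")


@dataclass
class MorphogenState:
    """Per-vertex morphogen fields plus simulation time.

    ``dilution`` is the per-vertex dilution rate produced by the previous
    deformation step (zero on the first step and on a static surface); it is
    carried on the state so refinement can interpolate it alongside u and v.
    """

    u: np.ndarray
    v: np.ndarray
    time: float = 0.0
    dilution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same length")


def reaction_terms(u, v, params: GrayScottParams):
    """Pointwise Gray-Scott kinetics: (-u v² + F (1 - u), u v² - (F + k) v)."""
    uv2 = u * v * v
    return (-uv2 + params.F * (1.0 - u), uv2 - (params.F + params.k) * v)


def homogeneous_equilibria(params: GrayScottParams) -> list[tuple[float, float]]:
    """Spatially uniform steady states.

    The trivial state (1, 0) always exists. Setting the v-equation to zero
    with v ≠ 0 gives u v = F + k; substituting into the u-equation yields the
    quadratic (F + k) v² - F v + F (F + k) = 0, which has real roots iff
    F ≥ 4 (F + k)² (a degenerate double root at equality).
    """
    F, k = params.F, params.k
    out = [(1.0, 0.0)]
    disc = F * F - 4.0 * F * (F + k) ** 2
    if F > 0 and disc >= -1e-12 * F * F:  # tolerate roundoff at the double root
        sq = np.sqrt(max(disc, 0.0))
        roots = {(F - sq) / (2.0 * (F + k)), (F + sq) / (2.0 * (F + k))}
        for v in sorted(roots):
            if v > 0:
                out.append(((F + k) / v, v))
    return out


def dilution_field(
    geom_prev: GeometryCache,
    geom_curr: GeometryCache,
    dt: float,
    faces: np.ndarray,
) -> np.ndarray:
    """Per-vertex dilution rate (1/√g) ∂√g/∂t from two geometry snapshots.

    Uses the backward difference d_T = (√g_T(t) - √g_T(t-dt)) / (dt √g_T(t))
    per face (the forward geometry is unknowable before the step) and
    averages incident-face rates at each vertex, weighted by current face
    area. Both caches must refer to the same connectivity.
    """
    if geom_prev.sqrt_g.shape != geom_curr.sqrt_g.shape:
        raise ValueError("geometry caches have mismatched connectivity")
    d_face = (geom_curr.sqrt_g - geom_prev.sqrt_g) / (dt * geom_curr.sqrt_g)
    n = geom_curr.vertex_areas.shape[0]
    num = np.zeros(n)
    den = np.zeros(n)
    w = geom_curr.face_areas
    for i in range(3):
        np.add.at(num, faces[:, i], w * d_face)
        np.add.at(den, faces[:, i], w)
    return num / den


def step_fields(
    state: MorphogenState,
    params: GrayScottParams,
    fem: FEMSystem,
    dilution: np.ndarray | None = None,
) -> MorphogenState:
    """One IMEX step of the reaction-diffusion system on the current mesh.

    With M the mass matrix, K the stiffness matrix, L the lumped mass and d
    the dilution field, the update solves

        (M + dt Du K + dt L diag[(vⁿ)² + F + d]) uⁿ⁺¹ = M uⁿ + dt F M 1
        (M + dt Dv K + dt L diag[F + k + d])     vⁿ⁺¹ = M vⁿ + dt M (uⁿ (vⁿ)²)

    Both matrices are SPD whenever d > -(F + k)/dt, which only fails under
    pathological shrinkage; that case raises.
    """
    n = fem.vertex_count
    if state.u.shape[0] != n:
        raise ValueError("state size does not match FEM system")
    if not (np.isfinite(state.u).all() and np.isfinite(state.v).all()):
        raise ValueError("non-finite morphogen field")
    d = np.zeros(n) if dilution is None else np.asarray(dilution, dtype=float)
    F, k, dt = params.F, params.k, params.dt
    if (F + k + d).min() < 0.0:
        raise ValueError("dilution below -(F + k): system matrix loses positivity")

    M = sp.diags(fem.mass_lumped) if params.lumped_mass else fem.mass
    L = fem.mass_lumped
    K = fem.stiffness
    u, v = state.u, state.v
    v2 = v * v

    A_u = (M + dt * params.Du * K + sp.diags(dt * L * (v2 + F + d))).tocsr()
    b_u = M @ u + dt * F * (M @ np.ones(n))
    u_new = solve_spd(A_u, b_u, tol=params.solver_tol, x0=u)

    A_v = (M + dt * params.Dv * K + sp.diags(dt * L * (F + k + d))).tocsr()
    b_v = M @ v + dt * (M @ (u * v2))
    v_new = solve_spd(A_v, b_v, tol=params.solver_tol, x0=v)

    if not (np.isfinite(u_new).all() and np.isfinite(v_new).all()):
        raise ValueError("non-finite morphogen field after step")
    lo = min(u_new.min(), v_new.min())
    hi = max(u_new.max(), v_new.max())
    if lo < -1e-6 or hi > 1.0 + 1e-6:
        # static message so repeated occurrences deduplicate
        warnings.warn("morphogen fields left [0, 1]", RuntimeWarning, stacklevel=2)
    return MorphogenState(u=u_new, v=v_new, time=state.time + dt, dilution=state.dilution)
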