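"""Absolute-conductivity reconstruction by regularized Gauss–Newton.

The solver minimizes the boundary-voltage misfit ∅ = ‖V_o − f(σ)‖ where
f(σ) is the FEM forward map, stabilized by a Tikhonov penalty λ‖Γσ‖² with
Γ an anatomically weighted graph Laplacian on element adjacency: neighbour
elements in the same labelled region are coupled with weight 1, neighbours
across a region boundary with a reduced weight, so the prior smooths within
organs but lets conductivity jump at organ boundaries.

Each iteration linearizes f at σₙ via the adjoint-method Jacobian J
(∂V/∂σ per element) and applies the regularized normal-equations update

    σₙ₊₁ = σₙ + (JᵀJ + λΓᵀΓ)⁻¹ Jᵀ (V_o − f(σₙ)),

followed by a positivity floor and a backtracking line search so the
misfit never increases on an accepted step.  Iteration stops when the
relative change ‖σₙ − σₙ₋₁‖/‖σₙ₋₁‖ drops below ``tol``.

λ defaults to the scale-invariant heuristic λ = α·tr(JᵀJ)/tr(ΓᵀΓ)
evaluated at the starting point and held fixed; Γ is geometry-only and
built once.  J is rebuilt every iteration.  The penalty is applied to σ
itself (not to σ − σ₀).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize_scalar

from .errors import ConditioningError, ParameterError
from .forward import (
    DEFAULT_CONTACT_IMPEDANCE,
    ConductivityField,
    ElectrodeModel,
    FEMSystem,
    MeasurementSet,
    StimulationPattern,
    assemble_system,
    solve_forward,
)
from .mesh import TriMesh, region_mask

#: default weight multiplier α in λ = α·tr(JᵀJ)/tr(ΓᵀΓ); α = 1 puts the
#: penalty and data terms into the normal equations at comparable scale
DEFAULT_ALPHA = 1.0
#: default relative weight of element adjacencies that cross a region boundary
DEFAULT_CROSS_WEIGHT = 0.1
#: positivity projection: floor at this fraction of the starting conductivity
POSITIVITY_FLOOR_FRACTION = 0.05


@dataclass
class GammaWeights:
    within: float = 1.0
    cross: float = DEFAULT_CROSS_WEIGHT

    def __post_init__(self):
        if self.within <= 0:
            raise ParameterError("within-region weight must be positive")
        if not 0.0 <= self.cross <= self.within:
            raise ParameterError("cross-region weight must be in [0, within]")


@dataclass
class Regularization:
    """λ and the Γ edge-weight rule.  lam=None selects the α-heuristic."""

    lam: float | None = None
    alpha: float = DEFAULT_ALPHA
    gamma_weights: GammaWeights = field(default_factory=GammaWeights)

    def __post_init__(self):
        if self.lam is not None and self.lam < 0:
            raise ParameterError("lambda must be >= 0")
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")


@dataclass
class SensitivityMatrix:
    """entries[k, e] = ∂(measurement k)/∂(σ on element e)."""

    entries: np.ndarray
    linearization_point: ConductivityField


@dataclass
class ReconstructionResult:
    sigma: ConductivityField
    objective_trace: list[float]
    iterations: int
    converged: bool
    lam_used: float
    sigma0: float
    residual: np.ndarray


# ---------------------------------------------------------------------------
# Jacobian (adjoint method)


def jacobian(
    mesh: TriMesh,
    sigma: ConductivityField,
    pattern: StimulationPattern,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
    system: FEMSystem | None = None,
) -> SensitivityMatrix:
    """Adjoint sensitivities of every measurement w.r.t. per-element σ.

    With a symmetric grounded system A(σ), drive solution u_d and adjoint
    solution z_m for the measurement source, each entry is
    J(k, e) = −z_mᵀ (∂A/∂σ_e) u_d = −z_m[tri_e]ᵀ S_e u_d[tri_e] with S_e the
    unit-σ local stiffness; one LU factorization serves all right-hand sides.
    """
    sys_ = system if system is not None else assemble_system(
        mesh, sigma, electrode_model, contact_impedance
    )
    L = mesh.n_electrodes
    # distinct drive and measurement electrode pairs
    drives = [f.drive for f in pattern.frames]
    pair_ids: dict[tuple[int, int], int] = {}
    for f in pattern.frames:
        for pr in f.measurement_pairs:
            pair_ids.setdefault(pr, len(pair_ids))

    U = np.empty((sys_.dim, len(drives)))
    for j, (a, b) in enumerate(drives):
        cur = np.zeros(L)
        cur[a] = pattern.frames[j].current_ma * 1e-3
        cur[b] = -pattern.frames[j].current_ma * 1e-3
        U[:, j] = sys_.solve(sys_.electrode_rhs(cur))
    Z = np.empty((sys_.dim, len(pair_ids)))
    for pr, j in pair_ids.items():
        Z[:, j] = sys_.solve(sys_.measurement_rhs(pr))

    tri = mesh.elements  # (E,3)
    S = sys_.local_stiffness  # (E,3,3)
    Utri = U[: mesh.n_nodes][tri]  # (E,3,D)
    Ztri = Z[: mesh.n_nodes][tri]  # (E,3,P)
    T = np.einsum("eij,ejd->eid", S, Utri)  # (E,3,D)
    M = np.einsum("eip,eid->epd", Ztri, T)  # (E,P,D)

    rows = []
    for d, f in enumerate(pattern.frames):
        for pr in f.measurement_pairs:
            rows.append(-M[:, pair_ids[pr], d])
    J = np.array(rows)
    if not np.all(np.isfinite(J)):
        raise ConditioningError("non-finite Jacobian entries")
    return SensitivityMatrix(J, sigma)


# ---------------------------------------------------------------------------
# weighted Laplacian prior


def build_gamma(mesh: TriMesh, weights: GammaWeights = GammaWeights()) -> sp.csr_matrix:
    """Region-weighted graph Laplacian on shared-edge element adjacency.

    Rows sum to zero; adjacencies crossing a region boundary carry
    ``weights.cross`` instead of ``weights.within``.
    """
    tri = mesh.elements
    edge_owner: dict[tuple[int, int], int] = {}
    pairs = []
    for e in range(len(tri)):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[e, a], tri[e, b]), max(tri[e, a], tri[e, b]))
            other = edge_owner.pop(key, None)
            if other is None:
                edge_owner[key] = e
            else:
                pairs.append((other, e))
    lab = mesh.element_region
    r, c, v = [], [], []
    for a, b in pairs:
        w = weights.within if lab[a] == lab[b] else weights.cross
        if w == 0.0:
            continue
        r += [a, b, a, b]
        c += [a, b, b, a]
        v += [w, w, -w, -w]
    E = mesh.n_elements
    return sp.coo_matrix((v, (r, c)), shape=(E, E)).tocsr()


# ---------------------------------------------------------------------------
# Gauss-Newton machinery


def _misfit(
    mesh: TriMesh,
    sigma: ConductivityField,
    data: MeasurementSet,
    electrode_model: ElectrodeModel,
    contact_impedance: float,
) -> tuple[float, np.ndarray]:
    pred = solve_forward(
        mesh, sigma, data.pattern, electrode_model, contact_impedance
    ).as_vector()
    res = data.as_vector() - pred
    return float(np.linalg.norm(res)), res


def fit_homogeneous(
    mesh: TriMesh,
    data: MeasurementSet,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
    bounds: tuple[float, float] = (1e-3, 10.0),
) -> float:
    """Best-fitting homogeneous conductivity (1-D fit of the misfit norm).

    Used as the default σ₀; fixes the absolute scale of the reconstruction.
    """

    def cost(logs: float) -> float:
        s = float(np.exp(logs))
        return _misfit(
            mesh, ConductivityField.homogeneous(mesh, s), data, electrode_model, contact_impedance
        )[0]

    res = minimize_scalar(
        cost, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def resolve_lambda(reg: Regularization, J: np.ndarray, gamma: sp.csr_matrix) -> float:
    if reg.lam is not None:
        return float(reg.lam)
    trJ = float(np.einsum("ke,ke->", J, J))
    trG = float((gamma.multiply(gamma)).sum())
    if trG == 0.0:
        raise ConditioningError("Gamma is zero; cannot use the alpha heuristic")
    return reg.alpha * trJ / trG


def gn_step(
    mesh: TriMesh,
    sigma_prev: ConductivityField,
    data: MeasurementSet,
    J: SensitivityMatrix,
    reg: Regularization,
    gamma: sp.csr_matrix | None = None,
    lam: float | None = None,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
    line_search: bool = True,
    floor: float | None = None,
) -> tuple[ConductivityField, float, bool]:
    """One regularized Gauss–Newton update with positivity floor and damping.

    Returns (new field, misfit at the new field, step_accepted).  With
    ``line_search`` the step length is halved until the misfit does not
    increase; if no length succeeds the previous field is returned with
    ``step_accepted=False``.
    """
    if gamma is None:
        gamma = build_gamma(mesh, reg.gamma_weights)
    Jm = J.entries
    if lam is None:
        lam = resolve_lambda(reg, Jm, gamma)
    phi0, res = _misfit(mesh, sigma_prev, data, electrode_model, contact_impedance)
    H = Jm.T @ Jm + lam * (gamma.T @ gamma).toarray()
    g = Jm.T @ res
    try:
        delta = np.linalg.solve(H, g)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "normal equations are singular; raise lambda (or alpha)"
        ) from exc
    if floor is None:
        floor = POSITIVITY_FLOOR_FRACTION * float(np.median(sigma_prev.values))
    if not line_search:
        new = np.maximum(sigma_prev.values + delta, floor)
        fld = ConductivityField(new, sigma_prev.mesh_id)
        return fld, _misfit(mesh, fld, data, electrode_model, contact_impedance)[0], True
    t = 1.0
    for _ in range(7):
        cand = np.maximum(sigma_prev.values + t * delta, floor)
        fld = ConductivityField(cand, sigma_prev.mesh_id)
        phi, _ = _misfit(mesh, fld, data, electrode_model, contact_impedance)
        if phi <= phi0 * (1.0 + 1e-12):
            return fld, phi, True
        t *= 0.5
    return sigma_prev, phi0, False


def reconstruct(
    mesh: TriMesh,
    data: MeasurementSet,
    sigma0: float | None = None,
    reg: Regularization | None = None,
    tol: float = 1e-3,
    max_iter: int = 25,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
) -> ReconstructionResult:
    """Iterated Gauss–Newton absolute reconstruction.

    ``sigma0=None`` initializes from the best homogeneous fit.  Divergence
    (two consecutive rejected damped steps) yields ``converged=False``
    rather than an exception.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    reg = reg if reg is not None else Regularization()
    if sigma0 is None:
        sigma0 = fit_homogeneous(mesh, data, electrode_model, contact_impedance)
    sigma = ConductivityField.homogeneous(mesh, sigma0)
    gamma = build_gamma(mesh, reg.gamma_weights)
    floor = POSITIVITY_FLOOR_FRACTION * sigma0

    phi, res = _misfit(mesh, sigma, data, electrode_model, contact_impedance)
    trace = [phi]
    lam: float | None = reg.lam
    converged = False
    rejected = 0
    it = 0
    while it < max_iter:
        it += 1
        J = jacobian(mesh, sigma, data.pattern, electrode_model, contact_impedance)
        if lam is None:
            lam = resolve_lambda(reg, J.entries, gamma)
        new, phi, accepted = gn_step(
            mesh, sigma, data, J, reg, gamma=gamma, lam=lam,
            electrode_model=electrode_model, contact_impedance=contact_impedance,
            floor=floor,
        )
        trace.append(phi)
        if not accepted:
            rejected += 1
            if rejected >= 2:
                break
            continue
        rejected = 0
        rel = float(
            np.linalg.norm(new.values - sigma.values) / np.linalg.norm(sigma.values)
        )
        sigma = new
        if rel < tol:
            converged = True
            break
    _, res = _misfit(mesh, sigma, data, electrode_model, contact_impedance)
    return ReconstructionResult(
        sigma=sigma,
        objective_trace=trace,
        iterations=it,
        converged=converged,
        lam_used=float(lam) if lam is not None else 0.0,
        sigma0=float(sigma0),
        residual=res,
    )


def liver_conductivity(result: ReconstructionResult, mesh: TriMesh) -> tuple[float, float]:
    """Area-weighted mean and spatial SD of reconstructed σ over the liver."""
    idx = region_mask(mesh, "liver")
    w = mesh.element_areas()[idx]
    v = result.sigma.values[idx]
    mean = float(np.average(v, weights=w))
    var = float(np.average((v - mean) ** 2, weights=w))
    return mean, float(np.sqrt(var))
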