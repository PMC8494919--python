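"""Finite-element forward model for 2-D absolute EIT.

Solves the conductivity equation ∇·(−σ∇V) = 0 on a :class:`TriMesh` with
piecewise-constant σ and linear (P1) triangular elements, under either a
point electrode model (current injected at the electrode centre node; used
for analytic validation) or the complete electrode model (finite pads,
contact impedance, shunting; the physical default for belt systems).

Units: node coordinates are cm, σ is S·m⁻¹, injected current mA, voltages V.
The P1 stiffness matrix is scale-invariant in 2-D, so σ in S/m can multiply
cm-based element matrices directly; the complete-electrode boundary terms
are the one place lengths matter, and there pad arc lengths are converted
to metres and the contact impedance is taken in Ω·cm (converted to Ω·m)
so every assembled entry is in siemens per metre of body height.  The model
is per-unit-depth: a frame injecting I mA is interpreted as I mA per metre
of belt height.

A "skip s" stimulation pattern drives electrode pairs separated by s
intervening electrodes (positions e and e+s+1) and measures on all
similarly offset pairs not touching a drive electrode — the study's belt
used 32 electrodes with skip 4.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import AssemblyError, InputError, ParameterError, PatternError
from .mesh import TriMesh

CM_PER_M = 100.0

#: default 2-D contact impedance for the complete electrode model, Ω·cm
#: (per-unit-depth; electrode gel + skin interface, order-of-magnitude value
#: standard in CEM simulation studies)
DEFAULT_CONTACT_IMPEDANCE = 50.0

ElectrodeModel = Literal["point", "complete"]


@dataclass
class ConductivityField:
    """Per-element conductivity in S/m, tied to a mesh by its id."""

    values: np.ndarray
    mesh_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ParameterError("conductivity must be strictly positive and finite")

    @classmethod
    def homogeneous(cls, mesh: TriMesh, value: float) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, float(value)), mesh.mesh_id)

    @classmethod
    def from_values(cls, mesh: TriMesh, values) -> "ConductivityField":
        v = np.asarray(values, dtype=float)
        if v.shape != (mesh.n_elements,):
            raise ParameterError("conductivity length must equal element count")
        return cls(v, mesh.mesh_id)


@dataclass(frozen=True)
class Frame:
    drive: tuple[int, int]          # (+I, −I) electrode indices
    current_ma: float
    measurement_pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class StimulationPattern:
    frames: tuple[Frame, ...]
    n_electrodes: int

    @property
    def n_measurements(self) -> int:
        return sum(len(f.measurement_pairs) for f in self.frames)


@dataclass
class MeasurementSet:
    """Boundary voltage data: the V_o the inversion fits."""

    pattern: StimulationPattern
    voltages: list[np.ndarray]      # one array per frame
    frequency_khz: float = 50.0
    noise_model: str = "none"
    seed: int | None = None

    def __post_init__(self):
        if len(self.voltages) != len(self.pattern.frames):
            raise InputError("voltage frame count does not match the pattern")
        for v, f in zip(self.voltages, self.pattern.frames):
            if len(v) != len(f.measurement_pairs):
                raise InputError("voltage count mismatch within a frame")

    def as_vector(self) -> np.ndarray:
        return np.concatenate(self.voltages)

    def with_vector(self, vec: np.ndarray, **meta) -> "MeasurementSet":
        out, i = [], 0
        for f in self.pattern.frames:
            out.append(np.asarray(vec[i : i + len(f.measurement_pairs)], dtype=float))
            i += len(f.measurement_pairs)
        kw = dict(frequency_khz=self.frequency_khz, noise_model=self.noise_model, seed=self.seed)
        kw.update(meta)
        return MeasurementSet(self.pattern, out, **kw)


def make_skip_pattern(n_electrodes: int, skip: int, current_ma: float) -> StimulationPattern:
    """Skip-s pairwise pattern: drive (e, e+s+1), measure all offset-(s+1)
    pairs not touching a drive electrode; one frame per electrode."""
    if skip < 0 or skip >= n_electrodes - 1:
        raise PatternError(f"skip={skip} is degenerate for {n_electrodes} electrodes")
    if not 1.0 <= current_ma <= 4.0:
        warnings.warn(
            f"injection current {current_ma} mA is outside the study range 1-4 mA",
            stacklevel=2,
        )
    off = skip + 1
    frames = []
    for e in range(n_electrodes):
        d = (e, (e + off) % n_electrodes)
        pairs = []
        for m in range(n_electrodes):
            p = (m, (m + off) % n_electrodes)
            if d[0] in p or d[1] in p:
                continue
            pairs.append(p)
        frames.append(Frame(d, float(current_ma), tuple(pairs)))
    return StimulationPattern(tuple(frames), n_electrodes)


# ---------------------------------------------------------------------------
# P1 assembly


def p1_unit_stiffness(mesh: TriMesh) -> np.ndarray:
    """(E, 3, 3) local stiffness matrices for σ = 1 (scale-invariant in 2-D)."""
    p = mesh.nodes[mesh.elements]  # (E,3,2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]  # = 2A (signed)
    S = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (
        2.0 * area2[:, None, None]
    )
    return S


def _electrode_edges(mesh: TriMesh) -> list[list[tuple[int, int, float]]]:
    """Per electrode: boundary edges (i, j, length_m) joining its own nodes."""
    own = [set(int(i) for i in nds) for nds in mesh.electrode_nodes]
    out: list[list[tuple[int, int, float]]] = [[] for _ in own]
    for a, b in mesh.boundary_edges:
        a, b = int(a), int(b)
        for l, s in enumerate(own):
            if a in s and b in s:
                ln = float(np.linalg.norm(mesh.nodes[a] - mesh.nodes[b])) / CM_PER_M
                out[l].append((a, b, ln))
                break
    return out


class FEMSystem:
    """Assembled, factorized forward operator for one (mesh, σ, model) triple.

    Exposes solves for arbitrary electrode current vectors and the pieces the
    adjoint Jacobian needs (full solution vectors and per-element local
    stiffness).  The grounded system appends one Lagrange multiplier row
    enforcing a zero-mean potential (nodal mean for the point model,
    electrode-potential mean for the complete model), which leaves
    differential voltages invariant under relabelling.
    """

    def __init__(
        self,
        mesh: TriMesh,
        sigma: ConductivityField,
        electrode_model: ElectrodeModel = "complete",
        contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
    ):
        if sigma.mesh_id != mesh.mesh_id:
            raise AssemblyError("conductivity field does not index this mesh")
        if len(sigma.values) != mesh.n_elements:
            raise AssemblyError("conductivity length mismatch")
        self.mesh = mesh
        self.sigma = sigma
        self.electrode_model = electrode_model
        self.n = mesh.n_nodes
        self.L = mesh.n_electrodes

        S = p1_unit_stiffness(mesh)
        self.local_stiffness = S
        tri = mesh.elements
        rows = np.repeat(tri, 3, axis=1).ravel()
        cols = np.tile(tri, (1, 3)).ravel()
        vals = (S * sigma.values[:, None, None]).ravel()
        K = sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)).tocsr()

        if electrode_model == "point":
            # representative node = central node of each pad
            self.rep = np.array(
                [int(nds[len(nds) // 2]) for nds in mesh.electrode_nodes]
            )
            g = np.ones(self.n) / self.n
            A = sp.bmat([[K, g[:, None]], [g[None, :], None]], format="csc")
            self.dim = self.n + 1
        elif electrode_model == "complete":
            if contact_impedance <= 0:
                raise AssemblyError("contact impedance must be positive")
            z_m = contact_impedance / CM_PER_M  # Ω·cm → Ω·m (per unit depth)
            edges = _electrode_edges(mesh)
            if any(len(e) == 0 for e in edges):
                raise AssemblyError(
                    "an electrode has no boundary edge; mesh pads need >= 2 nodes"
                )
            r, c, v = [], [], []
            Cc = np.zeros((self.n, self.L))
            D = np.zeros(self.L)
            for l, el in enumerate(edges):
                for a, b, ln in el:
                    # edge mass matrix [[2,1],[1,2]]*ln/6 scaled by 1/z
                    m11 = ln / (3.0 * z_m)
                    m12 = ln / (6.0 * z_m)
                    r += [a, b, a, b]
                    c += [a, b, b, a]
                    v += [m11, m11, m12, m12]
                    Cc[a, l] -= ln / (2.0 * z_m)
                    Cc[b, l] -= ln / (2.0 * z_m)
                    D[l] += ln / z_m
            M = sp.coo_matrix((v, (r, c)), shape=(self.n, self.n)).tocsr()
            gU = np.zeros(self.L + 1)
            gU[: self.L] = 1.0 / self.L
            top = sp.hstack([K + M, sp.csr_matrix(Cc), sp.csr_matrix((self.n, 1))])
            mid = sp.hstack(
                [sp.csr_matrix(Cc.T), sp.diags(D), sp.csr_matrix(np.ones((self.L, 1)) / self.L)]
            )
            bot = sp.hstack(
                [
                    sp.csr_matrix((1, self.n)),
                    sp.csr_matrix(np.ones((1, self.L)) / self.L),
                    sp.csr_matrix((1, 1)),
                ]
            )
            A = sp.vstack([top, mid, bot], format="csc")
            self.dim = self.n + self.L + 1
        else:
            raise AssemblyError(f"unknown electrode model {electrode_model!r}")

        self.K = K
        try:
            self.lu = splu(A.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular geometry
            raise AssemblyError(f"singular system after grounding: {exc}") from exc

    # -- current → solution ------------------------------------------------
    def electrode_rhs(self, currents_a: np.ndarray) -> np.ndarray:
        """RHS for a vector of per-electrode currents in amps (sums to 0)."""
        rhs = np.zeros(self.dim)
        if self.electrode_model == "point":
            rhs[self.rep] = currents_a
        else:
            rhs[self.n : self.n + self.L] = currents_a
        return rhs

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.lu.solve(rhs)

    def electrode_potentials(self, sol: np.ndarray) -> np.ndarray:
        if self.electrode_model == "point":
            return sol[self.rep]
        return sol[self.n : self.n + self.L]

    def measurement_rhs(self, pair: tuple[int, int]) -> np.ndarray:
        """Adjoint source for the differential measurement V(m+) − V(m−)."""
        cur = np.zeros(self.L)
        cur[pair[0]] = 1.0
        cur[pair[1]] = -1.0
        return self.electrode_rhs(cur)


def assemble_system(
    mesh: TriMesh,
    sigma: ConductivityField,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
) -> FEMSystem:
    """Assemble and factorize the grounded FEM system (linear in per-element σ)."""
    return FEMSystem(mesh, sigma, electrode_model, contact_impedance)


def solve_forward(
    mesh: TriMesh,
    sigma: ConductivityField,
    pattern: StimulationPattern,
    electrode_model: ElectrodeModel = "complete",
    contact_impedance: float = DEFAULT_CONTACT_IMPEDANCE,
    frequency_khz: float = 50.0,
    system: FEMSystem | None = None,
) -> MeasurementSet:
    """Noise-free boundary voltages for every frame of ``pattern``."""
    if pattern.n_electrodes != mesh.n_electrodes:
        raise PatternError(
            f"pattern is for {pattern.n_electrodes} electrodes, mesh has {mesh.n_electrodes}"
        )
    sys_ = system if system is not None else assemble_system(
        mesh, sigma, electrode_model, contact_impedance
    )
    voltages = []
    for f in pattern.frames:
        cur = np.zeros(mesh.n_electrodes)
        cur[f.drive[0]] = f.current_ma * 1e-3
        cur[f.drive[1]] = -f.current_ma * 1e-3
        sol = sys_.solve(sys_.electrode_rhs(cur))
        U = sys_.electrode_potentials(sol)
        voltages.append(np.array([U[a] - U[b] for a, b in f.measurement_pairs]))
    return MeasurementSet(pattern, voltages, frequency_khz=frequency_khz)


# ---------------------------------------------------------------------------
# noise


@dataclass(frozen=True)
class NoiseModel:
    """none | additive (SD in volts) | additive_relative (fraction of RMS
    voltage) | multiplicative (fractional SD per sample)."""

    kind: Literal["none", "additive", "additive_relative", "multiplicative"] = "none"
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("noise SD must be non-negative")

    def describe(self) -> str:
        if self.kind == "none" or self.sd == 0.0:
            return "none"
        return f"{self.kind}:{self.sd!r}"


def add_noise(data: MeasurementSet, model: NoiseModel, seed: int) -> MeasurementSet:
    """Apply a reproducible noise model; identical seeds give identical output."""
    v = data.as_vector()
    if model.kind == "none" or model.sd == 0.0:
        return data.with_vector(v, noise_model="none", seed=seed)
    rng = np.random.default_rng(seed)
    if model.kind == "additive":
        out = v + rng.normal(0.0, model.sd, size=v.shape)
    elif model.kind == "additive_relative":
        sd = model.sd * float(np.sqrt(np.mean(v**2)))
        out = v + rng.normal(0.0, sd, size=v.shape)
    elif model.kind == "multiplicative":
        out = v * (1.0 + rng.normal(0.0, model.sd, size=v.shape))
    else:
        raise ParameterError(f"unknown noise model {model.kind!r}")
    return data.with_vector(out, noise_model=model.describe(), seed=seed)


# ---------------------------------------------------------------------------
# CSV round trip


def save_measurements(data: MeasurementSet, csv_path, sidecar_path=None) -> None:
    """One row per frame × measurement pair, plus a JSON sidecar of metadata."""
    with open(csv_path, "w") as fh:
        fh.write("frame,drive_pos,drive_neg,meas_pos,meas_neg,current_mA,voltage_V\n")
        for i, (f, v) in enumerate(zip(data.pattern.frames, data.voltages)):
            for (a, b), vv in zip(f.measurement_pairs, v):
                fh.write(
                    f"{i},{f.drive[0]},{f.drive[1]},{a},{b},{f.current_ma!r},{float(vv)!r}\n"
                )
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "frequency_khz": data.frequency_khz,
                    "noise_model": data.noise_model,
                    "seed": data.seed,
                    "n_electrodes": data.pattern.n_electrodes,
                },
                fh,
                indent=1,
            )


def load_measurements(csv_path, sidecar_path=None) -> MeasurementSet:
    import csv as _csv

    frames: dict[int, dict] = {}
    with open(csv_path) as fh:
        rd = _csv.DictReader(fh)
        need = {"frame", "drive_pos", "drive_neg", "meas_pos", "meas_neg", "current_mA", "voltage_V"}
        if rd.fieldnames is None or not need.issubset(rd.fieldnames):
            raise InputError(f"{csv_path}: missing measurement columns")
        for row in rd:
            try:
                i = int(row["frame"])
                fr = frames.setdefault(
                    i,
                    {
                        "drive": (int(row["drive_pos"]), int(row["drive_neg"])),
                        "current": float(row["current_mA"]),
                        "pairs": [],
                        "volts": [],
                    },
                )
                fr["pairs"].append((int(row["meas_pos"]), int(row["meas_neg"])))
                fr["volts"].append(float(row["voltage_V"]))
            except (TypeError, ValueError) as exc:
                raise InputError(f"{csv_path}: malformed row {row!r}") from exc
    if not frames:
        raise InputError(f"{csv_path}: no measurement rows")
    meta = {"frequency_khz": 50.0, "noise_model": "none", "seed": None, "n_electrodes": None}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta.update(json.load(fh))
    n_el = meta["n_electrodes"]
    if n_el is None:
        n_el = 1 + max(
            max(max(f["drive"]) for f in frames.values()),
            max(max(max(p) for p in f["pairs"]) for f in frames.values()),
        )
    fr_objs, volts = [], []
    for i in sorted(frames):
        f = frames[i]
        fr_objs.append(Frame(f["drive"], f["current"], tuple(f["pairs"])))
        volts.append(np.array(f["volts"]))
    return MeasurementSet(
        StimulationPattern(tuple(fr_objs), int(n_el)),
        volts,
        frequency_khz=float(meta["frequency_khz"]),
        noise_model=str(meta["noise_model"]),
        seed=meta["seed"],
    )
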