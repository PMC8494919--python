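"""Parametric 2-D abdomen phantoms and their finite-element meshes.

A phantom is an abdominal cross-section given as a closed outline polygon
(coordinates in cm) with labelled internal organ polygons (liver,
subcutaneous fat, spine) carrying true conductivities in S·m⁻¹, plus an
electrode belt.  ``build_phantom`` triangulates the phantom into a
:class:`TriMesh` whose elements inherit the label of the innermost region
containing their centroid; these labels are the anatomical prior consumed
by the regularized inversion.

Electrodes are centred at equally spaced arc-length positions along the
outline, counter-clockwise, starting where the positive-x ray from the
outline centroid crosses the boundary.  Each electrode owns the contiguous
run of boundary nodes inside its arc span.

Meshing is Delaunay-based: boundary nodes are placed by arc-length sampling
(outline and region-polygon boundaries both contribute points so triangle
edges follow organ boundaries closely), interior nodes come from a hexagonal
lattice, and triangles whose centroid falls outside the outline are
discarded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient

from .errors import GeometryError, ResolutionError

REGION_LABELS = ("liver", "subcutaneous_fat", "spine", "background")

#: Arc-length fraction of the belt covered by one electrode pad.  The study
#: hardware used disposable ECG electrodes (~2.5 cm pads on a ~100 cm belt);
#: the width is a config default, not a measured quantity.
DEFAULT_ELECTRODE_WIDTH = 0.012


class RegionSpec(BaseModel):
    """One labelled organ polygon with its true conductivity."""

    label: str
    polygon: list[tuple[float, float]]
    conductivity: float = Field(gt=0.0, description="true conductivity, S/m")

    @field_validator("label")
    @classmethod
    def _known_label(cls, v: str) -> str:
        if v not in REGION_LABELS:
            raise ValueError(f"label must be one of {REGION_LABELS}, got {v!r}")
        return v

    @field_validator("polygon")
    @classmethod
    def _enough_vertices(cls, v):
        if len(v) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        return v


class PhantomSpec(BaseModel):
    """Abdomen phantom: outline (cm), organ regions, electrode belt.

    ``background_conductivity`` applies to every element not inside any
    region polygon (skin/muscle/viscera average).
    """

    outline: list[tuple[float, float]]
    regions: list[RegionSpec] = Field(default_factory=list)
    background_conductivity: float = Field(default=0.45, gt=0.0)
    n_electrodes: int = 32
    electrode_width: float = Field(default=DEFAULT_ELECTRODE_WIDTH, gt=0.0, lt=0.5)

    @field_validator("outline")
    @classmethod
    def _enough_vertices(cls, v):
        if len(v) < 3:
            raise ValueError("outline needs at least 3 vertices")
        return v

    @field_validator("n_electrodes")
    @classmethod
    def _electrode_count(cls, v: int) -> int:
        if v < 8 or v % 2:
            raise ValueError("n_electrodes must be even and >= 8")
        return v

    @model_validator(mode="after")
    def _geometry_checks(self) -> "PhantomSpec":
        poly = Polygon(self.outline)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("outline polygon is self-intersecting or invalid")
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise GeometryError("region labels must be unique")
        for r in self.regions:
            rp = Polygon(r.polygon)
            if not rp.is_valid or not rp.is_simple:
                raise GeometryError(f"region {r.label!r} polygon is invalid")
            if not poly.buffer(1e-9 * np.sqrt(poly.area)).contains(rp):
                raise GeometryError(f"region {r.label!r} is not inside the outline")
        if self.n_electrodes * self.electrode_width >= 1.0:
            raise GeometryError("electrodes overlap: n_electrodes * electrode_width >= 1")
        return self

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def conductivity_of(self, label: str) -> float:
        if label == "background":
            return self.background_conductivity
        for r in self.regions:
            if r.label == label:
                return r.conductivity
        raise KeyError(label)


@dataclass
class TriMesh:
    """Triangulated phantom with region labels and electrode node sets.

    nodes are (N, 2) cm coordinates; elements (E, 3) CCW node triples;
    boundary_edges (B, 2) trace the outline as one closed CCW loop;
    electrode_nodes[k] lists the boundary nodes owned by electrode k.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_edges: np.ndarray
    element_region: np.ndarray  # dtype=object / str per element
    electrode_nodes: list[np.ndarray]
    _mesh_id: str = field(default="", repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    @property
    def mesh_id(self) -> str:
        if not self._mesh_id:
            h = hashlib.sha1()
            h.update(np.ascontiguousarray(self.nodes).tobytes())
            h.update(np.ascontiguousarray(self.elements).tobytes())
            self._mesh_id = h.hexdigest()[:16]
        return self._mesh_id

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def total_area(self) -> float:
        return float(self.element_areas().sum())


# ---------------------------------------------------------------------------
# mesh construction


def _arc_origin(poly: Polygon) -> float:
    """Arc-length position where the +x ray from the centroid hits the boundary."""
    c = poly.centroid
    reach = 10.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    ray = LineString([(c.x, c.y), (c.x + reach, c.y)])
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:  # centroid outside (crescent shapes) — fall back to vertex 0
        return 0.0
    if hit.geom_type != "Point":
        hit = min(list(hit.geoms), key=lambda g: c.distance(g))
    return float(poly.exterior.project(hit))


def _sample_ring(ring, spacing: float) -> np.ndarray:
    """Points along a closed ring at approximately uniform arc spacing."""
    n = max(int(np.ceil(ring.length / spacing)), 8)
    s = np.arange(n) * ring.length / n
    return np.array([ring.interpolate(float(t)).coords[0] for t in s])


def build_phantom(spec: PhantomSpec, target_element_size: float) -> TriMesh:
    """Triangulate a phantom at the requested nominal element edge length (cm).

    The union of element areas matches the outline polygon area to ~1 %, each
    element carries the label of the innermost region polygon containing its
    centroid, and electrode k's nodes are the boundary nodes within its arc
    span (guaranteed non-empty and disjoint).
    """
    if target_element_size <= 0:
        raise ResolutionError("target_element_size must be positive")
    h = float(target_element_size)
    poly = orient(Polygon(spec.outline), sign=1.0)  # CCW exterior
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("outline polygon is self-intersecting or invalid")
    ring = poly.exterior
    L = ring.length

    # --- boundary nodes: electrode pads + gap fill, by arc position
    n_el = spec.n_electrodes
    w = spec.electrode_width * L
    if w < 1e-12:
        raise GeometryError("electrode width is degenerate")
    s0 = _arc_origin(poly)
    centres = (s0 + np.arange(n_el) * L / n_el) % L
    arcs: list[float] = []
    electrode_spans: list[tuple[float, float]] = []
    for sc in centres:
        lo, hi = sc - w / 2.0, sc + w / 2.0
        electrode_spans.append((lo, hi))
        n_sub = max(2, int(np.ceil(w / h)) + 1)  # >= 3 nodes per pad
        arcs.extend(np.linspace(lo, hi, n_sub + 1))
    # gap nodes between consecutive pads (modular arc arithmetic handles the
    # pad that straddles the arc origin)
    for k in range(n_el):
        lo = electrode_spans[k][1]
        gap = (electrode_spans[(k + 1) % n_el][0] - lo) % L
        if gap <= 1e-9 * L:
            raise GeometryError("electrode pads overlap; reduce electrode_width")
        n_gap = int(np.ceil(gap / h))
        if n_gap > 1:
            arcs.extend(lo + np.arange(1, n_gap) * gap / n_gap)
    arcs = np.sort(np.mod(arcs, L))
    keep = np.ones(len(arcs), bool)
    keep[1:] = np.diff(arcs) > 1e-9 * L
    arcs = arcs[keep]
    boundary_pts = np.array([ring.interpolate(float(s)).coords[0] for s in arcs])

    # --- region-boundary nodes (constrained-edge surrogate)
    for r in spec.regions:
        if h * h > Polygon(r.polygon).area:
            raise ResolutionError(
                f"element size {h} cm too large to resolve region {r.label!r}"
            )
    region_polys = []
    extra: list[np.ndarray] = []
    inner = poly.buffer(-0.55 * h)
    for r in spec.regions:
        rp = orient(Polygon(r.polygon), sign=1.0)
        region_polys.append((r.label, rp))
        pts = _sample_ring(rp.exterior, h)
        mask = np.array([inner.contains(Point(*p)) for p in pts])
        extra.append(pts[mask])

    # --- interior hex lattice
    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3.0) / 2.0
    rows = np.arange(miny - h, maxy + h, dy)
    grid = []
    for i, y in enumerate(rows):
        xs = np.arange(minx - h, maxx + h, h) + (0.5 * h if i % 2 else 0.0)
        grid.append(np.column_stack([xs, np.full_like(xs, y)]))
    grid = np.vstack(grid)
    from shapely import contains_xy

    inside = contains_xy(inner, grid[:, 0], grid[:, 1])
    grid = grid[inside]
    # drop lattice points crowding the sampled region boundaries
    if extra and any(len(e) for e in extra):
        rb = np.vstack([e for e in extra if len(e)])
        if len(rb):
            from scipy.spatial import cKDTree

            d, _ = cKDTree(rb).query(grid)
            grid = grid[d > 0.55 * h]
    else:
        rb = np.empty((0, 2))

    pts = np.vstack([boundary_pts, rb, grid]) if len(rb) else np.vstack([boundary_pts, grid])
    n_bound = len(boundary_pts)

    # --- Delaunay + outside-triangle filtering
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    keep = contains_xy(poly, cent[:, 0], cent[:, 1])
    p = pts[tri.simplices]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    keep &= np.abs(area2) > 1e-12 * h * h
    elements = tri.simplices[keep]
    flip = area2[keep] < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    # drop unreferenced points, renumber
    used = np.unique(elements)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    elements = remap[elements]
    bidx_old = np.arange(n_bound)
    if not np.all(remap[bidx_old] >= 0):
        raise GeometryError("mesh lost outline nodes; refine target_element_size")

    # --- boundary edge loop
    edges = np.vstack(
        [elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bmask = counts[inv] == 1
    bedges = edges[bmask]  # oriented CCW because elements are CCW
    nxt = dict(zip(bedges[:, 0].tolist(), bedges[:, 1].tolist()))
    if len(nxt) != len(bedges):
        raise GeometryError("boundary is not a single simple loop; adjust element size")
    start = bedges[0, 0]
    loop = [start]
    cur = nxt[start]
    while cur != start:
        loop.append(cur)
        cur = nxt.get(cur, None)
        if cur is None or len(loop) > len(bedges):
            raise GeometryError("boundary edges do not close into one loop")
    loop_arr = np.array(loop)
    boundary_edges = np.column_stack([loop_arr, np.roll(loop_arr, -1)])

    # --- electrode node sets by arc span
    arc_of = {int(remap[i]): float(arcs[i]) for i in range(n_bound) if remap[i] >= 0}
    electrode_nodes: list[np.ndarray] = []
    tol = 1e-9 * L
    for lo, hi in electrode_spans:
        own = []
        for nd, s in arc_of.items():
            for shift in (0.0, L, -L):
                if lo - tol <= s + shift <= hi + tol:
                    own.append(nd)
                    break
        if not own:
            raise ResolutionError("an electrode owns no boundary node; refine mesh")
        own = sorted(own, key=lambda nd: (arc_of[nd] - lo) % L)
        electrode_nodes.append(np.array(own, dtype=int))
    flat = np.concatenate(electrode_nodes)
    if len(np.unique(flat)) != len(flat):
        raise GeometryError("electrode node sets overlap; reduce electrode_width")

    # --- region labels: innermost containing polygon wins
    cent = nodes[elements].mean(axis=1)
    labels = np.array(["background"] * len(elements), dtype=object)
    for lab, rp in sorted(region_polys, key=lambda t: -t[1].area):
        m = contains_xy(rp, cent[:, 0], cent[:, 1])
        labels[m] = lab
    for lab, rp in region_polys:
        if not np.any(labels == lab):
            raise ResolutionError(
                f"element size {h} cm cannot resolve region {lab!r}"
            )

    return TriMesh(
        nodes=nodes,
        elements=elements,
        boundary_edges=boundary_edges,
        element_region=labels,
        electrode_nodes=electrode_nodes,
    )


def region_mask(mesh: TriMesh, label: str) -> np.ndarray:
    """Indices of elements carrying ``label``; KeyError if the label is absent."""
    if label not in set(mesh.element_region.tolist()):
        raise KeyError(f"no elements labelled {label!r}")
    return np.flatnonzero(mesh.element_region == label)


def phantom_conductivity(mesh: TriMesh, spec: PhantomSpec) -> np.ndarray:
    """Per-element true conductivity (S/m) from the phantom's region table."""
    sig = np.full(mesh.n_elements, spec.background_conductivity)
    for r in spec.regions:
        sig[mesh.element_region == r.label] = r.conductivity
    return sig


# ---------------------------------------------------------------------------
# canonical phantoms


def ellipse_polygon(a: float, b: float, n: int = 96, centre=(0.0, 0.0)) -> list:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return [(centre[0] + a * np.cos(x), centre[1] + b * np.sin(x)) for x in t]


def circle_polygon(r: float, n: int = 96, centre=(0.0, 0.0)) -> list:
    return ellipse_polygon(r, r, n, centre)


def reference_abdomen_phantom(
    liver_conductivity: float = 0.30,
    background_conductivity: float = 0.45,
    n_electrodes: int = 32,
) -> PhantomSpec:
    """Elliptical abdominal cross-section with a single liver inclusion.

    Semi-axes 15 cm x 10 cm; the liver sits in the subject-left upper
    quadrant as a 4.5 cm disc, mimicking the mid-liver slice used for belt
    placement.  Conductivities default to a muscle/viscera background of
    0.45 S/m and a liver of 0.30 S/m.
    """
    return PhantomSpec(
        outline=ellipse_polygon(15.0, 10.0),
        regions=[
            RegionSpec(
                label="liver",
                polygon=circle_polygon(4.5, 48, centre=(6.0, 2.0)),
                conductivity=liver_conductivity,
            )
        ],
        background_conductivity=background_conductivity,
        n_electrodes=n_electrodes,
    )


def anatomical_abdomen_phantom(
    liver_conductivity: float = 0.30,
    background_conductivity: float = 0.45,
    fat_conductivity: float = 0.05,
    spine_conductivity: float = 0.08,
    n_electrodes: int = 32,
) -> PhantomSpec:
    """Reference phantom plus a subcutaneous fat ring segment and spine."""
    return PhantomSpec(
        outline=ellipse_polygon(15.0, 10.0),
        regions=[
            RegionSpec(
                label="liver",
                polygon=circle_polygon(4.5, 48, centre=(6.0, 2.0)),
                conductivity=liver_conductivity,
            ),
            RegionSpec(
                label="subcutaneous_fat",
                polygon=ellipse_polygon(4.0, 1.6, 48, centre=(0.0, -8.0)),
                conductivity=fat_conductivity,
            ),
            RegionSpec(
                label="spine",
                polygon=circle_polygon(1.6, 32, centre=(0.0, -5.2)),
                conductivity=spine_conductivity,
            ),
        ],
        background_conductivity=background_conductivity,
        n_electrodes=n_electrodes,
    )


# ---------------------------------------------------------------------------
# mesh text format (round-trip exact)

_FMT_HEADER = "# livereit trimesh v1"


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh to the plain-text node/element/label format (bit-exact)."""
    with open(path, "w") as fh:
        fh.write(_FMT_HEADER + "\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
        fh.write(f"elements {mesh.n_elements}\n")
        for a, b, c in mesh.elements:
            fh.write(f"{a} {b} {c}\n")
        fh.write(f"boundary_edges {len(mesh.boundary_edges)}\n")
        for a, b in mesh.boundary_edges:
            fh.write(f"{a} {b}\n")
        fh.write(f"element_region {mesh.n_elements}\n")
        for lab in mesh.element_region:
            fh.write(f"{lab}\n")
        fh.write(f"electrodes {mesh.n_electrodes}\n")
        for nds in mesh.electrode_nodes:
            fh.write(" ".join(str(int(i)) for i in nds) + "\n")


def load_mesh(path) -> TriMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _FMT_HEADER:
        from .errors import InputError

        raise InputError(f"{path} is not a livereit trimesh file")
    i = 1

    def block(name):
        nonlocal i
        tag, n = lines[i].split()
        if tag != name:
            raise ValueError(f"expected section {name}, found {tag}")
        i += 1
        out = lines[i : i + int(n)]
        i += int(n)
        return out

    nodes = np.array([[float(t) for t in ln.split()] for ln in block("nodes")])
    elements = np.array([[int(t) for t in ln.split()] for ln in block("elements")])
    bedges = np.array([[int(t) for t in ln.split()] for ln in block("boundary_edges")])
    labels = np.array(block("element_region"), dtype=object)
    electrodes = [np.array([int(t) for t in ln.split()], dtype=int) for ln in block("electrodes")]
    return TriMesh(nodes, elements, bedges, labels, electrodes)
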