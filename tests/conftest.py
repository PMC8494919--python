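"""Shared fixtures: canonical meshes and one reference reconstruction
experiment reused across inverse-solver and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from livereit.mesh import PhantomSpec, TriMesh, build_phantom, circle_polygon
from livereit.pipeline import reference_recovery_experiment


@pytest.fixture(scope="session")
def fine_disk():
    """Unit-disk mesh (cm) fine enough for ~0.5 % analytic agreement."""
    spec = PhantomSpec(outline=circle_polygon(1.0, 256), n_electrodes=16)
    return build_phantom(spec, 0.06)


@pytest.fixture(scope="session")
def coarse_disk():
    """Small disk mesh (~120 elements) for finite-difference Jacobian checks."""
    spec = PhantomSpec(outline=circle_polygon(1.0, 64), n_electrodes=8, electrode_width=0.02)
    return build_phantom(spec, 0.25)


@pytest.fixture(scope="session")
def abdomen_recovery():
    """The reference inclusion-recovery experiment (liver 0.30, bg 0.45)."""
    return reference_recovery_experiment(0.30)


@pytest.fixture(scope="session")
def liver_sweep(abdomen_recovery):
    """Reconstructed liver means for a 5-point sweep of true liver σ."""
    values = [0.24, 0.28, 0.32, 0.36, 0.40]
    means = [reference_recovery_experiment(s)["liver_mean"] for s in values]
    return values, means


def make_crisscross_mesh(n: int = 4, half: float = 1.0) -> TriMesh:
    """Hand-built mirror-symmetric mesh of [-1,1]²: each grid cell split into
    4 triangles around its centre, symmetric about the x axis for even n."""
    xs = np.linspace(-half, half, n + 1)
    grid_id = {}
    nodes = []
    for j, y in enumerate(xs):
        for i, x in enumerate(xs):
            grid_id[(i, j)] = len(nodes)
            nodes.append((x, y))
    elements = []
    for j in range(n):
        for i in range(n):
            c = len(nodes)
            nodes.append(((xs[i] + xs[i + 1]) / 2.0, (xs[j] + xs[j + 1]) / 2.0))
            a, b = grid_id[(i, j)], grid_id[(i + 1, j)]
            d, e = grid_id[(i + 1, j + 1)], grid_id[(i, j + 1)]
            elements += [(a, b, c), (b, d, c), (d, e, c), (e, a, c)]
    nodes = np.array(nodes)
    elements = np.array(elements)
    # boundary loop by edge counting
    edges = np.vstack([elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bedges = edges[counts[inv] == 1]
    nxt = dict(zip(bedges[:, 0].tolist(), bedges[:, 1].tolist()))
    loop = [int(bedges[0, 0])]
    while True:
        nx = nxt[loop[-1]]
        if nx == loop[0]:
            break
        loop.append(nx)
    bnd = np.column_stack([loop, np.roll(loop, -1)])
    labels = np.array(["background"] * len(elements), dtype=object)
    # four single-node point electrodes, mirror-symmetric about the x axis
    def node_at(x, y):
        return int(np.argmin(np.hypot(nodes[:, 0] - x, nodes[:, 1] - y)))

    electrodes = [
        np.array([node_at(half, half / 2)]),     # A
        np.array([node_at(half, -half / 2)]),    # B = mirror(A)
        np.array([node_at(-half, half / 2)]),    # C
        np.array([node_at(-half, -half / 2)]),   # D = mirror(C)
    ]
    return TriMesh(nodes, elements, bnd, labels, electrodes)
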