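import networkx as nx
import numpy as np
import pytest

from gliatrace.skeleton import FilamentGraph


def make_graph(points, edges, soma=0, radii=None):
    """Build a FilamentGraph from raw (z, y, x) µm coordinates."""
    g = nx.Graph()
    for i, p in enumerate(points):
        r = radii[i] if radii is not None else 0.5
        g.add_node(i, pos=np.asarray(p, dtype=float), radius=float(r))
    g.add_edges_from(edges)
    return FilamentGraph(graph=g, soma=soma)


@pytest.fixture
def straight_process_graph():
    """Soma at origin plus a straight 10 µm process along +x."""
    pts = [(0.0, 0.0, 0.0)] + [(0.0, 0.0, float(i)) for i in range(1, 11)]
    edges = [(i, i + 1) for i in range(10)]
    return make_graph(pts, edges, radii=[3.0] + [0.5] * 10)


@pytest.fixture
def star_graph():
    """Four coplanar 5.5 µm arms at right angles from the soma."""
    pts = [(0.0, 0.0, 0.0)]
    edges = []
    nid = 1
    for d in [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
        pts.append((0.0, 5.5 * d[1], 5.5 * d[2]))
        edges.append((0, nid))
        nid += 1
    return make_graph(pts, edges, radii=[3.0, 0.5, 0.5, 0.5, 0.5])


@pytest.fixture
def small_scene():
    """One compact noise-free cell in a small anisotropic stack."""
    from gliatrace.synthetic import CellSpec, SceneSpec, rasterize_scene

    scene = SceneSpec(
        field_xy_um=48.0,
        n_slices=30,
        voxel_xy_um=0.25,
        voxel_z_um=0.8,
        n_cells=1,
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        seed=3,
    )
    spec = CellSpec(
        soma_radius_um=3.5,
        nucleus_radius_um=2.5,
        n_primary=4,
        branch_prob=0.5,
        segment_length_mean_um=8.0,
        segment_length_sd_um=1.0,
        max_order=2,
        tortuosity=0.12,
        process_radius_um=0.6,
        taper=0.9,
    )
    stack, gt = rasterize_scene(scene, [spec], soma_centers=[np.array([12.0, 24.0, 24.0])])
    return stack, gt, scene, spec
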