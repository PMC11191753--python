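"""Mesh engine: conformity, volume conservation, region tagging, trusses."""

import numpy as np
import pytest

import spinefem as sf
from spinefem import meshing
from spinefem.anatomy import place_cement
from spinefem.params import CementPlan, LIGAMENT_AREAS


def test_unit_cube_volume_conserved():
    mesh = sf.box_mesh((1.0, 1.0, 1.0), (2, 2, 2), order=1)
    assert mesh.element_volumes().sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(mesh.element_volumes() > 0)


def test_prism_split_is_conforming():
    """Every interior face is shared by exactly two tets; boundary faces by
    one (checked on the spine mesh and a box)."""
    for mesh in (sf.box_mesh((1.0, 2.0, 3.0), (2, 3, 4), order=1),
                 sf.generate_mesh(sf.build_segment(),
                                  sf.MeshSettings(target_edge_solid=9.0,
                                                  target_edge_cartilage=2.5,
                                                  element_order=1))):
        faces = mesh.tets[:, :4][:, [[1, 2, 3], [0, 3, 2], [0, 1, 3],
                                     [0, 2, 1]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        assert counts.max() <= 2
        # Euler-type sanity: some boundary faces exist
        assert (counts == 1).sum() > 0


def test_no_inverted_elements_and_quality_floor(default_mesh):
    vols = default_mesh.element_volumes()
    assert vols.min() > 0
    assert default_mesh.min_dihedral_deg() > 1.0


def test_nodes_all_referenced(default_mesh):
    used = np.unique(default_mesh.tets)
    assert len(used) == default_mesh.n_nodes


def test_region_tags_cover_all_elements(default_mesh):
    assert np.all(default_mesh.region_ids >= 0)
    expected = {"cortical", "cancellous", "endplate", "annulus", "nucleus",
                "cartilage"}
    kinds = {t.split("_")[0] for t in default_mesh.region_tags()}
    assert expected <= kinds


def test_region_volumes_match_geometry_at_reference_density():
    """Element volumes per analytic region agree with the geometric volume
    within 2% at the 2 mm reference density."""
    geo = sf.build_segment()
    mesh = sf.generate_mesh(geo, sf.MeshSettings.reference(order=1))
    ana = geo.region_volumes()
    for tag in ("cancellous_T12", "endplate_T12_sup", "annulus_T11T12",
                "nucleus_T11T12", "annulus_T12L1", "nucleus_T12L1",
                "cancellous_L1"):
        vm = mesh.region_volume(tag)
        assert vm == pytest.approx(ana[tag], rel=0.02), tag


def test_mesh_budget_matches_reference_study_order_of_magnitude():
    """Node/element counts at the 2 mm / 0.5 mm density sit within the
    order of magnitude of the reference budget (~3e5 nodes, ~1.9e5
    elements)."""
    geo = place_cement(sf.build_segment(), CementPlan.for_group("B-B"))
    mesh = sf.generate_mesh(geo, sf.MeshSettings.reference(order=2))
    assert 1e5 < mesh.n_nodes < 1e6
    assert 0.5e5 < mesh.n_elements < 1e6


def test_truss_areas_sum_to_table_per_level(default_mesh):
    sums = default_mesh.truss_area_sums()
    for name, area in LIGAMENT_AREAS.items():
        # two disc levels, full sectional area at each
        assert sums[name] == pytest.approx(2 * area, rel=1e-9)


def test_mesh_is_mirror_symmetric(default_mesh):
    from scipy.spatial import cKDTree
    tree = cKDTree(default_mesh.nodes)
    mirrored = default_mesh.nodes * np.array([1.0, -1.0, 1.0])
    d, idx = tree.query(mirrored)
    assert d.max() < 1e-9
    # the reflected coordinate multiset equals the original one
    a = default_mesh.nodes[np.lexsort(default_mesh.nodes.T)]
    b = mirrored[np.lexsort(mirrored.T)]
    assert np.allclose(a, b, atol=1e-9)


def test_cement_retagging_is_mirror_consistent():
    geo_ll = place_cement(sf.build_segment(), CementPlan.for_group("L-L"))
    geo_rr = place_cement(sf.build_segment(), CementPlan.for_group("R-R"))
    st = sf.MeshSettings(target_edge_solid=8.0, target_edge_cartilage=2.0,
                         element_order=1)
    m_ll = sf.generate_mesh(geo_ll, st)
    m_rr = sf.generate_mesh(geo_rr, st)
    # identical meshes; cement element centroids mirror each other
    for vert in ("T11", "L1"):
        c_ll = m_ll.element_centroids()[m_ll.elements_in(f"cement_{vert}")]
        c_rr = m_rr.element_centroids()[m_rr.elements_in(f"cement_{vert}")]
        assert len(c_ll) == len(c_rr) > 0
        flip = c_ll * np.array([1.0, -1.0, 1.0])
        # round the sort keys: mirror partners agree only to round-off
        a = np.lexsort(np.round(flip, 6).T)
        b = np.lexsort(np.round(c_rr, 6).T)
        assert np.allclose(flip[a], c_rr[b], atol=1e-9)


def test_cement_elements_only_replace_cancellous():
    geo = place_cement(sf.build_segment(), CementPlan.for_group("B-B"))
    st = sf.MeshSettings(target_edge_solid=8.0, target_edge_cartilage=2.0,
                         element_order=1)
    with_c = sf.generate_mesh(geo, st)
    without = sf.generate_mesh(sf.build_segment(), st)
    assert with_c.n_elements == without.n_elements
    changed = np.flatnonzero(with_c.region_ids != without.region_ids)
    new_tags = {with_c.region_names[i] for i in with_c.region_ids[changed]}
    old_tags = {without.region_names[i] for i in without.region_ids[changed]}
    assert new_tags <= {"cement_T11", "cement_L1"}
    assert old_tags <= {"cancellous_T11", "cancellous_L1"}


def test_determinism_identical_meshes(coarse_settings):
    m1 = sf.generate_mesh(sf.build_segment(), coarse_settings)
    m2 = sf.generate_mesh(sf.build_segment(), coarse_settings)
    assert np.array_equal(m1.nodes, m2.nodes)
    assert np.array_equal(m1.tets, m2.tets)
    assert np.array_equal(m1.region_ids, m2.region_ids)


def test_surface_groups_populated(default_mesh):
    for name in ("T11_superior", "L1_inferior", "T11_superior_face",
                 "T12_superior_face", "L1_superior_face"):
        assert len(default_mesh.node_sets[name]) > 3
    assert default_mesh.facet_sets["T11_superior"].shape[0] > 10
    # facet corner nodes all lie on the top surface
    top = default_mesh.facet_sets["T11_superior"][:, :3]
    z = default_mesh.nodes[np.unique(top), 2]
    assert np.allclose(z, z.max())


def test_tet10_midside_nodes_are_edge_midpoints(coarse_mesh):
    t = coarse_mesh.tets
    x = coarse_mesh.nodes
    pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for m, (a, b) in enumerate(pairs):
        mid = 0.5 * (x[t[:, a]] + x[t[:, b]])
        assert np.abs(x[t[:, 4 + m]] - mid).max() < 1e-12


def test_vtu_roundtrip(tmp_path, coarse_mesh):
    from spinefem import io
    p = str(tmp_path / "mesh.vtu")
    io.write_vtu(coarse_mesh, p,
                 cell_data={"vms": np.arange(coarse_mesh.n_elements,
                                             dtype=float)})
    nodes, cells, cdata, pdata = io.read_vtu(p)
    assert np.allclose(nodes, coarse_mesh.nodes, atol=1e-8)
    assert np.array_equal(cells, coarse_mesh.tets)
    assert np.array_equal(cdata["region"], coarse_mesh.region_ids)
    assert np.allclose(cdata["vms"],
                       np.arange(coarse_mesh.n_elements, dtype=float))


def test_msh_and_stl_export(tmp_path):
    from spinefem import io
    mesh = sf.box_mesh((1.0, 1.0, 1.0), (1, 1, 1), order=2)
    p = io.write_msh(mesh, str(tmp_path / "m.msh"))
    text = open(p).read()
    assert "$MeshFormat" in text and "4.1" in text
    paths = io.write_stl(mesh, str(tmp_path / "stl"))
    stl = open(paths["solid"]).read()
    assert stl.startswith("solid") and "facet normal" in stl
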