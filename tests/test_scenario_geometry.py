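import dataclasses

import numpy as np
import pytest

from cortistim.errors import GeometryError, MeshError, ParameterError, PlacementError
from cortistim.scenario_geometry import (
    AsymmetricParams,
    ElectrodeSpec,
    SlabParams,
    Tissue,
    build_asymmetric_geometry,
    build_slab_geometry,
    default_electrode_pair,
    generate_mesh,
    label_regions,
    place_electrodes,
)


class TestSlabParams:
    def test_default_gyral_width(self):
        assert SlabParams().precentral_gyrus_width == 8.5

    def test_non_positive_dimension_rejected(self):
        with pytest.raises(ParameterError):
            build_slab_geometry(dataclasses.replace(SlabParams(),
                                                    gm_thickness=-1.0))

    def test_zero_sulcal_depth_is_geometry_error(self):
        with pytest.raises(GeometryError):
            build_slab_geometry(dataclasses.replace(SlabParams(),
                                                    sulcal_depth=0.0))


class TestSlabGeometry:
    def test_path_samples_57_at_1mm(self):
        geom = build_slab_geometry()
        path = geom.cortical_path()
        n = int(np.floor(path.length / 1.0 + 1e-9)) + 1
        assert n == 57

    def test_path_mirror_symmetric(self, small_geom):
        path = small_geom.cortical_path()
        s = np.linspace(0.0, path.length, 101)
        a = path.sample(s)
        b = path.sample(path.length - s)
        b[:, 0] *= -1.0
        assert np.abs(a - b).max() < 1e-9

    def test_tissue_ordering_outside_in(self, small_geom):
        p = small_geom.params
        ys = [p.csf_thickness + p.dura_thickness + p.skull_thickness + 1.0,
              p.csf_thickness + p.dura_thickness + 1.0,
              p.csf_thickness + 0.1,
              0.5 * p.csf_thickness, -1.0, -5.0]
        expected = [Tissue.SCALP, Tissue.SKULL, Tissue.DURA, Tissue.CSF,
                    Tissue.GM, Tissue.WM]
        pts = np.array([[-10.0, y, 0.0] for y in ys])
        assert list(small_geom.tissue_at(pts)) == [int(t) for t in expected]

    def test_depth_sign_convention(self, small_geom):
        assert small_geom.depth([[-10.0, -1.0]])[0] == pytest.approx(1.0)
        assert small_geom.depth([[0.0, -1.0]])[0] < 0.0  # inside the slot
        assert small_geom.depth([[-10.0, 0.5]])[0] < 0.0  # above the brain


class TestAsymmetricGeometry:
    def test_factor_one_reproduces_slab(self, small_params):
        asym = build_asymmetric_geometry(
            AsymmetricParams(**dataclasses.asdict(small_params),
                             asymmetry_factor=1.0))
        slab = build_slab_geometry(small_params)
        a = np.asarray(asym.slot.exterior.coords)
        b = np.asarray(slab.slot.exterior.coords)
        assert a.shape == b.shape
        assert np.abs(a - b).max() < 1e-9

    def test_factor_1p3_bank_longer_by_30pct(self):
        # fillet-free fold keeps the banks as straight polygon walls, so the
        # generated surface arc lengths can be measured directly
        params = AsymmetricParams(asymmetry_factor=1.3, lip_fillet_radius=0.0)
        geom = build_asymmetric_geometry(params)
        coords = np.asarray(geom.slot.exterior.coords)
        hw = params.sulcus_half_width
        yc = -(params.sulcal_depth - hw)
        left = np.abs(coords[:, 0] + hw) < 1e-9
        left_len = coords[left][:, 1].max() - coords[left][:, 1].min()
        top_right = coords[np.argmax(coords[:, 0])]
        right_len = float(np.hypot(top_right[0] - hw, top_right[1] - yc))
        assert right_len / left_len == pytest.approx(1.3, rel=0.01)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ParameterError):
            build_asymmetric_geometry(AsymmetricParams(asymmetry_factor=0.9))

    def test_negative_curvature_rejected(self):
        with pytest.raises(GeometryError):
            build_asymmetric_geometry(
                AsymmetricParams(bank_curvature_opposite=-0.1))


class TestElectrodes:
    def test_separation_13mm(self, small_geom):
        placed = place_electrodes(small_geom,
                                  default_electrode_pair(small_geom))
        a, r = placed.electrodes
        d = np.hypot(a.center_x - r.center_x, a.center_z - r.center_z)
        assert d == pytest.approx(13.0, abs=0.01)

    def test_monopolar_single_contact(self, small_geom):
        placed = place_electrodes(
            small_geom, [ElectrodeSpec(center_x=-6.0, center_z=0.0)])
        assert len(placed.electrodes) == 1
        assert placed.electrodes[0].role == "active"

    def test_overlap_rejected(self, small_geom):
        specs = [ElectrodeSpec(center_x=-6.0, center_z=-2.5, diameter=11.5),
                 ElectrodeSpec(center_x=-6.0, center_z=2.5, diameter=11.5,
                               role="return")]
        with pytest.raises(PlacementError):
            place_electrodes(small_geom, specs)

    def test_min_active_return_separation(self, small_geom):
        specs = [ElectrodeSpec(center_x=-6.0, center_z=-4.0),
                 ElectrodeSpec(center_x=-6.0, center_z=4.0, role="return")]
        with pytest.raises(PlacementError):
            place_electrodes(small_geom, specs)


class TestRegionMap:
    def test_point_under_electrode_is_crown(self, small_geom_electrodes):
        rm = label_regions(small_geom_electrodes)
        e = small_geom_electrodes.active_electrode
        label = rm.label_points([[e.center_x, -1.0]])[0]
        assert label == "C"

    def test_deepest_point_is_bottom_sulcus(self, small_geom):
        rm = label_regions(small_geom)
        p = small_geom.params
        assert rm.label_points([[0.0, -p.sulcal_depth + 0.5]])[0] == "BS"

    def test_mirror_of_crown_is_opposite_crown(self, small_geom):
        rm = label_regions(small_geom)
        path = small_geom.cortical_path()
        q = path.sample([1.0])[0]
        assert rm.label_points([q])[0] == "C"
        assert rm.label_points([[-q[0], q[1]]])[0] == "OC"

    def test_labels_partition_path(self, small_geom):
        rm = label_regions(small_geom)
        s = np.linspace(0, rm.path.length, 300)
        labels = set(rm.label_of_s(s))
        assert labels == {"C", "L", "B", "BS", "OB", "OL", "OC"}

    def test_labels_invariant_along_extrusion(self, small_geom):
        rm = label_regions(small_geom)
        pts = np.array([[-6.0, -1.0], [0.0, -9.0], [6.0, -1.0]])
        base = rm.label_points(pts)
        assert (rm.label_points(pts) == base).all()  # z never enters


class TestMesh:
    def test_volume_matches_geometry(self, small_mesh, small_geom_electrodes):
        vol = small_mesh.element_volumes().sum()
        assert vol == pytest.approx(small_geom_electrodes.analytic_volume(),
                                    rel=0.01)

    def test_refinement_monotone(self, small_geom):
        coarse = generate_mesh(small_geom, resolution=3.0)
        fine = generate_mesh(small_geom, resolution=1.5)
        assert fine.n_elements > coarse.n_elements

    def test_every_element_single_tissue(self, small_mesh):
        assert small_mesh.tissue.shape == (small_mesh.n_elements,)
        assert set(np.unique(small_mesh.tissue)) <= {int(t) for t in Tissue}

    def test_boundary_facets_cover_exterior(self, small_mesh):
        # total tagged facet area equals the surface area of the box
        (x0, x1), (y0, y1), (z0, z1) = (
            (g[0], g[-1]) for g in small_mesh.grid)
        lx, ly, lz = x1 - x0, y1 - y0, z1 - z0
        expected = 2 * (lx * ly + ly * lz + lx * lz)
        area = 0.0
        seen = set()
        for tris in small_mesh.facets.values():
            for tri in tris:
                key = tuple(sorted(tri))
                assert key not in seen  # exactly one tag per facet
                seen.add(key)
            p = small_mesh.nodes[tris]
            area += 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1).sum()
        assert area == pytest.approx(expected, rel=1e-9)

    def test_node_set_mirror_symmetric(self, small_mesh):
        nodes = small_mesh.nodes
        reflected = nodes.copy()
        reflected[:, 0] *= -1.0
        a = nodes[np.lexsort(nodes.T)]
        b = reflected[np.lexsort(reflected.T)]
        assert np.abs(a - b).max() < 1e-9

    def test_quality_above_floor(self, small_mesh):
        assert small_mesh.quality().min() >= 0.05

    def test_bad_resolution_rejected(self, small_geom):
        with pytest.raises(ParameterError):
            generate_mesh(small_geom, resolution=0.0)

    def test_element_budget_guard(self, small_geom):
        with pytest.raises(MeshError):
            generate_mesh(small_geom, resolution=0.05)
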