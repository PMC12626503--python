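"""Osteotomy plane, anatomical frame, block cutting and volume."""

import numpy as np
import pytest
import trimesh

import condylomorph as cm
from condylomorph.block import (
    block_volume_mesh,
    build_cut_plane,
    build_frame,
    cut_block,
)
from condylomorph.geometry import (
    GeometryError,
    Plane,
    RigidTransform,
    apply_rigid,
    signed_distance,
)
from condylomorph.synthetic import CondyleParams, _profile

from conftest import make_frame


def _frame_for(plane):
    return build_frame(plane, (-60, 0, 0), (60, 0, 0), (0, 70, 0), "right")


class TestCutPlane:
    def test_parallel_offset_through_s(self):
        fh = Plane((0, 0, 0), (0, 0, 1))
        c = build_cut_plane(fh, (10, 5, -20), superior_ref=(10, 5, 0))
        assert np.allclose(c.normal, [0, 0, 1])
        assert signed_distance((0, 0, -20), c) == 0

    def test_s_on_fh_gives_same_plane(self):
        fh = Plane((0, 0, 0), (0, 0, 1))
        c = build_cut_plane(fh, (3, -2, 0), superior_ref=(0, 0, 5))
        assert abs(signed_distance(fh.origin, c)) < 1e-12

    def test_tilted_fh_parallelism_dot_product_oracle(self):
        n = np.array([0.0, np.sin(np.radians(10)), np.cos(np.radians(10))])
        fh = Plane((0, 0, 0), n)
        s = np.array([4.0, -7.0, -25.0])
        c = build_cut_plane(fh, s, superior_ref=s + 10 * n)
        assert abs(signed_distance(s, c)) < 1e-12
        assert abs(np.dot(c.normal, fh.normal)) > 1 - 1e-9

    def test_reference_on_plane_is_ambiguous(self):
        fh = Plane((0, 0, 0), (0, 0, 1))
        with pytest.raises(GeometryError, match="ambiguous"):
            build_cut_plane(fh, (0, 0, -5), superior_ref=(9, 9, -5))


class TestFrame:
    def test_axis_aligned_landmarks(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        fr = build_frame(plane, (-60, 0, 0), (60, 0, 0), (0, 70, 0), "right")
        assert np.allclose(fr.u_ml, [1, 0, 0])
        assert np.allclose(fr.u_ap, [0, 1, 0])
        assert np.allclose(fr.u_si, [0, 0, 1])
        fl = build_frame(plane, (-60, 0, 0), (60, 0, 0), (0, 70, 0), "left")
        assert np.allclose(fl.u_ml, [-1, 0, 0])

    def test_mirrored_landmarks_with_flipped_side(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        fr = build_frame(plane, (-60, 1, 0), (55, 2, 0), (5, 70, 0), "right")
        fl = build_frame(plane, (-55, 2, 0), (60, 1, 0), (-5, 70, 0), "left")
        mirror = np.diag([-1.0, 1.0, 1.0])
        assert np.allclose(fl.u_ml, mirror @ fr.u_ml, atol=1e-12)
        assert np.allclose(fl.u_ap, mirror @ fr.u_ap, atol=1e-12)

    def test_rotation_equivariance(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        t = RigidTransform.from_axis_angle([0.2, 0.9, 0.1], 28.0, (3, 1, -2))
        fr = build_frame(plane, (-60, 0, 0), (60, 0, 0), (0, 70, 0), "right")
        fr2 = build_frame(apply_rigid(plane, t),
                          apply_rigid(np.array([-60.0, 0, 0]), t),
                          apply_rigid(np.array([60.0, 0, 0]), t),
                          apply_rigid(np.array([0.0, 70, 0]), t), "right")
        for ax in ("u_ml", "u_ap", "u_si"):
            assert np.allclose(getattr(fr2, ax),
                               t.rotation @ getattr(fr, ax), atol=1e-9)

    def test_degenerate_landmarks_raise(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        with pytest.raises(GeometryError, match="porions"):
            build_frame(plane, (1, 2, 3), (1, 2, 3), (0, 70, 0), "right")
        with pytest.raises(GeometryError, match="parallel"):
            build_frame(plane, (0, 0, -5), (0, 0, 5), (0, 70, 0), "right")


class TestCutAndVolume:
    def test_hemisphere_volume_one_percent(self, sphere10):
        plane = Plane((0, 0, 0), (0, 0, 1))
        block = cut_block(sphere10, plane, _frame_for(plane))
        analytic = 2.0 / 3.0 * np.pi * 10.0 ** 3
        assert block.volume == pytest.approx(analytic, rel=0.01)
        assert block.mesh.is_watertight
        # every non-cap vertex sits above C
        assert block.heights().min() > -1e-6

    def test_half_ellipsoid_volume_one_percent(self, sphere10):
        ell = sphere10.copy()
        ell.vertices = ell.vertices / 10.0 * np.array([10.0, 8.0, 12.0])
        plane = Plane((0, 0, 0), (0, 0, 1))
        block = cut_block(ell, plane, _frame_for(plane))
        analytic = 0.5 * 4.0 / 3.0 * np.pi * 10 * 8 * 12
        assert block.volume == pytest.approx(analytic, rel=0.01)

    def test_unit_cube_volume_exact_and_additive(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        assert block_volume_mesh(box.copy()) == pytest.approx(1.0, abs=1e-12)
        other = box.copy()
        other.apply_translation([5, 0, 0])
        both = trimesh.util.concatenate([box, other])
        assert block_volume_mesh(both) == pytest.approx(2.0, abs=1e-12)

    def test_plane_below_mesh_returns_full_volume(self, sphere10):
        plane = Plane((0, 0, -15), (0, 0, 1))
        block = cut_block(sphere10, plane, _frame_for(plane))
        assert block.volume == pytest.approx(float(sphere10.volume), rel=1e-9)

    def test_plane_above_mesh_is_empty_block_error(self, sphere10):
        plane = Plane((0, 0, 15), (0, 0, 1))
        with pytest.raises(GeometryError, match="empty block"):
            cut_block(sphere10, plane, _frame_for(plane))

    def test_non_watertight_input_reports_open_edges(self, sphere10):
        broken = trimesh.Trimesh(vertices=sphere10.vertices,
                                 faces=sphere10.faces[:-3], process=False)
        plane = Plane((0, 0, 0), (0, 0, 1))
        with pytest.raises(GeometryError, match="not watertight"):
            cut_block(broken, plane, _frame_for(plane))

    def test_multiple_components_keep_most_posterior(self, sphere10):
        # two spheres crossing the plane: condyle is the posterior one
        posterior = sphere10.copy()
        posterior.apply_translation([0, -30, 0])
        anterior = sphere10.copy()
        anterior.vertices = anterior.vertices * 0.5
        anterior.apply_translation([0, 30, 0])
        scene = trimesh.util.concatenate([posterior, anterior])
        plane = Plane((0, 0, 0), (0, 0, 1))
        block = cut_block(scene, plane, _frame_for(plane))
        assert block.n_components_above == 2
        hemi = 2.0 / 3.0 * np.pi * 10 ** 3
        assert block.volume == pytest.approx(hemi, rel=0.01)

    def test_rigid_invariance_of_volume(self, default_condyle):
        _, plane, frame = make_frame(default_condyle.landmarks, "right")
        v0 = cut_block(default_condyle.mesh, plane, frame).volume
        t = RigidTransform.from_axis_angle([1, 0.4, -0.2], 52.0, (8, -3, 11))
        frame_t = build_frame(apply_rigid(plane, t),
                              apply_rigid(default_condyle.landmarks["porion_l"], t),
                              apply_rigid(default_condyle.landmarks["porion_r"], t),
                              apply_rigid(default_condyle.landmarks["orbitale"], t),
                              "right")
        v1 = cut_block(apply_rigid(default_condyle.mesh, t),
                       apply_rigid(plane, t), frame_t).volume
        assert v1 == pytest.approx(v0, rel=1e-9)


class TestVolumeOracles:
    def test_convergence_to_quadrature_truth(self):
        """Block volume error against the profile quadrature shrinks
        monotonically with subdivision level."""
        errs = []
        for sub in (1, 2, 3):
            p = CondyleParams(subdivision=sub)
            gen = cm.generate_condyle(p)
            _, plane, frame = make_frame(gen.landmarks, "right")
            block = cut_block(gen.mesh, plane, frame)
            errs.append(abs(block.volume - gen.true_block_volume)
                        / gen.true_block_volume)
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 0.015

    def test_grid_membership_oracle(self, default_condyle, default_block):
        """Voxel-style oracle: count grid cells whose centers lie inside the
        generator's implicit solid of revolution."""
        p = default_condyle.params
        r_of_z, _, zc, _, _ = _profile(p)
        pitch = 0.25
        xs = np.arange(-p.head_ml - 1, p.head_ml + 1, pitch) + pitch / 2
        ys = np.arange(-p.head_ap - 1, p.head_ap + 1, pitch) + pitch / 2
        zs = np.arange(0, zc + p.head_si + 1, pitch) + pitch / 2
        ratio = p.head_ml / p.head_ap
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        count = 0
        for z in zs:
            r = r_of_z(float(z))
            count += int(((X / ratio) ** 2 + Y ** 2 <= r * r).sum())
        vox_volume = count * pitch ** 3
        assert default_block.volume == pytest.approx(vox_volume, rel=0.02)
        assert vox_volume == pytest.approx(default_condyle.true_block_volume,
                                           rel=0.01)
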