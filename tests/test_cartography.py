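"""Canonical-map registration: staged affine, warp field, auto-assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vsdpipe import cartography as cg
from vsdpipe import synthgen as sg
from vsdpipe.traces import ROI, ROISet


def rois_from_points(points, radii=None, prefix="r"):
    radii = radii if radii is not None else [3.0] * len(points)
    return ROISet([
        ROI(f"{prefix}{i}", "ventral",
            ellipse=(float(x), float(y), float(rad), float(rad), 0.0))
        for i, ((x, y), rad) in enumerate(zip(points, radii))])


def map_from_points(points, radii=None, prefix="n"):
    radii = radii if radii is not None else [3.0] * len(points)
    return sg.CanonicalMap([
        sg.Neuron(f"{prefix}{i}", "ventral", 1, float(x), float(y),
                  float(rad), None)
        for i, ((x, y), rad) in enumerate(zip(points, radii))])


def apply_planted(points, angle_deg=0.0, scale=1.0, stretch=(1.0, 1.0),
                  shift=(0.0, 0.0)):
    th = np.deg2rad(angle_deg)
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = scale * np.asarray(points) @ r.T
    out = out * np.asarray(stretch)
    return out + np.asarray(shift)


@pytest.fixture
def cloud(rng):
    return rng.uniform([-60, -25], [60, 25], size=(25, 2))


def pairs_for(cmap, roi_ids=None):
    ids = [n.id for n in cmap.neurons]
    rois = roi_ids if roi_ids is not None else [f"r{i}" for i in
                                               range(len(ids))]
    return pd.DataFrame({"roi_id": rois, "neuron_id": ids})


class TestCoarseAlign:
    def test_identity_when_points_coincide(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        tf = cg.coarse_align(pairs_for(cmap), cmap, rois)[None]
        assert tf.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert tf.s1 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tf.s2, 1.0, atol=1e-9)
        assert np.allclose(tf.apply(cloud), cloud, atol=1e-9)

    def test_recovers_rotation_and_scale(self, cloud):
        planted = apply_planted(cloud, angle_deg=10.0, scale=1.2,
                                shift=(30.0, -12.0))
        cmap = map_from_points(cloud)
        rois = rois_from_points(planted)
        tf = cg.coarse_align(pairs_for(cmap), cmap, rois)[None]
        assert tf.rotation_deg == pytest.approx(10.0, abs=0.1)
        assert tf.s1 == pytest.approx(1.2, abs=0.01)
        assert np.allclose(tf.apply(cloud), planted, atol=1e-6)

    def test_recovers_anisotropic_stretch(self, cloud):
        planted = apply_planted(cloud, angle_deg=8.0, stretch=(1.3, 0.9))
        cmap = map_from_points(cloud)
        rois = rois_from_points(planted)
        tf = cg.coarse_align(pairs_for(cmap), cmap, rois)[None]
        assert tf.s2[0] * tf.s1 == pytest.approx(1.3, abs=0.02)
        assert tf.s2[1] * tf.s1 == pytest.approx(0.9, abs=0.02)

    def test_staged_fit_never_increases_discrepancy(self, cloud, rng):
        """Each stage (T, S1, R, S2) must not worsen the summed squared
        discrepancy on a realistic planted distortion with jitter."""
        planted = apply_planted(cloud, angle_deg=12.0, scale=1.1,
                                stretch=(1.15, 0.92), shift=(20.0, 5.0))
        planted += rng.normal(0, 0.5, planted.shape)
        cmap = map_from_points(cloud)
        rois = rois_from_points(planted)
        tf = cg.coarse_align(pairs_for(cmap), cmap, rois)[None]

        def ssd(points):
            return float(((points - planted) ** 2).sum())

        c0 = cloud + tf.t1
        r0 = planted - tf.t2
        stage_t = float(((c0 - r0) ** 2).sum())
        stage_s1 = float(((tf.s1 * c0 - r0) ** 2).sum())
        stage_r = float((((tf.s1 * c0) @ tf.r.T - r0) ** 2).sum())
        stage_s2 = float(((((tf.s1 * c0) @ tf.r.T) * tf.s2 - r0) ** 2).sum())
        assert stage_s1 <= stage_t + 1e-9
        assert stage_r <= stage_s1 + 1e-9
        assert stage_s2 <= stage_r + 1e-9

    def test_translation_equivariance(self, cloud):
        """Translating all ROIs changes T2 only; assignment unchanged."""
        cmap = map_from_points(cloud)
        base = apply_planted(cloud, angle_deg=5.0, scale=1.1)
        t1 = cg.coarse_align(pairs_for(cmap), cmap,
                             rois_from_points(base))[None]
        t2 = cg.coarse_align(pairs_for(cmap), cmap,
                             rois_from_points(base + [17.0, -4.0]))[None]
        assert np.allclose(t2.t2 - t1.t2, [17.0, -4.0], atol=1e-9)
        assert t2.s1 == pytest.approx(t1.s1, abs=1e-12)
        assert np.allclose(t2.r, t1.r, atol=1e-12)
        assert np.allclose(t2.t1, t1.t1, atol=1e-12)

    def test_too_few_or_collinear_pairs_rejected(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        cmap = map_from_points(pts)
        rois = rois_from_points(pts)
        with pytest.raises(cg.DegenerateInputError):
            cg.coarse_align(pairs_for(cmap), cmap, rois)

    def test_packet_fallback_to_whole_aspect(self, cloud):
        """Packets without enough anchors inherit the global transform."""
        cmap = sg.CanonicalMap([
            sg.Neuron(f"n{i}", "ventral", 1 + (i % 2), float(x), float(y),
                      3.0, None)
            for i, (x, y) in enumerate(cloud)])
        rois = rois_from_points(cloud)
        # confirm only packet-1 cells plus one packet-2 cell
        sel = [i for i in range(len(cloud)) if i % 2 == 0] + [1]
        pairs = pd.DataFrame({"roi_id": [f"r{i}" for i in sel],
                              "neuron_id": [f"n{i}" for i in sel]})
        tfs = cg.coarse_align(pairs, cmap, rois)
        assert 1 in tfs and 2 not in tfs and None in tfs


class TestFineAlign:
    def test_zero_residuals_zero_field(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        tfs = cg.coarse_align(pairs_for(cmap), cmap, rois)
        warp = cg.fine_align(pairs_for(cmap), cmap, rois, tfs)
        probe = np.array([[0.0, 0.0], [30.0, 10.0]])
        assert np.allclose(warp.delta(probe), 0.0, atol=1e-9)

    def test_single_anchor_kernel_closed_form(self, cloud):
        """One anchor with dX = 5: field is exactly 5 at the anchor and
        5 e^{-9/2} < 0.06 at distance 3 sigma."""
        cmap = map_from_points(cloud)
        shifted = cloud.copy()
        shifted[0] += [5.0, 0.0]
        rois = rois_from_points(shifted)
        tfs = {None: cg.PacketTransform(None, np.zeros(2), 1.0, np.eye(2),
                                        np.ones(2), np.zeros(2))}
        one_pair = pairs_for(cmap).iloc[:1]
        warp = cg.fine_align(one_pair, cmap, rois, tfs)
        anchor = shifted[0]
        assert warp.delta(anchor[None])[0][0] == pytest.approx(5.0, abs=1e-12)
        far = anchor + [3.0 * warp.sigmas[0], 0.0]
        expect = 5.0 * np.exp(-4.5)
        assert warp.delta(far[None])[0][0] == pytest.approx(expect, rel=1e-9)
        assert expect < 0.06

    def test_sigma_is_sqrt3_times_nearest_anchor_distance(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [40.0, 0.5], [0.0, 30.0]])
        cmap = map_from_points(pts)
        rois = rois_from_points(pts)
        tfs = cg.coarse_align(pairs_for(cmap), cmap, rois)
        warp = cg.fine_align(pairs_for(cmap), cmap, rois, tfs)
        d01 = 10.0
        assert warp.sigmas[0] == pytest.approx(np.sqrt(3) * d01)
        assert warp.sigmas[1] == pytest.approx(np.sqrt(3) * d01)

    def test_isolated_anchor_residual_reproduced_within_1pct(self, rng):
        """Anchors farther apart than 6 sigma reproduce their residuals.

        The kernel scale follows the local ROI spacing, so anchors chosen
        from a dense ROI cloud but far from *each other* act as isolated
        kernels.
        """
        # dense cloud: spacing ~10 px; three anchors >= 150 px apart
        grid = np.stack(np.meshgrid(np.arange(0, 310, 10.0),
                                    np.arange(0, 30, 10.0)), -1).reshape(-1, 2)
        cmap = map_from_points(grid)
        shifted = grid + rng.normal(0, 1.0, grid.shape)
        rois = rois_from_points(shifted)
        anchor_idx = [0, 30, 2 * 31 + 15]  # (0,0), (300,0), (150,20)
        apts = grid[anchor_idx]
        assert (np.sqrt(((apts[:, None] - apts[None]) ** 2).sum(-1))
                [~np.eye(3, dtype=bool)].min() > 6 * np.sqrt(3) * 11.0)
        pairs = pd.DataFrame({"roi_id": [f"r{i}" for i in anchor_idx],
                              "neuron_id": [f"n{i}" for i in anchor_idx]})
        tfs = {None: cg.PacketTransform(None, np.zeros(2), 1.0, np.eye(2),
                                        np.ones(2), np.zeros(2))}
        warp = cg.fine_align(pairs, cmap, rois, tfs)
        assert warp.sigmas.max() < np.sqrt(3) * 13.0
        got = warp.delta(warp.anchors_xy)
        assert np.allclose(got, warp.residuals, rtol=0.01, atol=1e-3)

    def test_coincident_anchors_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]])
        cmap = map_from_points(pts)
        rois = rois_from_points(pts)
        tfs = {None: cg.PacketTransform(None, np.zeros(2), 1.0, np.eye(2),
                                        np.ones(2), np.zeros(2))}
        with pytest.raises(cg.DegenerateInputError):
            cg.fine_align(pairs_for(cmap), cmap, rois, tfs)


class TestAutoAssign:
    def test_perfect_geometry_perfect_assignment(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        pairs = pairs_for(cmap).iloc[:4]
        asg = cg.register(cmap, rois, pairs)
        assert len(asg.pairs) == len(cloud)
        for _, row in asg.pairs.iterrows():
            assert row["roi_id"][1:] == row["neuron_id"][1:]
        assert not asg.unassigned_rois and not asg.unassigned_neurons

    def test_size_matched_neuron_wins_conflict(self):
        """Toy case checked against exhaustive cost minimization."""
        # n0 (big) and n1 (small) are both nearest to the small r0; the
        # size-matched small neuron n1 should take r0 and the big n0 its
        # size-matched second-nearest ROI r1
        n_pts = [(0.0, 0.0), (1.8, 0.0), (30.0, 0.0)]
        n_rad = [8.0, 3.0, 3.0]
        r_pts = [(1.0, 0.0), (-1.2, 0.0), (31.0, 0.0)]
        r_rad = [3.0, 8.0, 3.0]
        cmap = map_from_points(n_pts, n_rad)
        rois = rois_from_points(r_pts, r_rad)
        tfs = {None: cg.PacketTransform(None, np.zeros(2), 1.0, np.eye(2),
                                        np.ones(2), np.zeros(2))}
        asg = cg.auto_assign(cmap, rois, tfs, None)
        got = dict(zip(asg.pairs["neuron_id"], asg.pairs["roi_id"]))

        # exhaustive oracle over all one-to-one assignments
        med_nn = 2.2  # median nearest-neighbor distance of the ROI cloud
        lam = med_nn ** 2
        med_rad = float(np.median(n_rad))

        def cost(ni, ri):
            d = np.hypot(n_pts[ni][0] - r_pts[ri][0],
                         n_pts[ni][1] - r_pts[ri][1])
            return (d ** 2 * n_rad[ni] / med_rad
                    + lam * np.log(n_rad[ni] / r_rad[ri]) ** 2)

        best = min(itertools.permutations(range(3)),
                   key=lambda p: sum(cost(i, p[i]) for i in range(3)))
        for i in range(3):
            assert got[f"n{i}"] == f"r{best[i]}"
        assert got["n1"] == "r0"  # the size-matched small neuron wins
        assert got["n0"] == "r1"  # the big one takes its second-nearest

    def test_jittered_ganglion_identification_rate(self, rng):
        """Planted affine + warp + 1 px jitter, 10% of ROIs deleted:
        >= 90% of surviving cells identified; deleted cells reported."""
        pts = rng.uniform([-80, -30], [80, 30], size=(60, 2))
        radii = rng.uniform(2.5, 6.0, 60)
        cmap = map_from_points(pts, radii)
        distorted = apply_planted(pts, angle_deg=7.0, scale=1.15,
                                  stretch=(1.05, 0.95), shift=(12.0, -6.0))
        distorted += rng.normal(0, 1.0, distorted.shape)  # 1 px jitter
        keep = rng.permutation(60)[:54]  # delete 10%
        rois = ROISet([
            ROI(f"r{i}", "ventral",
                ellipse=(float(distorted[i, 0]), float(distorted[i, 1]),
                         float(radii[i]), float(radii[i]), 0.0))
            for i in keep])
        anchor_ids = keep[:6]
        pairs = pd.DataFrame({"roi_id": [f"r{i}" for i in anchor_ids],
                              "neuron_id": [f"n{i}" for i in anchor_ids]})
        asg = cg.register(cmap, rois, pairs)
        auto = asg.pairs[asg.pairs["provenance"] == "automatic"]
        correct = (auto["roi_id"].str[1:] == auto["neuron_id"].str[1:]).mean()
        assert correct >= 0.9
        deleted = {f"n{i}" for i in range(60)} - {f"n{i}" for i in keep}
        assert deleted <= set(asg.unassigned_neurons)

    def test_coarse_fine_reduce_distance_80pct(self, rng):
        """Registration shrinks mean canonical-to-ROI distance >= 80%
        versus the identity mapping."""
        pts = rng.uniform([-80, -30], [80, 30], size=(40, 2))
        cmap = map_from_points(pts)
        distorted = apply_planted(pts, angle_deg=9.0, scale=1.2,
                                  shift=(25.0, 10.0))
        distorted += rng.normal(0, 0.5, distorted.shape)
        rois = rois_from_points(distorted)
        pairs = pairs_for(cmap).iloc[:8]
        tfs = cg.coarse_align(pairs, cmap, rois)
        warp = cg.fine_align(pairs, cmap, rois, tfs)
        mapped = np.array([
            tfs[None].apply([(n.x, n.y)])[0] for n in cmap.neurons])
        mapped += warp.delta(mapped)
        d_before = np.linalg.norm(pts - distorted, axis=1).mean()
        d_after = np.linalg.norm(mapped - distorted, axis=1).mean()
        assert d_after < 0.2 * d_before

    def test_user_pairs_preserved_verbatim(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        # deliberately wrong user pair: must survive auto-assignment
        pairs = pd.DataFrame({"roi_id": ["r0", "r1", "r2", "r3"],
                              "neuron_id": ["n1", "n0", "n2", "n3"]})
        asg = cg.register(cmap, rois, pairs)
        got = asg.as_dict()
        assert got["r0"] == "n1" and got["r1"] == "n0"
        prov = asg.pairs.set_index("roi_id")["provenance"]
        assert prov["r0"] == "user"

    @given(st.integers(5, 30), st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_assignment_always_injective(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform([-50, -20], [50, 20], size=(n, 2))
        if np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
            return
        cmap = map_from_points(pts, rng.uniform(2, 6, n))
        rois = rois_from_points(pts + rng.normal(0, 2.0, pts.shape),
                                rng.uniform(2, 6, n))
        pairs = pairs_for(cmap).iloc[:3]
        try:
            asg = cg.register(cmap, rois, pairs)
        except cg.DegenerateInputError:
            return
        assert asg.pairs["roi_id"].is_unique
        assert asg.pairs["neuron_id"].is_unique


class TestIterateRegistration:
    def test_fixed_point_on_perfect_data(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        asg = cg.iterate_registration(cmap, rois, pairs_for(cmap).iloc[:4])
        assert len(asg.pairs) == len(cloud)

    def test_extra_confirmations_do_not_reduce_accuracy(self, rng):
        pts = rng.uniform([-80, -30], [80, 30], size=(40, 2))
        cmap = map_from_points(pts)
        distorted = apply_planted(pts, angle_deg=6.0, scale=1.1)
        distorted += rng.normal(0, 1.0, distorted.shape)
        rois = rois_from_points(distorted)

        def accuracy(asg):
            # all identified cells, user-confirmed ones included
            p = asg.pairs
            return (p["roi_id"].str[1:] == p["neuron_id"].str[1:]).sum() / 40

        base = cg.register(cmap, rois, pairs_for(cmap).iloc[:4])

        def confirm(asg):
            # confirm five known-correct additional pairs, as a user would
            return pairs_for(cmap).iloc[4:9]

        refined = cg.iterate_registration(cmap, rois,
                                          pairs_for(cmap).iloc[:4], confirm)
        assert accuracy(refined) >= accuracy(base) - 1e-9

    def test_contradictory_pairs_rejected(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        bad = pd.DataFrame({"roi_id": ["r0", "r0", "r1"],
                            "neuron_id": ["n0", "n1", "n2"]})
        with pytest.raises(ValueError):
            cg.register(cmap, rois, bad)


class TestEstimatorInterface:
    def test_fit_predict(self, cloud):
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        reg = cg.CanonicalRegistration(canonical=cmap)
        reg.fit(rois, pairs_for(cmap).iloc[:4])
        pos = reg.predict([n.id for n in cmap.neurons])
        assert np.allclose(pos, cloud, atol=1e-6)
        assert hasattr(reg, "assignment_")

    def test_plot_overlay_runs(self, cloud, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        cmap = map_from_points(cloud)
        rois = rois_from_points(cloud)
        reg = cg.CanonicalRegistration(canonical=cmap)
        reg.fit(rois, pairs_for(cmap).iloc[:4])
        ax = cg.plot_overlay(cmap, rois, reg.assignment_)
        ax.figure.savefig(tmp_path / "overlay.png")
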