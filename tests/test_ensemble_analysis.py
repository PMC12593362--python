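"""Gyration metrics, Flory fits, contact maps, affinity kernel, clustering."""

import numpy as np
import pytest

from synsplice import ensemble_analysis as ea
from synsplice import synthetic_data as sd


def rod(n=30, spacing=0.38):
    f = np.zeros((1, n, 3))
    f[0, :, 0] = spacing * np.arange(n)
    return f


def cube_corners():
    pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                   float)
    return pts[None]


def random_rigid_motion(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y*y + z*z), 2 * (x*y - w*z), 2 * (x*z + w*y)],
        [2 * (x*y + w*z), 1 - 2 * (x*x + z*z), 2 * (y*z - w*x)],
        [2 * (x*z - w*y), 2 * (y*z + w*x), 1 - 2 * (x*x + y*y)]])
    return rot, rng.standard_normal(3) * 5


class TestGyrationMetrics:
    def test_rod_limit(self):
        m = ea.gyration_metrics(rod())
        assert m.asphericity == pytest.approx(1.0, abs=1e-12)
        assert m.prolateness == pytest.approx(2.0, abs=1e-12)

    def test_isotropic_limit(self):
        m = ea.gyration_metrics(cube_corners())
        assert m.asphericity == pytest.approx(0.0, abs=1e-12)
        assert m.prolateness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_chain_asphericity(self):
        frames, _, _ = sd.gen_toy_ensemble(140, 2000, "ideal", seed=5)
        m = ea.gyration_metrics(frames)
        assert 0.50 <= m.asphericity <= 0.56

    def test_matches_per_frame_eigen_oracle(self, rng):
        frames = rng.standard_normal((5, 25, 3))
        m = ea.gyration_metrics(frames)
        # brute-force eigen-decomposition per frame
        num2 = den2 = num3 = den3 = 0.0
        rgs = []
        for f in frames:
            c = f - f.mean(0)
            t = (c.T @ c) / len(f)
            lam = np.sort(np.linalg.eigvalsh(t))
            dev = lam - lam.mean()
            rgs.append(np.sqrt(lam.sum()))
            num2 += (dev**2).sum(); den2 += lam.sum()**2
            num3 += dev.prod(); den3 += lam.sum()**3
        assert m.rg_mean == pytest.approx(np.mean(rgs), rel=1e-12)
        assert m.asphericity == pytest.approx(1.5 * num2 / den2, rel=1e-12)
        assert m.prolateness == pytest.approx(27.0 * num3 / den3, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        frames, _, _ = sd.gen_toy_ensemble(40, 20, "ideal", seed=1)
        moved = frames.copy()
        for i in range(len(moved)):
            rot, shift = random_rigid_motion(rng)
            moved[i] = moved[i] @ rot.T + shift
        m0, m1 = ea.gyration_metrics(frames), ea.gyration_metrics(moved)
        assert m1.rg_mean == pytest.approx(m0.rg_mean, rel=1e-9)
        assert m1.asphericity == pytest.approx(m0.asphericity, rel=1e-9)
        assert m1.prolateness == pytest.approx(m0.prolateness, rel=1e-9)

    def test_degenerate_frame_rejected(self):
        with pytest.raises(ValueError):
            ea.gyration_metrics(np.zeros((1, 10, 3)))


class TestFloryExponent:
    def test_ideal_chain(self):
        frames, _, _ = sd.gen_toy_ensemble(140, 1500, "ideal", seed=2)
        nu, err, r0 = ea.flory_exponent(frames)
        assert nu == pytest.approx(0.50, abs=0.02)

    def test_rod(self):
        nu, err, r0 = ea.flory_exponent(np.repeat(rod(60), 2, axis=0))
        assert nu == pytest.approx(1.0, abs=1e-6)

    def test_compact_ensemble_below_half(self):
        frames, _, _ = sd.gen_toy_ensemble(100, 300, "nc_tethered_mixture",
                                           mixture_weight=1.0, seed=3)
        nu, _, _ = ea.flory_exponent(frames)
        assert nu < 0.5

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            ea.flory_exponent(np.zeros((2, 15, 3)) + np.arange(15)[None, :,
                                                                  None])


class TestContactMap:
    def test_all_close_single_frame(self):
        f = 0.1 * np.random.default_rng(0).standard_normal((1, 10, 3))
        cm = ea.contact_map(f, threshold=2.0)
        i, j = np.triu_indices(10, k=2)
        assert np.all(cm.matrix[i, j] == 1.0)

    def test_rod_geometry(self):
        cm = ea.contact_map(rod(30, 0.38), threshold=2.0)
        for i, j in [(0, 5), (0, 6), (10, 15), (10, 16)]:
            expected = 1.0 if 0.38 * (j - i) <= 2.0 else 0.0
            assert cm.matrix[i, j] == expected

    def test_half_occupancy(self):
        a = rod(10, 0.38)
        b = rod(10, 1.5)
        cm = ea.contact_map(np.concatenate([a, b]), threshold=2.0)
        assert cm.matrix[0, 4] == 0.5   # 4*0.38 <= 2 but 4*1.5 > 2

    def test_bonded_masked(self):
        cm = ea.contact_map(rod(10))
        assert np.isnan(cm.matrix[3, 3]) and np.isnan(cm.matrix[3, 4])


class TestAffinity:
    def test_identical_frames_unit_affinity(self):
        base, _, _ = sd.gen_toy_ensemble(30, 3, "ideal", seed=4)
        frames = np.concatenate([base, base[:1]])
        a = ea.affinity_matrix(frames)
        assert a[0, 3] == pytest.approx(1.0)
        assert np.all(np.diag(a) == 1.0)
        assert np.all((a > 0) & (a <= 1))
        assert np.allclose(a, a.T)

    def test_two_frame_hand_oracle(self):
        frames, _, _ = sd.gen_toy_ensemble(25, 2, "ideal", seed=6)
        a = ea.affinity_matrix(frames)
        # scalar hand computation over nonbonded pairs i > j+1
        n = frames.shape[1]
        num = []
        var = []
        for j in range(n):
            for i in range(j + 2, n):
                d = [np.linalg.norm(frames[f, i] - frames[f, j])
                     for f in range(2)]
                num.append((d[0] - d[1]) ** 2)
                var.append(np.var(d))
        expected = np.exp(-np.mean(num) / (2 * np.mean(var)))
        assert a[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_iid_normalisation_identity(self):
        """For i.i.d. frames the numerator expectation equals the
        denominator, so mean off-diagonal −ln A ≈ 1."""
        frames, _, _ = sd.gen_toy_ensemble(60, 400, "ideal", seed=7)
        a = ea.affinity_matrix(frames)
        off = ~np.eye(len(a), dtype=bool)
        assert np.mean(-np.log(a[off])) == pytest.approx(1.0, abs=0.1)

    def test_rigid_motion_invariance(self, rng):
        frames, _, _ = sd.gen_toy_ensemble(30, 10, "ideal", seed=8)
        moved = frames.copy()
        for i in range(len(moved)):
            rot, shift = random_rigid_motion(rng)
            moved[i] = moved[i] @ rot.T + shift
        assert np.allclose(ea.affinity_matrix(frames),
                           ea.affinity_matrix(moved), atol=1e-9)

    def test_static_ensemble_rejected(self):
        frames = np.repeat(rod(20), 5, axis=0)
        with pytest.raises(ValueError):
            ea.affinity_matrix(frames)


class TestClustering:
    def test_planted_partition_populations(self):
        frames, labels, _ = sd.gen_toy_ensemble(
            60, 300, "nc_tethered_mixture", mixture_weight=0.6, seed=9)
        res = ea.cluster_conformers(ea.affinity_matrix(frames), frames, k=2,
                                    seed=0)
        assert abs(res.populations[0] - 60.0) <= 5.0
        assert res.populations.sum() == pytest.approx(100.0, abs=1e-9)

    def test_class_one_is_most_compact(self):
        frames, labels, _ = sd.gen_toy_ensemble(
            60, 200, "nc_tethered_mixture", mixture_weight=0.5, seed=10)
        res = ea.cluster_conformers(ea.affinity_matrix(frames), frames, k=2,
                                    seed=0)
        m = ea.gyration_metrics(frames)
        rg1 = m.rg_frames[res.labels == 1].mean()
        rg2 = m.rg_frames[res.labels == 2].mean()
        assert rg1 < rg2

    def test_permutation_equivariance(self):
        frames, _, _ = sd.gen_toy_ensemble(
            40, 120, "nc_tethered_mixture", mixture_weight=0.5, seed=11)
        aff = ea.affinity_matrix(frames)
        res = ea.cluster_conformers(aff, frames, k=2, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(frames))
        res_p = ea.cluster_conformers(aff[np.ix_(perm, perm)], frames[perm],
                                      k=2, seed=0)
        assert np.array_equal(res.labels[perm], res_p.labels)

    def test_repeatability_at_fixed_seed(self):
        frames, _, _ = sd.gen_toy_ensemble(
            40, 150, "nc_tethered_mixture", seed=12)
        aff = ea.affinity_matrix(frames)
        r1 = ea.cluster_conformers(aff, frames, k=3, seed=42)
        r2 = ea.cluster_conformers(aff, frames, k=3, seed=42)
        assert np.array_equal(r1.labels, r2.labels)

    def test_report_carries_caveat(self):
        frames, _, _ = sd.gen_toy_ensemble(
            40, 100, "nc_tethered_mixture", seed=13)
        res = ea.cluster_conformers(ea.affinity_matrix(frames), frames, k=2,
                                    seed=0)
        rep = ea.cluster_report(res)
        assert "spectrum of conformations" in rep["caveat"]


def test_ca_pdb_written_for_viewers(tmp_path):
    """The Cα-only PDB export is readable by an independent parser and
    preserves coordinates (nm → Å) and residue identities."""
    import biotite.structure.io.pdb as pdb
    rng = np.random.default_rng(0)
    frame = rng.standard_normal((20, 3))
    path = tmp_path / "rep.pdb"
    ea.write_ca_pdb(frame, path, "ACDEFGHIKLMNPQRSTVWY")
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    assert len(arr) == 20
    assert np.allclose(arr.coord, frame * 10.0, atol=1e-3)
    assert list(arr.res_name[:3]) == ["ALA", "CYS", "ASP"]


class TestRepresentativeFrame:
    def test_singleton_class(self):
        aff = np.eye(3)
        labels = np.array([1, 2, 2])
        assert ea.representative_frame(aff, labels, 1) == 0

    def test_centroid_frame_selected(self):
        # frame 1 is the pairwise centroid: highest mean affinity to others
        aff = np.array([[1.0, 0.9, 0.2],
                        [0.9, 1.0, 0.8],
                        [0.2, 0.8, 1.0]])
        labels = np.ones(3, dtype=int)
        assert ea.representative_frame(aff, labels, 1) == 1

    def test_tie_breaks_to_lowest_index(self):
        aff = np.full((4, 4), 0.5)
        np.fill_diagonal(aff, 1.0)
        labels = np.ones(4, dtype=int)
        assert ea.representative_frame(aff, labels, 1) == 0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ea.representative_frame(np.eye(2), np.array([1, 1]), 2)
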