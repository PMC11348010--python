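import numpy as np
import pytest

from capgen import probe as pb
from capgen.errors import ConvergenceError, FormatError, ValidationError
from capgen.probe import Anchor, Optode, ProbeDesign, Spring


def minimal_probe():
    return ProbeDesign([Optode([0.0, 0.0, 100.0])], anchors=[Anchor(0, "Cz")])


class TestJSON:
    def test_minimal(self, tmp_path):
        p = minimal_probe()
        path = tmp_path / "p.json"
        pb.write_probe_json(p, path)
        p2 = pb.read_probe_design(path)
        assert len(p2.optodes) == 1
        assert len(p2.springs) == 0
        assert p2.anchors[0].landmark == "Cz"

    def test_roundtrip_identity(self, tmp_path):
        p = ProbeDesign(
            [Optode([0, 0, 100], "source", "#A1", 30.0),
             Optode([30, 0, 100], "detector", "#B2", 0.0),
             Optode([15, 26, 100], "dummy")],
            springs=[Spring(0, 1, 30.0), Spring(1, 2, pb.FLEX)],
            anchors=[Anchor(2, "Cz")],
            measurements=[(0, 1)])
        path = tmp_path / "p.json"
        pb.write_probe_json(p, path)
        assert pb.read_probe_design(path) == p

    def test_missing_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"springs": []}')
        with pytest.raises(FormatError):
            pb.read_probe_design(path)


class TestSDMat:
    def _write_sd(self, path, spring_len=30.0):
        from scipy.io import savemat

        sd = {
            "SrcPos": np.array([[0.0, 0, 100], [30, 0, 100]]),
            "DetPos": np.array([[15.0, 26, 100]]),
            "DummyPos": np.array([[45.0, 26, 100]]),
            "SpringList": np.array([[1, 3, spring_len], [2, 3, -1.0]]),
            "AnchorList": np.array([[4, "Cz"]], dtype=object),
            "SrcGrommetType": np.array(["#NIRX2", "#NIRX2"], dtype=object),
            "DetGrommetType": np.array(["#EEG"], dtype=object),
            "DummyGrommetType": np.array(["#STD"], dtype=object),
            "SrcGrommetRot": np.array([0.0, 90.0]),
            "MeasList": np.array([[1, 1, 1, 1], [2, 1, 1, 1]]),
        }
        savemat(path, {"SD": sd})

    def test_read_sd(self, tmp_path):
        path = tmp_path / "probe.SD"
        self._write_sd(path)
        p = pb.read_probe_design(path, format="sd-mat")
        assert [o.kind for o in p.optodes] == ["source", "source", "detector", "dummy"]
        assert p.optodes[0].grommet_id == "#NIRX2"
        assert p.optodes[2].grommet_id == "#EEG"
        assert p.optodes[1].rotation == 90.0
        # 1-based MAT indices -> 0-based
        assert (p.springs[0].i, p.springs[0].j) == (0, 2)
        assert p.springs[0].rest_length == 30.0
        assert p.anchors[0] == Anchor(3, "Cz")
        assert p.measurements == [(0, 2), (1, 2)]

    def test_negative_length_is_flex(self, tmp_path):
        path = tmp_path / "probe.SD"
        self._write_sd(path)
        p = pb.read_probe_design(path, format="sd-mat")
        assert p.springs[1].rest_length is pb.FLEX
        assert not p.springs[1].rigid


class TestValidation:
    def test_dangling_spring_index(self):
        p = ProbeDesign([Optode([0, 0, 0]) for _ in range(5)],
                        springs=[Spring(0, 99, 30.0)], anchors=[Anchor(0, "Cz")])
        rep = pb.validate_probe(p)
        assert any(v["code"] == "dangling-index" for v in rep["violations"])

    def test_unreachable_cluster(self):
        p = ProbeDesign([Optode([i * 10, 0, 0]) for i in range(4)],
                        springs=[Spring(0, 1, 10.0), Spring(2, 3, 10.0)],
                        anchors=[Anchor(0, "Cz")])
        rep = pb.validate_probe(p)
        assert any(v["code"] == "unreachable-from-anchor" for v in rep["violations"])

    def test_duplicate_anchor(self):
        p = ProbeDesign([Optode([0, 0, 0])],
                        anchors=[Anchor(0, "Cz"), Anchor(0, "Pz")])
        rep = pb.validate_probe(p)
        assert any(v["code"] == "duplicate-anchor" for v in rep["violations"])

    def test_unknown_landmark(self, sphere_landmarks):
        p = ProbeDesign([Optode([0, 0, 0])], anchors=[Anchor(0, "XX99")])
        rep = pb.validate_probe(p, sphere_landmarks)
        assert any(v["code"] == "unknown-landmark" for v in rep["violations"])

    def test_valid_probe_empty_report(self, sphere_landmarks):
        from capgen.fixtures import default_probe

        rep = pb.validate_probe(default_probe(), sphere_landmarks)
        assert rep["valid"]
        assert rep["violations"] == []


class TestRegistration:
    def test_anchored_dummy_exact(self, sphere_head, sphere_landmarks):
        res = pb.register_probe(minimal_probe(), sphere_head, sphere_landmarks)
        # bit-identical to the landmark coordinates
        assert np.array_equal(res.positions[0], sphere_landmarks.point("Cz"))

    def test_rigid_pair_on_sphere(self, sphere_head, sphere_landmarks):
        p = ProbeDesign([Optode([0, 0, 100]), Optode([30, 0, 100])],
                        springs=[Spring(0, 1, 30.0)], anchors=[Anchor(0, "Cz")])
        res = pb.register_probe(p, sphere_head, sphere_landmarks)
        sep = np.linalg.norm(res.positions[1] - res.positions[0])
        assert abs(sep - 30.0) <= 0.5
        dist = sphere_head.mesh.closest_point(res.positions[1])[1][0]
        assert dist < 0.1

    def test_triangle_vs_bruteforce_oracle(self, sphere_head, sphere_landmarks,
                                           sphere_radius):
        p = ProbeDesign(
            [Optode([0, 0, 100]), Optode([30, 0, 100]), Optode([15, 26, 100])],
            springs=[Spring(0, 1, 30.0), Spring(1, 2, 30.0), Spring(0, 2, 30.0)],
            anchors=[Anchor(0, "Cz")])
        res = pb.register_probe(p, sphere_head, sphere_landmarks)
        X = res.positions
        for a, b in ((0, 1), (1, 2), (0, 2)):
            assert abs(np.linalg.norm(X[a] - X[b]) - 30.0) <= 0.5

        # independent oracle: constrained minimization on the exact sphere
        from scipy.optimize import minimize

        r = sphere_radius
        cz = sphere_landmarks.point("Cz")

        def sph(t, f):
            return r * np.array([np.sin(t) * np.cos(f), np.sin(t) * np.sin(f),
                                 np.cos(t)])

        def cost(v):
            p1, p2 = sph(v[0], v[1]), sph(v[2], v[3])
            return ((np.linalg.norm(p1 - cz) - 30) ** 2
                    + (np.linalg.norm(p2 - cz) - 30) ** 2
                    + (np.linalg.norm(p1 - p2) - 30) ** 2)

        best = minimize(cost, [0.3, 0.0, 0.3, 1.0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        p1, p2 = sph(best.x[0], best.x[1]), sph(best.x[2], best.x[3])
        for a, b in ((cz, p1), (cz, p2), (p1, p2)):
            assert abs(np.linalg.norm(a - b) - 30.0) <= 0.5

    def test_permutation_invariance(self, sphere_head, sphere_landmarks):
        p = ProbeDesign(
            [Optode([0, 0, 100]), Optode([30, 0, 100]), Optode([15, 26, 100])],
            springs=[Spring(0, 1, 30.0), Spring(1, 2, 30.0), Spring(0, 2, 30.0)],
            anchors=[Anchor(0, "Cz")])
        perm = ProbeDesign(
            [Optode([15, 26, 100]), Optode([0, 0, 100]), Optode([30, 0, 100])],
            springs=[Spring(1, 2, 30.0), Spring(2, 0, 30.0), Spring(1, 0, 30.0)],
            anchors=[Anchor(1, "Cz")])
        r1 = pb.register_probe(p, sphere_head, sphere_landmarks)
        r2 = pb.register_probe(perm, sphere_head, sphere_landmarks)
        assert np.allclose(r1.positions[[0, 1, 2]], r2.positions[[1, 2, 0]], atol=1e-9)

    def test_residual_decreases(self, sphere_head, sphere_landmarks):
        p = ProbeDesign([Optode([0, 0, 100]), Optode([30, 0, 100])],
                        springs=[Spring(0, 1, 30.0)], anchors=[Anchor(0, "Cz")])
        res = pb.register_probe(p, sphere_head, sphere_landmarks)
        h = res.residual_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_default_probe_residual_trend(self, pipeline_stage):
        h = pipeline_stage["registration"].residual_history
        running_min = np.minimum.accumulate(h)
        assert running_min[-1] < 0.02 * h[0]
        assert pipeline_stage["registration"].max_spring_error < 0.5

    def test_invalid_probe_raises(self, sphere_head, sphere_landmarks):
        p = ProbeDesign([Optode([0, 0, 0])], anchors=[])
        with pytest.raises(ValidationError):
            pb.register_probe(p, sphere_head, sphere_landmarks)

    def test_infeasible_spring_reported(self, sphere_head, sphere_landmarks,
                                        sphere_radius):
        # rest length far beyond the head diameter cannot be satisfied
        p = ProbeDesign([Optode([0, 0, 100]), Optode([30, 0, 100])],
                        springs=[Spring(0, 1, 4 * sphere_radius)],
                        anchors=[Anchor(0, "Cz")])
        try:
            res = pb.register_probe(p, sphere_head, sphere_landmarks)
            assert res.max_spring_error > 1.0    # reported, not silently absorbed
        except ConvergenceError as e:
            assert e.residuals                    # or an explicit failure
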