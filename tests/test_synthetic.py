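import numpy as np
import pytest

from alfkrig.geometry import ALFFeaturizer, infer_bonds
from alfkrig.kriging import KrigingRegressor, PSOConfig
from alfkrig.synthetic import (
    DistortionSpec,
    SurfaceSpec,
    build_template,
    central_fragment,
    distort,
    evaluate_surface,
    make_paired_systems,
)


def all_bonds_and_angles(g, bonds):
    coords = g.coords
    lengths = {}
    for e in bonds.edges:
        i, j = tuple(e)
        lengths[(i, j)] = np.linalg.norm(coords[i] - coords[j])
    angles = {}
    for j in range(g.n_atoms):
        nbrs = bonds.neighbors(j)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angles[(i, j, k)] = np.arccos(np.clip(c, -1, 1))
    return lengths, angles


class TestTemplates:
    @pytest.mark.parametrize("name,n_atoms", [
        ("ALA", 22), ("AAA", 42), ("GAG", 36), ("VAV", 54)])
    def test_atom_counts_and_connectivity(self, name, n_atoms):
        g, bonds = build_template(name)
        assert g.n_atoms == n_atoms
        assert len(bonds.edges) == n_atoms - 1  # acyclic chain

    def test_central_fragment_is_the_10_atom_alanine_unit(self):
        frag = central_fragment("AAA")
        g, _ = build_template("AAA")
        assert len(frag) == 10
        assert sorted(g.elements[i] for i in frag) == sorted(
            ["N", "H", "C", "H", "C", "H", "H", "H", "C", "O"])

    def test_unknown_template(self):
        with pytest.raises(ValueError, match="unknown template"):
            build_template("AXA")


class TestDistortion:
    def test_bounds_hold_on_every_frame(self, aaa, aaa_frames):
        """Independent recomputation: no bond or angle beyond +/-15%."""
        g, bonds = aaa
        L0, A0 = all_bonds_and_angles(g, bonds)
        worst_bond = worst_angle = 0.0
        for frame in aaa_frames:
            L, A = all_bonds_and_angles(frame, bonds)
            for k, v in L.items():
                worst_bond = max(worst_bond, abs(v - L0[k]) / L0[k])
            for k, v in A.items():
                worst_angle = max(worst_angle, abs(v - A0[k]) / A0[k])
        assert worst_bond <= 0.15 + 1e-9
        assert worst_angle <= 0.15 + 1e-9
        # the draws genuinely explore the allowed band
        assert worst_bond > 0.10

    def test_connectivity_preserved(self, aaa, aaa_frames):
        _, bonds = aaa
        for frame in aaa_frames[:10]:
            assert infer_bonds(frame).edges == bonds.edges

    def test_zero_distortion_limit(self, aaa):
        g, bonds = aaa
        spec = DistortionSpec(max_bond_frac=1e-6, max_angle_frac=1e-6,
                              max_dihedral_deg=0.0, n_frames=3, seed=0)
        for frame in distort(g, bonds, spec):
            # rebuilt in a new global frame: compare internal geometry
            L0, A0 = all_bonds_and_angles(g, bonds)
            L, A = all_bonds_and_angles(frame, bonds)
            for k in L0:
                assert L[k] == pytest.approx(L0[k], abs=1e-5)

    def test_seed_determinism(self, aaa):
        g, bonds = aaa
        spec = DistortionSpec(n_frames=4, seed=77)
        f1 = distort(g, bonds, spec)
        f2 = distort(g, bonds, spec)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            DistortionSpec(max_bond_frac=0.7)
        with pytest.raises(ValueError):
            DistortionSpec(n_frames=0)


class TestPairedSystems:
    @pytest.fixture(scope="class")
    def family(self):
        return make_paired_systems(
            "A", [("G", "G"), ("G", "A"), ("A", "A"), ("V", "A"), ("V", "V")],
            DistortionSpec(n_frames=8, seed=5))

    def test_family_layout(self, family):
        frames, frags = family
        assert set(frames) == {"GAG", "GAA", "AAA", "VAA", "VAV"}
        assert all(len(v) == 8 for v in frames.values())
        assert all(len(f) == 10 for f in frags.values())

    def test_fragment_features_shared_per_frame(self, family):
        frames, frags = family
        feats = {}
        for s in frames:
            feat = ALFFeaturizer(origin_atom=frags[s][2], fragment=frags[s])
            feats[s] = feat.fit(frames[s]).transform(frames[s])
        ref = feats["AAA"]
        for s, X in feats.items():
            np.testing.assert_allclose(X, ref, atol=1e-8, err_msg=s)

    def test_single_system_still_respects_bounds(self):
        frames, frags = make_paired_systems(
            "A", [("A", "A")], DistortionSpec(n_frames=3, seed=2))
        g, bonds = build_template("AAA")
        L0, A0 = all_bonds_and_angles(g, bonds)
        for frame in frames["AAA"]:
            L, _ = all_bonds_and_angles(frame, bonds)
            for k, v in L.items():
                assert abs(v - L0[k]) / L0[k] <= 0.15 + 1e-9


class TestSurfaces:
    def test_linear_zero_weights_is_constant(self):
        spec = SurfaceSpec("linear", {"intercept": 0.4,
                                      "weights": np.zeros(3)})
        truth, obs = evaluate_surface(np.random.default_rng(0)
                                      .normal(size=(10, 3)), spec)
        np.testing.assert_allclose(truth, 0.4)
        np.testing.assert_array_equal(truth, obs)

    def test_noise_separated_from_truth(self):
        spec = SurfaceSpec("gaussian-bump",
                           {"base": 0.5, "amplitude": 0.1,
                            "center": np.zeros(2), "width": 1.0},
                           noise_sd=0.01, seed=4)
        X = np.random.default_rng(1).normal(size=(50, 2))
        truth, obs = evaluate_surface(X, spec)
        assert not np.array_equal(truth, obs)
        assert np.abs(obs - truth).std() == pytest.approx(0.01, rel=0.5)
        # same spec, same noise
        _, obs2 = evaluate_surface(X, spec)
        np.testing.assert_array_equal(obs, obs2)

    def test_dimension_mismatch(self):
        spec = SurfaceSpec("linear", {"intercept": 0.0,
                                      "weights": np.zeros(3)})
        with pytest.raises(ValueError, match="features"):
            evaluate_surface(np.zeros((2, 4)), spec)

    def test_unknown_form(self):
        with pytest.raises(ValueError):
            SurfaceSpec("quadratic")


class TestOffsetTransfer:
    def test_mu_fix_recovers_a_constant_offset_across_systems(self):
        """Train on one system's surface, predict a shifted sibling."""
        frames, frags = make_paired_systems(
            "A", [("A", "A"), ("V", "V")], DistortionSpec(n_frames=60, seed=9))
        Xs = {}
        for s in frames:
            feat = ALFFeaturizer(origin_atom=frags[s][2], fragment=frags[s])
            Xs[s] = feat.fit(frames[s]).transform(frames[s])
        spec = SurfaceSpec.from_features("gaussian-bump", Xs["AAA"], seed=9)
        y_aaa, _ = evaluate_surface(Xs["AAA"], spec)
        offset = 0.03
        y_vav = evaluate_surface(Xs["VAV"], spec)[0] + offset
        model = KrigingRegressor(
            pso=PSOConfig(seed=1, n_particles=10, n_iterations_max=15)
        ).fit(Xs["AAA"], y_aaa)
        err_raw = np.abs(model.predict(Xs["VAV"]) - y_vav).mean()
        fixed = model.mu_fix(model.mu_ + offset)
        err_fix = np.abs(fixed.predict(Xs["VAV"]) - y_vav).mean()
        assert err_fix < err_raw
        # the fragment geometry is shared, so the fix removes the offset
        # essentially exactly
        assert err_fix < 1e-4
        assert err_raw == pytest.approx(offset, rel=0.05)
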