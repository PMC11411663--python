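import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fodm.orientation import GaussianSigmas, orient, sigmas
from fodm.profiles import (DegenerateProfileError, Profile, levitt_g,
                           normalize, observed_profile, theoretical_profile,
                           uniform_profile)
from fodm.scales import kyte_doolittle_normalized


def observed_oracle(coords, h, cutoff):
    """Independent double-loop evaluation of the observed raw profile."""
    n = len(coords)
    raw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            if r <= cutoff:
                x = r / cutoff
                g = 1 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)
                raw[i] += (h[i] + h[j]) * g
    return raw / raw.sum()


class TestLevittG:
    def test_polynomial_identities(self):
        assert levitt_g(0.0) == 1.0
        assert np.isclose(levitt_g(1.0), 0.0)

    def test_zero_beyond_cutoff(self):
        assert levitt_g(1.5) == 0.0

    def test_monotone_decreasing_on_unit_interval(self):
        x = np.linspace(0, 1, 200)
        g = levitt_g(x)
        assert np.all(np.diff(g) <= 1e-12)


class TestTheoreticalProfile:
    def test_symmetric_pair_splits_evenly(self, make_eas):
        out = orient(make_eas([[4.0, 0, 0], [-4.0, 0, 0]]))
        t = theoretical_profile(out, GaussianSigmas(2.0, 2.0, 2.0))
        assert np.allclose(t.values, [0.5, 0.5])

    def test_one_sigma_ratio(self, make_eas):
        # points at x = 0 and x = sigma_x: raw ratio exp(-1/2)
        out = orient(make_eas([[0.0, 0, 0], [3.0, 0, 0], [-3.0, 0, 0]]))
        s = GaussianSigmas(3.0, 1.0, 1.0)
        t = theoretical_profile(out, s)
        assert np.isclose(t.values[1] / t.values[0], np.exp(-0.5))

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_direct_evaluation(self, random_cloud, make_eas, seed):
        out = orient(make_eas(random_cloud(seed=seed, n=30)))
        s = sigmas(out)
        t = theoretical_profile(out, s)
        sig = np.array([s.sigma_x, s.sigma_y, s.sigma_z])
        raw = np.array([np.exp(-(c**2 / (2 * sig**2)).sum()) for c in out.coords])
        assert np.allclose(t.values, raw / raw.sum(), atol=1e-14)

    def test_maximized_nearest_origin(self, random_cloud, make_eas):
        out = orient(make_eas(random_cloud(seed=9, n=30)))
        s = sigmas(out)
        t = theoretical_profile(out, s)
        sig = np.array([s.sigma_x, s.sigma_y, s.sigma_z])
        scaled = np.linalg.norm(out.coords / sig, axis=1)
        assert np.argmax(t.values) == np.argmin(scaled)


class TestObservedProfile:
    def test_beyond_cutoff_degenerate(self, make_eas):
        eas = make_eas([[0.0, 0, 0], [10.0, 0, 0]])
        with pytest.raises(DegenerateProfileError):
            observed_profile(eas, np.array([1.0, 1.0]), cutoff_c=9.0)

    def test_three_residue_line_hand_sum(self, make_eas):
        # unit hydrophobicity, spacing 4 A, cutoff 9: ends interact with
        # middle at 4 A and with each other at 8 A
        eas = make_eas([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        h = np.ones(3)
        g4 = float(levitt_g(4 / 9))
        g8 = float(levitt_g(8 / 9))
        expected = np.array([2 * g4 + 2 * g8, 4 * g4, 2 * g4 + 2 * g8])
        o = observed_profile(eas, h)
        assert np.allclose(o.values, expected / expected.sum(), atol=1e-15)

    @pytest.mark.parametrize("seed,n", [(0, 12), (5, 20)])
    def test_matches_double_loop_oracle(self, random_cloud, make_eas, seed, n):
        coords = random_cloud(seed=seed, n=n, scale=5.0)
        rng = np.random.default_rng(seed + 100)
        h = rng.random(n)
        o = observed_profile(make_eas(coords), h)
        assert np.allclose(o.values, observed_oracle(coords, h, 9.0), atol=1e-12)

    def test_rigid_motion_invariant(self, random_cloud, make_eas):
        coords = random_cloud(seed=3, n=20, scale=5.0)
        h = np.linspace(0.1, 1.0, 20)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1]])
        moved = coords @ rot.T + np.array([10.0, -4.0, 2.0])
        o1 = observed_profile(make_eas(coords), h)
        o2 = observed_profile(make_eas(moved), h)
        assert np.allclose(o1.values, o2.values, atol=1e-12)

    def test_scale_doubling_cancels(self, random_cloud, make_eas):
        coords = random_cloud(seed=8, n=15, scale=5.0)
        h = np.linspace(0.2, 1.0, 15)
        o1 = observed_profile(make_eas(coords), h)
        o2 = observed_profile(make_eas(coords), 2 * h)
        assert np.allclose(o1.values, o2.values, atol=1e-14)

    def test_letter_scale_lookup_equivalent_to_array(self, random_cloud, make_eas):
        scale = kyte_doolittle_normalized()
        letters = list("AVLIFMCWGP" * 2)
        coords = random_cloud(seed=1, n=20, scale=5.0)
        eas = make_eas(coords, letters)
        o1 = observed_profile(eas, scale)
        o2 = observed_profile(eas, scale.lookup(eas.sequence))
        assert np.allclose(o1.values, o2.values)


class TestUniformAndNormalize:
    def test_uniform_values(self):
        assert np.allclose(uniform_profile(4).values, 0.25)
        assert np.isclose(uniform_profile(293).values.sum(), 1.0)

    def test_uniform_rejects_small_n(self):
        with pytest.raises(ValueError):
            uniform_profile(1)

    def test_normalize_examples(self):
        assert np.allclose(normalize(np.array([2.0, 2.0])).values, [0.5, 0.5])
        assert np.allclose(normalize(np.array([1.0, 2.0, 3.0])).values,
                           [1 / 6, 2 / 6, 3 / 6])

    def test_normalize_idempotent(self):
        p = normalize(np.array([0.3, 0.7]))
        assert np.allclose(normalize(p.values).values, p.values)

    def test_normalize_rejects_bad_input(self):
        with pytest.raises(DegenerateProfileError):
            normalize(np.zeros(3))
        with pytest.raises(ValueError):
            normalize(np.array([-1.0, 2.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=2, max_size=30))
    def test_every_profile_sums_to_one(self, raw):
        p = normalize(np.array(raw))
        assert np.all(p.values >= 0)
        assert abs(p.values.sum() - 1.0) <= 1e-12

    def test_profile_validates(self):
        with pytest.raises(ValueError):
            Profile(values=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            Profile(values=np.array([1.5, -0.5]))
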