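"""Three-level feature encoding: windows, protein-level block, exclusions."""

import numpy as np
import pytest

import disofun as d
from disofun.encoding import EncodingConfig


def make_profile(rng, L=20, constant=None):
    schema = d.default_schema()
    if constant is not None:
        values = np.full((L, schema.n_channels), constant)
    else:
        values = rng.random((L, schema.n_channels))
    return d.Profile("p1", values, schema.channels), schema


class TestWindowSlice:
    def test_interior_window(self):
        track = np.arange(1.0, 6.0)
        np.testing.assert_array_equal(d.window_slice(track, 3, 3, 0.0), [2, 3, 4])

    def test_left_edge_fill(self):
        track = np.arange(1.0, 6.0)
        np.testing.assert_array_equal(d.window_slice(track, 1, 5, 0.0), [0, 0, 1, 2, 3])

    def test_right_edge_mirrors_left(self):
        track = np.arange(1.0, 6.0)
        left = d.window_slice(track, 1, 5, -1.0)
        right = d.window_slice(track, 5, 5, -1.0)
        np.testing.assert_array_equal(right, [3, 4, 5, -1, -1])
        # mirror of the left-edge case on the reversed track
        np.testing.assert_array_equal(right[::-1], [-1, -1, 5, 4, 3])
        np.testing.assert_array_equal(left, [-1, -1, 1, 2, 3])

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            d.window_slice(np.arange(4.0), 2, 4, 0.0)


class TestProteinLevelFeatures:
    def test_channel_mean(self):
        schema = d.default_schema()
        values = np.zeros((4, 45))
        values[1, :] = 1.0
        values[3, :] = 1.0
        means, _, _, _ = d.protein_level_features(d.Profile("p", values, schema.channels))
        np.testing.assert_allclose(means, 0.5)

    def test_terminus_distances(self, rng):
        profile, _ = make_profile(rng, L=5)
        _, _, n_dist, c_dist = d.protein_level_features(profile)
        assert n_dist[0] == 0.0
        assert n_dist[2] == pytest.approx(0.4)
        assert c_dist[2] == pytest.approx(0.4)
        assert c_dist[-1] == 0.0

    def test_length_capped_normalisation(self, rng):
        profile, _ = make_profile(rng, L=10)
        _, length_feature, _, _ = d.protein_level_features(profile)
        assert length_feature == pytest.approx(10 / 10_000)


class TestEncode:
    def test_disorder_config_yields_318_columns(self, rng):
        for L in (1, 3, 40):
            profile, _ = make_profile(rng, L=L)
            fm = d.encode(profile, d.DISORDER_ENCODING)
            assert fm.values.shape == (L, 318)

    def test_function_config_yields_138_columns(self, rng):
        profile, _ = make_profile(rng, L=12)
        assert d.encode(profile, d.FUNCTION_ENCODING).values.shape[1] == 3 * 45 + 3

    def test_constant_profile_encodes_constant_channel_features(self, rng):
        profile, _ = make_profile(rng, L=9, constant=0.37)
        fm = d.encode(profile, d.DISORDER_ENCODING)
        channel_cols = [i for i, c in enumerate(fm.columns) if not c.startswith("prot:" ) or c.startswith("prot:mean")]
        np.testing.assert_allclose(fm.values[:, channel_cols], 0.37)

    def test_length_one_protein_repeats_own_values(self, rng):
        profile, _ = make_profile(rng, L=1)
        fm = d.encode(profile, d.DISORDER_ENCODING)
        res_block = fm.values[0, : 5 * 45].reshape(5, 45)
        np.testing.assert_allclose(res_block, np.tile(profile.values[0], (5, 1)))

    def test_window_mean_covering_chain_equals_protein_mean(self, rng):
        profile, _ = make_profile(rng, L=5)
        cfg = EncodingConfig(residue_window=1, average_window=15)
        fm = d.encode(profile, cfg)
        win_cols = [i for i, c in enumerate(fm.columns) if c.startswith("win15:")]
        mean_cols = [i for i, c in enumerate(fm.columns) if c.startswith("prot:mean:")]
        np.testing.assert_allclose(fm.values[:, win_cols], fm.values[:, mean_cols], atol=1e-12)

    @pytest.mark.parametrize(
        "r,a,expected",
        [(5, 15, 7 * 45 + 3), (1, 11, 3 * 45 + 3), (1, 15, 3 * 45 + 3), (5, 11, 7 * 45 + 3)],
    )
    def test_column_count_closed_form(self, r, a, expected):
        assert d.n_features(EncodingConfig(residue_window=r, average_window=a)) == expected

    def test_group_exclusion_removes_r_plus_two_per_channel(self):
        base = d.n_features(d.DISORDER_ENCODING)
        for group, size in (("iupred", 4), ("pssm", 20), ("function_predictors", 10)):
            cfg = EncodingConfig(excluded_groups=frozenset({group}))
            assert base - d.n_features(cfg) == (5 + 2) * size

    def test_level_exclusion_drops_whole_blocks(self):
        assert d.n_features(EncodingConfig(excluded_levels=frozenset({"protein"}))) == 318 - 48
        assert d.n_features(EncodingConfig(excluded_levels=frozenset({"window"}))) == 318 - 45
        assert d.n_features(EncodingConfig(excluded_levels=frozenset({"residue"}))) == 318 - 225

    def test_excluding_every_level_rejected(self):
        with pytest.raises(ValueError, match="all three"):
            EncodingConfig(excluded_levels=frozenset({"residue", "window", "protein"}))

    def test_reversal_equivariance(self, rng):
        profile, schema = make_profile(rng, L=17)
        reversed_profile = d.Profile("p1", profile.values[::-1], schema.channels)
        fm = d.encode(profile, d.DISORDER_ENCODING)
        fm_rev = d.encode(reversed_profile, d.DISORDER_ENCODING)
        cols = {c: i for i, c in enumerate(fm.columns)}

        def swap(name: str) -> str:
            if name.startswith("res["):
                offset = int(name[4 : name.index("]")])
                return f"res[{-offset:+d}]{name[name.index(']') + 1:]}"
            if name == "prot:n_dist":
                return "prot:c_dist"
            if name == "prot:c_dist":
                return "prot:n_dist"
            return name

        perm = [cols[swap(c)] for c in fm.columns]
        np.testing.assert_allclose(fm_rev.values[::-1], fm.values[:, perm], atol=1e-12)

    def test_empty_profile_rejected(self):
        schema = d.default_schema()
        with pytest.raises(ValueError):
            d.Profile("p1", np.zeros((0, 45)), schema.channels)

    def test_schema_mismatch_rejected(self, rng):
        profile = d.Profile("p1", rng.random((4, 3)), ("a", "b", "c"))
        with pytest.raises(ValueError, match="do not match schema"):
            d.encode(profile, d.DISORDER_ENCODING)


class TestProfileEncoder:
    def test_transformer_api(self, rng):
        profile, _ = make_profile(rng, L=8)
        enc = d.ProfileEncoder().fit()
        assert enc.n_features_ == 318
        assert enc.transform([profile, profile]).shape == (16, 318)
        assert len(enc.get_feature_names_out()) == 318

    def test_provenance_hash_changes_with_config(self):
        a = d.ProfileEncoder().fit().provenance_hash_
        b = d.ProfileEncoder(residue_window=1, average_window=11).fit().provenance_hash_
        assert a != b

    def test_get_set_params_round_trip(self):
        enc = d.ProfileEncoder(residue_window=3)
        params = enc.get_params()
        enc2 = d.ProfileEncoder().set_params(**params)
        assert enc2.residue_window == 3
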