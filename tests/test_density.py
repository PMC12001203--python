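"""Bond-density profiling, the paired test and the enantiomer call."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from bspa.density import (
    BondProbe,
    DensityGrid,
    ProbeOutsideGridError,
    ReplicateSet,
    call_enantiomer,
    paired_t,
    read_ccp4,
    read_probes_json,
    sample_bond_density,
    write_ccp4,
)
from bspa.simulate import simulate_density_pair, simulate_density_replicates


def t_sf_oracle(t, df):
    """Upper-tail Student-t probability by direct numerical integration of
    the density (independent of scipy.stats.t)."""
    lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)

    def pdf(x):
        return math.exp(lognorm - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _ = quad(pdf, abs(t), math.inf)
    return tail if t >= 0 else 1.0 - tail


class TestSampleBondDensity:
    def test_constant_field(self):
        grid = DensityGrid(values=np.full((4, 4, 4), 2.5), spacing=[1, 1, 1])
        profile = sample_bond_density(grid, BondProbe(a=(0, 0, 0), b=(3, 3, 3), n_samples=7))
        assert np.allclose(profile.samples, 2.5)
        assert profile.mean_positive == pytest.approx(2.5)

    def test_all_negative_gives_zero(self):
        grid = DensityGrid(values=np.full((4, 4, 4), -1.0), spacing=[1, 1, 1])
        profile = sample_bond_density(grid, BondProbe(a=(0, 0, 0), b=(3, 0, 0), n_samples=5))
        assert profile.mean_positive == 0.0

    def test_linear_field_closed_form(self):
        # f(x, y, z) = x sampled along the x axis from 0 to 1 with 5 points:
        # samples (0, .25, .5, .75, 1); mean over positives = 0.625
        spacing = 0.25
        n = 8
        values = np.broadcast_to(
            (np.arange(n) * spacing)[:, None, None], (n, n, n)).copy()
        grid = DensityGrid(values=values, spacing=[spacing] * 3)
        profile = sample_bond_density(grid, BondProbe(a=(0, 0, 0), b=(1, 0, 0), n_samples=5))
        assert np.allclose(profile.samples, [0.0, 0.25, 0.5, 0.75, 1.0], atol=1e-7)
        assert profile.mean_positive == pytest.approx(0.625)

    def test_trilinear_matches_closed_form_on_oblique_segments(self):
        # linear field f = 2x - y + 0.5z is reproduced exactly by trilinear
        # interpolation at arbitrary points
        n = 9
        ax = np.arange(n) * 0.5
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = DensityGrid(values=2 * X - Y + 0.5 * Z, spacing=[0.5] * 3)
        probe = BondProbe(a=(0.3, 0.2, 0.7), b=(3.1, 2.9, 1.8), n_samples=17)
        profile = sample_bond_density(grid, probe)
        pts = probe.points()
        expected = 2 * pts[:, 0] - pts[:, 1] + 0.5 * pts[:, 2]
        assert np.allclose(profile.samples, expected, atol=1e-6)

    def test_probe_outside_grid_names_endpoint(self):
        grid = DensityGrid(values=np.zeros((4, 4, 4)), spacing=[1, 1, 1])
        with pytest.raises(ProbeOutsideGridError, match="endpoint b"):
            sample_bond_density(grid, BondProbe(a=(0, 0, 0), b=(10, 0, 0)))

    def test_pointwise_increase_is_monotone_in_mean_positive(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(6, 6, 6))
        probe = BondProbe(a=(0.5, 0.5, 0.5), b=(4.5, 4.2, 3.9), n_samples=21)
        base = sample_bond_density(DensityGrid(values=values, spacing=[1, 1, 1]), probe)
        lifted = sample_bond_density(
            DensityGrid(values=values + 0.7, spacing=[1, 1, 1]), probe)
        assert lifted.mean_positive >= base.mean_positive


class TestPairedT:
    def test_identical_pairs_are_null(self):
        t, df, p = paired_t([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert (t, df, p) == (0.0, 2, 0.5)

    def test_hand_computed_example(self):
        # differences (2, 1, 3): mean 2, sd 1, k 3 -> t = 2 sqrt(3)
        t, df, p = paired_t([(2.0, 0.0), (1.0, 0.0), (3.0, 0.0)])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert df == 2
        assert p == pytest.approx(t_sf_oracle(t, 2), abs=1e-9)

    def test_symmetric_cancel(self):
        t, df, p = paired_t([(1.0, 0.0), (0.0, 1.0)])
        assert t == 0.0 and p == 0.5

    def test_degenerate_zero_spread(self):
        t, _, p = paired_t([(2.0, 1.0), (3.0, 2.0)])  # differences (1, 1)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([(1.0, 0.0)])

    @pytest.mark.parametrize("df", range(1, 11))
    def test_p_values_match_integral_oracle(self, df):
        for t in (-10.0, -3.2, -0.5, 0.0, 0.7, 2.1, 6.9, 10.0):
            pairs = _pairs_with_t(t, df)
            got_t, got_df, got_p = paired_t(pairs)
            assert got_df == df
            assert got_t == pytest.approx(t, abs=1e-9)
            assert got_p == pytest.approx(t_sf_oracle(t, df), abs=1e-6)


def _pairs_with_t(t, df):
    """Construct k = df + 1 paired differences with an exact t statistic."""
    k = df + 1
    base = np.zeros(k)
    base[0] = 1.0
    base -= base.mean()
    base /= base.std(ddof=1)  # mean 0, sd 1
    mean = t / math.sqrt(k)
    d = base + mean
    return [(float(v), 0.0) for v in d]


class TestCallEnantiomer:
    def test_strong_positive_differences_call_r(self):
        reps = simulate_density_replicates("R", 4.0, 1.0, k=3, seed=11)
        pairs = tuple(
            (sample_bond_density(grid, probes["R"]).mean_positive,
             sample_bond_density(grid, probes["S"]).mean_positive)
            for grid, probes in reps
        )
        call = call_enantiomer(ReplicateSet(pairs=pairs))
        assert call.call == "R"
        assert call.p_value < 0.01

    def test_equal_pairs_inconclusive(self):
        call = call_enantiomer(ReplicateSet(pairs=((1.0, 1.0), (2.0, 2.0), (0.5, 0.5))))
        assert call.call == "inconclusive"

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="single"):
            ReplicateSet(pairs=((1.0, 0.5),))

    def test_antisymmetry_swapping_columns_flips_call(self):
        pairs = ((3.0, 1.0), (2.5, 0.9), (3.2, 1.4))
        swapped = tuple((s, r) for r, s in pairs)
        fwd = call_enantiomer(ReplicateSet(pairs=pairs))
        rev = call_enantiomer(ReplicateSet(pairs=swapped))
        assert fwd.call == "R" and rev.call == "S"
        assert fwd.t_stat == pytest.approx(-rev.t_stat)

    def test_two_sided_mode_controls_family_alpha(self):
        pairs = ((3.0, 1.0), (2.5, 0.9), (3.2, 1.4))
        call = call_enantiomer(ReplicateSet(pairs=pairs), alternative="two-sided")
        t, df, p_upper = paired_t(pairs)
        assert call.p_value == pytest.approx(2 * p_upper)


class TestDensityFixtures:
    def test_noiseless_effect_separates_sites(self):
        grid, probes = simulate_density_pair("R", 1.0, 0.0, seed=0)
        mp_r = sample_bond_density(grid, probes["R"]).mean_positive
        mp_s = sample_bond_density(grid, probes["S"]).mean_positive
        assert mp_r > mp_s

    def test_null_grid_is_flat(self):
        grid, probes = simulate_density_pair("R", 0.0, 0.0, seed=0)
        assert sample_bond_density(grid, probes["R"]).mean_positive == 0.0
        assert sample_bond_density(grid, probes["S"]).mean_positive == 0.0

    def test_s_site_mirror(self):
        grid, probes = simulate_density_pair("S", 1.0, 0.0, seed=0)
        mp_r = sample_bond_density(grid, probes["R"]).mean_positive
        mp_s = sample_bond_density(grid, probes["S"]).mean_positive
        assert mp_s > mp_r

    def test_ccp4_roundtrip(self, tmp_path):
        grid, _ = simulate_density_pair("R", 2.0, 0.5, seed=3)
        path = tmp_path / "replicate.map"
        write_ccp4(grid, path)
        reread = read_ccp4(path)
        assert np.allclose(reread.values, grid.values, atol=1e-6)
        assert np.allclose(reread.spacing, grid.spacing)
        assert np.allclose(reread.origin, grid.origin)

    def test_probes_json_roundtrip(self, tmp_path):
        import json

        _, probes = simulate_density_pair("R", 1.0, 0.0, seed=0)
        path = tmp_path / "probes.json"
        path.write_text(json.dumps({
            "n_samples": probes["R"].n_samples,
            "R": {"a": list(probes["R"].a), "b": list(probes["R"].b)},
            "S": {"a": list(probes["S"].a), "b": list(probes["S"].b)},
        }))
        loaded = read_probes_json(path)
        assert loaded["R"] == probes["R"]
        assert loaded["S"] == probes["S"]
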