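"""Tests of the scenario simulator: genotype law, moment structure, I/O."""

import numpy as np
import pytest

from causaltrio import (InvalidScenarioError, ScenarioSpec, default_spec,
                        read_triplets, rng_for, simulate_genotypes,
                        simulate_replicate, simulate_triplet, write_triplet)
from causaltrio.simulate import (CONFOUNDED_SCENARIOS, EQUATIONS, SCENARIO_IDS)

VAR_ORDER = ("g", "e", "x", "y")


def implied_covariance(spec: ScenarioSpec) -> np.ndarray:
    """Closed-form covariance of (g, x, y) by path algebra.

    Independent oracle for the sampler: build the linear coefficient
    matrix B over (g, e, x, y) straight from the structural equations and
    use the reduced form Sigma = (I - B)^-1 Psi (I - B)^-T, then drop the
    latent row/column.  var(g) = 2 maf (1 - maf) is the binomial variance
    of the minor-allele count.
    """
    idx = {v: i for i, v in enumerate(VAR_ORDER)}
    B = np.zeros((4, 4))
    for child in ("x", "y"):
        for parent, coef in EQUATIONS[spec.scenario_id][child]:
            B[idx[child], idx[parent]] = getattr(spec, coef)
    psi = np.array([2 * spec.maf * (1 - spec.maf), spec.sigma_e**2,
                    spec.sigma_x**2, spec.sigma_y**2])
    inv = np.linalg.inv(np.eye(4) - B)
    full = inv @ np.diag(psi) @ inv.T
    keep = [idx["g"], idx["x"], idx["y"]]
    return full[np.ix_(keep, keep)]


class TestGenotypes:
    def test_hwe_frequencies(self, rng):
        n = 10**6
        g = simulate_genotypes(n, 0.1, rng)
        freqs = np.bincount(g, minlength=3) / n
        expected = np.array([0.81, 0.18, 0.01])
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freqs - expected) < 3 * se)
        # binomial(2, maf) variance
        assert g.var() == pytest.approx(0.18, abs=3 * 0.18 / np.sqrt(n) * 2)

    def test_vanishing_maf_gives_all_zeros(self, rng):
        assert simulate_genotypes(4, 1e-12, rng).tolist() == [0, 0, 0, 0]

    @pytest.mark.parametrize("n,maf", [(0, 0.1), (-5, 0.1), (10, 0.0),
                                       (10, 0.6), (10, -0.1)])
    def test_invalid_arguments(self, rng, n, maf):
        with pytest.raises(ValueError):
            simulate_genotypes(n, maf, rng)


class TestScenarioSpec:
    def test_defaults_match_stated_world(self):
        spec = default_spec("a")
        assert (spec.alpha, spec.beta, spec.gamma, spec.delta, spec.zeta) == (1,) * 5
        assert (spec.mu_x, spec.mu_y) == (10, 10)
        assert (spec.sigma_x, spec.sigma_y, spec.sigma_e) == (0.3, 0.3, 0.3)
        assert spec.maf == 0.1 and spec.n == 1000
        h = default_spec("h")
        assert h.zeta == 1 and h.sigma_e == 0.3

    def test_unknown_scenario_rejected(self):
        with pytest.raises(InvalidScenarioError):
            default_spec("z")

    @pytest.mark.parametrize("kw", [{"sigma_x": 0.0}, {"maf": 0.7},
                                    {"maf": 0.0}, {"n": 1}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario_id="a", **kw)


class TestSimulateTriplet:
    def test_global_null_has_no_correlations(self, rng):
        spec = default_spec("b").replace(alpha=0.0, gamma=0.0, n=10**5)
        ds = simulate_triplet(spec, rng)
        assert abs(np.corrcoef(ds.g, ds.x)[0, 1]) < 0.02
        assert abs(np.corrcoef(ds.x, ds.y)[0, 1]) < 0.02

    def test_mediation_chain_gy_correlation(self, rng):
        # population corr(G, Y) = 0.18 / sqrt(0.18 * 0.36) ~= 0.707 under (b)
        ds = simulate_triplet(default_spec("b").replace(n=4 * 10**5), rng)
        assert np.corrcoef(ds.g, ds.y)[0, 1] == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_confounded_trait_covariance(self, rng):
        # scenario (h): cov(X, Y) = alpha*beta*var(G) + zeta^2*sigma_e^2 = 0.27
        n = 4 * 10**5
        ds = simulate_triplet(default_spec("h").replace(n=n), rng)
        sigma = implied_covariance(default_spec("h"))
        # Gaussian-formula SE; widened to 4 SEs because the binomial
        # genotype's fourth moment inflates the covariance sampling noise
        se = np.sqrt((sigma[1, 1] * sigma[2, 2] + sigma[1, 2] ** 2) / n)
        assert np.cov(ds.x, ds.y)[0, 1] == pytest.approx(0.27, abs=4 * se)
        assert sigma[1, 2] == pytest.approx(0.27)

    @pytest.mark.parametrize("scenario", SCENARIO_IDS)
    def test_moments_match_path_algebra(self, scenario):
        """Sample covariance of (g,x,y) within 4 SEs of the closed form."""
        n = 10**5
        spec = default_spec(scenario).replace(n=n)
        ds = simulate_triplet(spec, rng_for(123, scenario, 0))
        sample = np.cov(np.vstack([ds.g, ds.x, ds.y]), ddof=1)
        sigma = implied_covariance(spec)
        for i in range(3):
            for j in range(3):
                # Gaussian-formula SE, widened (see note above on the
                # genotype's fourth moment)
                se = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n)
                assert sample[i, j] == pytest.approx(sigma[i, j], abs=5 * se), \
                    f"cov[{i},{j}] off under scenario {scenario}"

    @pytest.mark.parametrize("scenario", SCENARIO_IDS)
    def test_confounder_stored_iff_scenario_has_one(self, scenario):
        ds = simulate_triplet(default_spec(scenario).replace(n=50),
                              rng_for(5, scenario, 0))
        assert (ds.e is not None) == (scenario in CONFOUNDED_SCENARIOS)
        # the method-facing accessors never expose e
        assert len(ds.triplet()) == 3
        assert list(ds.to_frame().columns) == ["g", "x", "y"]

    def test_same_seed_reproduces_bitwise(self):
        for scenario in ("a", "h"):
            d1 = simulate_replicate(default_spec(scenario), base_seed=9, replicate=3)
            d2 = simulate_replicate(default_spec(scenario), base_seed=9, replicate=3)
            assert np.array_equal(d1.g, d2.g)
            assert np.array_equal(d1.x, d2.x) and np.array_equal(d1.y, d2.y)
        d3 = simulate_replicate(default_spec("a"), base_seed=9, replicate=4)
        assert not np.array_equal(d1.x, d3.x)


class TestIO:
    def test_roundtrip(self, tmp_path):
        spec = default_spec("h").replace(n=40)
        ds = simulate_replicate(spec, 2, 0)
        path = write_triplet(ds, tmp_path / "rep.csv", spec=spec)
        text = path.read_text()
        assert text.splitlines()[0] == "g,x,y"  # header, and no e column
        back = read_triplets(path)
        assert np.array_equal(back.g, ds.g)
        np.testing.assert_allclose(back.x, ds.x)
        np.testing.assert_allclose(back.y, ds.y)
        assert back.truth == "h"
        assert back.seed_record == ds.seed_record

    def test_reader_rejects_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("g,x\n0,1.0\n")
        with pytest.raises(ValueError, match="columns"):
            read_triplets(p)

    def test_reader_rejects_bad_genotypes(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("g,x,y\n3,1.0,1.0\n")
        with pytest.raises(ValueError, match="genotype"):
            read_triplets(p)
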