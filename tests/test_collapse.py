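"""Finite-size scaling collapse: density estimation and exponent recovery."""

import numpy as np
import pytest

from pillarmps.collapse import (
    ScalingCollapse,
    collapse_distributions,
    collapse_objective,
    empirical_pdf,
)
from pillarmps.synthetic import synth_scaling_distributions

MASSES = [1.0, 2.2, 4.0]


def synthetic_pdfs(delta0, n=2000, seed=11, masses=MASSES):
    out = synth_scaling_distributions(delta0, masses, n, seed=seed)
    return [empirical_pdf(s) for s in out["samples"].values()]


class TestEmpiricalPdf:
    def test_uniform_density(self):
        rng = np.random.default_rng(0)
        x, y = empirical_pdf(rng.uniform(0.5, 1.5, 50_000), n_bins=20,
                             log_bins=False)
        assert np.allclose(y, 1.0, atol=0.05)

    def test_normalisation(self):
        rng = np.random.default_rng(1)
        x, y = empirical_pdf(rng.lognormal(0.0, 0.5, 20_000), n_bins=50)
        edges = np.geomspace(x[0] / np.sqrt(x[1] / x[0]),
                             x[-1] * np.sqrt(x[1] / x[0]), 51)
        integral = np.sum(y * np.diff(edges))
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_lognormal_matches_closed_form(self):
        mu, sig = 0.0, 0.5
        rng = np.random.default_rng(2)
        x, y = empirical_pdf(rng.lognormal(mu, sig, 100_000), n_bins=40)
        ref = np.exp(-((np.log(x) - mu) ** 2) / (2 * sig**2)) \
            / (x * sig * np.sqrt(2 * np.pi))
        core = (ref > 0.1 * ref.max())
        assert np.allclose(y[core], ref[core], rtol=0.15)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            empirical_pdf(np.ones(10))


class TestCollapse:
    @pytest.mark.parametrize("delta0", [0.6, 0.75, 1.0])
    def test_recovers_known_exponent(self, delta0):
        res = collapse_distributions(synthetic_pdfs(delta0), MASSES, seed=5)
        assert res.delta == pytest.approx(delta0, abs=0.05)

    def test_isometric_when_proportional(self):
        # B exactly proportional to m (degenerate X): delta = 1 recovered
        out = synth_scaling_distributions(1.0, MASSES, 2000, seed=3,
                                          base_cv=0.4)
        pdfs = [empirical_pdf(s) for s in out["samples"].values()]
        res = collapse_distributions(pdfs, MASSES, seed=5)
        assert res.delta == pytest.approx(1.0, abs=0.05)

    def test_identical_distributions_flagged_degenerate(self):
        rng = np.random.default_rng(8)
        s = rng.lognormal(0.0, 0.4, 3000)
        pdfs = [empirical_pdf(s)] * 3
        res = collapse_distributions(pdfs, [1.0, 1.0 + 1e-9, 1.0 + 2e-9],
                                     seed=0)
        assert res.degenerate
        assert res.distance == pytest.approx(0.0, abs=1e-6)

    def test_optimum_beats_offsets(self):
        # local identifiability: distance rises away from the optimum
        pdfs = synthetic_pdfs(0.75)
        model = ScalingCollapse(pdfs, MASSES)
        res = model.fit(seed=2)
        for off in (-0.2, 0.2):
            assert model.objective(res.delta + off) > res.distance + 1e-3

    def test_matches_dense_grid_scan(self):
        pdfs = synthetic_pdfs(0.6)
        res = collapse_distributions(pdfs, MASSES, seed=9)
        grid = np.arange(0.3, 1.5, 0.001)
        vals = [collapse_objective(pdfs, np.asarray(MASSES), 1.0, d)
                for d in grid]
        best = grid[int(np.argmin(vals))]
        assert abs(res.delta - best) <= 0.001 + 1e-9

    def test_invariant_to_common_mass_scale(self):
        pdfs = synthetic_pdfs(0.75)
        r1 = collapse_distributions(pdfs, MASSES, seed=4)
        r2 = collapse_distributions(pdfs, [7.3 * m for m in MASSES], seed=4)
        assert r2.delta == pytest.approx(r1.delta, abs=0.01)

    def test_needs_two_geometries(self):
        with pytest.raises(ValueError):
            collapse_distributions(synthetic_pdfs(0.75)[:1], MASSES[:1])

    def test_summary_mentions_exponent(self):
        res = collapse_distributions(synthetic_pdfs(0.75), MASSES, seed=5)
        assert "delta" in res.summary()
        assert res.alpha == res.delta
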