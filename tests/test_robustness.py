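import numpy as np
import pytest

from batfruitnet import (
    correlate_impact,
    extinction_replicate,
    jackknife_removals,
    robustness,
)
from batfruitnet.errors import BatFruitNetError
from batfruitnet.netio import SpeciesMeta
from batfruitnet.robustness import RemovalImpact
from batfruitnet.roles import SpeciesRole

from conftest import make_matrix


class TestExtinctionReplicate:
    def test_one_to_one_area_half(self):
        m = make_matrix(np.eye(5))
        for seed in range(5):
            x, y, area = extinction_replicate(m, "animal", seed)
            assert area == pytest.approx(0.5)
            assert np.allclose(y, 1 - x)

    @pytest.mark.parametrize("n_plants", [3, 5, 8])
    def test_complete_network_closed_form(self, n_plants):
        m = make_matrix(np.ones((3, n_plants)))
        x, y, area = extinction_replicate(m, "plant", 0)
        assert area == pytest.approx(1 - 1 / (2 * n_plants))
        assert y[-1] == 0.0 and y[0] == 1.0

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        w = (rng.random((6, 9)) < 0.4).astype(float)
        w[w.sum(axis=1) == 0, 0] = 1
        w[0, w.sum(axis=0) == 0] = 1
        m = make_matrix(w)
        for seed in range(5):
            x, y, area = extinction_replicate(m, "animal", seed)
            assert np.all(np.diff(y) <= 1e-12)
            assert 0.0 <= area <= 1.0

    def test_explicit_order(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1]])
        x, y, area = extinction_replicate(m, "animal", 0, order=np.array([0, 1]))
        # removing bat1 first: plant1 orphaned -> 2/3 survive; then none
        assert np.allclose(y, [1.0, 2 / 3, 0.0])

    def test_conservation_each_step(self):
        rng = np.random.default_rng(7)
        w = (rng.random((5, 7)) < 0.5).astype(float)
        w[w.sum(axis=1) == 0, 0] = 1
        w[0, w.sum(axis=0) == 0] = 1
        m = make_matrix(w)
        x, y, _ = extinction_replicate(m, "plant", 1)
        survivors = y * m.n_animals
        lost = m.n_animals - survivors
        assert np.all(survivors + lost == m.n_animals)
        assert float(survivors[0]) == m.n_animals  # validated: none start lost


class TestRobustness:
    def test_complete_network_zero_sd(self):
        res = robustness(make_matrix(np.ones((3, 4))), "animal", 20, 0)
        assert res.r_sd == pytest.approx(0.0, abs=1e-12)
        assert res.r_mean == pytest.approx(1 - 1 / 6)

    def test_one_to_one_mean_half(self):
        res = robustness(make_matrix(np.eye(4)), "plant", 30, 1)
        assert res.r_mean == pytest.approx(0.5)
        assert res.r_sd == 0.0

    def test_reproducible_by_seed(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        a = robustness(m, "animal", 25, 42)
        b = robustness(m, "animal", 25, 42)
        assert np.array_equal(a.r_values, b.r_values)

    def test_curve_mean_endpoints(self):
        m = make_matrix([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        res = robustness(m, "plant", 10, 0)
        assert res.curve_y_mean[0] == pytest.approx(1.0)
        assert res.curve_y_mean[-1] == pytest.approx(0.0)


class TestJackknife:
    def test_generalist_removal_orphans_specialist_plant(self, nested3):
        impacts = {i.species_id: i for i in jackknife_removals(nested3)}
        # bat1 is the only consumer of plant3
        assert impacts["bat1"].sl_r == pytest.approx(1 / 3)
        # bat3 eats plant1, also eaten by others: no secondary loss
        assert impacts["bat3"].sl_r == 0.0

    def test_redundant_partners_no_loss(self):
        m = make_matrix(np.ones((3, 3)))
        assert all(i.sl_r == 0.0 for i in jackknife_removals(m))

    def test_degenerating_removal_flagged_not_computable(self):
        m = make_matrix([[1, 1], [1, 0]])
        impacts = {i.species_id: i for i in jackknife_removals(m)}
        assert impacts["bat1"].nodf_r is None  # removal degenerates the matrix
        assert impacts["bat1"].sl_r == pytest.approx(0.5)

    def test_both_sides_covered(self, nested3):
        impacts = jackknife_removals(nested3)
        sides = {i.side for i in impacts}
        assert sides == {"animal", "plant"}
        assert len(impacts) == 6


class TestCorrelateImpact:
    def _impacts_roles(self, kr_vals, nodf_vals):
        impacts = [
            RemovalImpact(f"a{i}", "animal", nodf_r=nv, sl_r=0.0)
            for i, nv in enumerate(nodf_vals)
        ]
        roles = [
            SpeciesRole(f"a{i}", "animal", k_r=kv, bc=0.0)
            for i, kv in enumerate(kr_vals)
        ]
        return impacts, roles

    def test_monotone_decreasing_gives_minus_one(self):
        kr = [0.1, 0.3, 0.5, 0.7, 0.9]
        nr = [-0.01 * k for k in range(5)]
        impacts, roles = self._impacts_roles(kr, nr)
        cors, _ = correlate_impact(impacts, roles)
        assert cors["animal"].spearman_r == pytest.approx(-1.0)

    def test_constant_impacts_flagged_degenerate(self):
        impacts, roles = self._impacts_roles([0.1, 0.5, 0.9], [0.0, 0.0, 0.0])
        with pytest.raises(BatFruitNetError, match="constant"):
            correlate_impact(impacts, roles)

    def test_frugivory_kruskal_included_with_meta(self):
        kr = np.linspace(0.1, 0.9, 9)
        nr = [-0.04, -0.05, -0.035, -0.01, -0.012, -0.011, 0.0, -0.001, 0.0]
        impacts, roles = self._impacts_roles(kr, nr)
        meta = {}
        levels = ["primary"] * 3 + ["secondary"] * 3 + ["occasional"] * 3
        for imp, lvl in zip(impacts, levels):
            meta[imp.species_id] = SpeciesMeta(imp.species_id, "animal", "X", lvl)
        cors, kw = correlate_impact(impacts, roles, meta)
        assert kw is not None
        assert kw.df == 2
        assert kw.group_medians["primary"] < kw.group_medians["occasional"]
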