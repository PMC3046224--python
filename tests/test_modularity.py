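import math

import numpy as np
import pytest

from batfruitnet import (
    Partition,
    anneal_modularity,
    count_preferred_pairings,
    g_test_yates,
    modularity_of_partition,
)
from batfruitnet.netio import SpeciesMeta

from conftest import make_matrix


def block_matrix(k: int, bats_per: int = 2, plants_per: int = 2):
    """k disconnected complete bipartite blocks."""
    w = np.zeros((k * bats_per, k * plants_per))
    for b in range(k):
        w[b * bats_per : (b + 1) * bats_per, b * plants_per : (b + 1) * plants_per] = 1
    return make_matrix(w)


def block_assignment(m, k: int, bats_per: int = 2, plants_per: int = 2):
    ass = {}
    for i, a in enumerate(m.animal_ids):
        ass[a] = i // bats_per
    for j, p in enumerate(m.plant_ids):
        ass[p] = j // plants_per
    return ass


class TestModularityOfPartition:
    def test_two_blocks_half(self, two_blocks):
        ass = block_assignment(two_blocks, 2)
        assert modularity_of_partition(two_blocks, ass) == pytest.approx(0.5)

    def test_single_module_zero(self, nested3):
        ass = {s: 0 for s in nested3.species_ids()}
        assert modularity_of_partition(nested3, ass) == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_equal_blocks_closed_form(self, k):
        m = block_matrix(k)
        ass = block_assignment(m, k)
        assert modularity_of_partition(m, ass) == pytest.approx(1 - 1 / k)

    def test_missing_node_rejected(self, nested3):
        with pytest.raises(KeyError):
            modularity_of_partition(nested3, {"bat1": 0})


class TestAnnealModularity:
    def test_recovers_two_blocks(self, two_blocks):
        part = anneal_modularity(two_blocks, rng_seed=0, restarts=2)
        assert part.m_value == pytest.approx(0.5)
        assert part.n_modules == 2
        # the two blocks are exactly the modules
        mods = part.modules()
        groups = {frozenset(v) for v in mods.values()}
        assert groups == {
            frozenset({"bat1", "bat2", "plant1", "plant2"}),
            frozenset({"bat3", "bat4", "plant3", "plant4"}),
        }

    def test_at_least_single_module_value(self, nested3):
        part = anneal_modularity(nested3, rng_seed=1, restarts=2)
        assert part.m_value >= 0.0

    def test_deterministic_given_seed(self, two_blocks):
        a = anneal_modularity(two_blocks, rng_seed=5, restarts=2)
        b = anneal_modularity(two_blocks, rng_seed=5, restarts=2)
        assert a.assignment == b.assignment
        assert a.m_value == b.m_value

    def test_best_of_restarts_monotone(self):
        m = block_matrix(3, 2, 3)
        values = [
            anneal_modularity(m, rng_seed=9, restarts=r).m_value for r in (1, 3, 5)
        ]
        assert values == sorted(values)

    def test_invalid_schedule_rejected(self, two_blocks):
        with pytest.raises(ValueError):
            anneal_modularity(two_blocks, cooling=1.5)
        with pytest.raises(ValueError):
            anneal_modularity(two_blocks, t0=-1.0)

    def test_partition_value_consistent(self, two_blocks):
        part = anneal_modularity(two_blocks, rng_seed=3)
        assert modularity_of_partition(two_blocks, part.assignment) == pytest.approx(
            part.m_value
        )


def _meta(species: dict[str, tuple[str, str]]) -> dict[str, SpeciesMeta]:
    out = {}
    for sp, (side, genus) in species.items():
        level = "primary" if side == "animal" else "not_applicable"
        out[sp] = SpeciesMeta(sp, side, genus, level)
    return out


class TestCountPreferredPairings:
    def test_follow_when_module_contains_predicted_plant(self):
        part = Partition({"c1": 0, "c2": 0, "p1": 0, "s1": 1}, 0.3, 2)
        meta = _meta(
            {
                "c1": ("animal", "Carollia"),
                "c2": ("animal", "Carollia"),
                "p1": ("plant", "Piper"),
                "s1": ("plant", "Solanum"),
            }
        )
        counts = count_preferred_pairings([part], [meta])
        assert counts["Carollia"].n_follow == 1
        assert counts["Carollia"].n_not == 0

    def test_absent_genus_contributes_nothing(self):
        part = Partition({"c1": 0, "p1": 0}, 0.0, 1)
        meta = _meta({"c1": ("animal", "Carollia"), "p1": ("plant", "Piper")})
        counts = count_preferred_pairings([part], [meta])
        assert counts["Artibeus"].n_follow + counts["Artibeus"].n_not == 0

    def test_split_genus_uses_majority_module_and_logs(self):
        part = Partition(
            {"c1": 0, "c2": 1, "c3": 1, "piper": 0, "solanum": 1}, 0.2, 2
        )
        meta = _meta(
            {
                "c1": ("animal", "Carollia"),
                "c2": ("animal", "Carollia"),
                "c3": ("animal", "Carollia"),
                "piper": ("plant", "Piper"),
                "solanum": ("plant", "Solanum"),
            }
        )
        counts = count_preferred_pairings([part], [meta])
        # majority module (1) has no Piper -> not followed, and the split is logged
        assert counts["Carollia"].n_not == 1
        assert counts["Carollia"].split_events

    def test_pooling_across_networks(self):
        follow = Partition({"c1": 0, "piper": 0}, 0.1, 1)
        not_follow = Partition({"c1": 0, "solanum": 0}, 0.1, 1)
        meta_f = _meta({"c1": ("animal", "Carollia"), "piper": ("plant", "Piper")})
        meta_n = _meta({"c1": ("animal", "Carollia"), "solanum": ("plant", "Solanum")})
        parts = [follow] * 7 + [not_follow] * 2
        metas = [meta_f] * 7 + [meta_n] * 2
        counts = count_preferred_pairings(parts, metas)
        assert (counts["Carollia"].n_follow, counts["Carollia"].n_not) == (7, 2)
        assert counts["Carollia"].proportion == pytest.approx(7 / 9)


class TestGTestYates:
    def test_balanced_counts_give_zero(self):
        res = g_test_yates(5, 5)
        assert res.g_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_direct_evaluation(self):
        res = g_test_yates(7, 2)
        expected = 2 * (6.5 * math.log(6.5 / 4.5) + 2.5 * math.log(2.5 / 4.5))
        assert res.g_statistic == pytest.approx(expected)
        assert res.proportion == pytest.approx(7 / 9)

    def test_symmetric_in_arguments(self):
        assert g_test_yates(8, 3).g_statistic == pytest.approx(
            g_test_yates(3, 8).g_statistic
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            g_test_yates(0, 0)

    def test_correction_does_not_cross_expected(self):
        # counts one apart: O' must stop at E, giving G = 0
        res = g_test_yates(3, 4)
        assert res.g_statistic == pytest.approx(0.0, abs=1e-12)
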