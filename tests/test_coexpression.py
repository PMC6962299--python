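"""Differential co-expression edge rule, network assembly and the SCNA
co-alteration matrix."""

import numpy as np
import pytest

from pdsgscreen import (build_network, co_alteration_matrix, diff_coex_edges,
                        simulate_cohort, write_sif)
from pdsgscreen.coexpression import (ACTIVE_IN_ALTERATION,
                                     ACTIVE_IN_NON_ALTERATION, DiffCoexEdge,
                                     _classify)
from pdsgscreen.simulate import BlockSpec, PartnerSpec, PlantedGene, SimConfig

from conftest import build_cohort


def _planted_cohort(rng, r_alt_noise=0.2, couple_non=False):
    """1 PDSG + 1 partner + 2 background genes; partner tracks the PDSG in
    the altered class only (or in CNNS when couple_non)."""
    n = 200
    scna = rng.normal(0, 0.05, size=(4, n))
    scna[0, :60] = rng.uniform(0.5, 1.5, size=60)
    expr = np.abs(rng.normal(10, 3, size=(4, n)))
    active = slice(0, 60) if not couple_non else slice(60, n)
    inactive = slice(60, n) if not couple_non else slice(0, 60)
    expr[1, active] = expr[0, active] + rng.normal(
        0, r_alt_noise, active.stop - active.start)
    # exactly decorrelate the partner from the PDSG in the inactive class
    src = expr[0, inactive] - expr[0, inactive].mean()
    res = expr[1, inactive] - expr[1, inactive].mean()
    res -= src * (res @ src) / (src @ src)
    expr[1, inactive] = np.maximum(10 + res, 0)
    t = rng.exponential(100, n)
    return build_cohort(scna, expr, t, [1] * n)


class TestEdgeRule:
    def test_alteration_active_partner_detected(self, rng):
        cohort = _planted_cohort(rng)
        edges = diff_coex_edges(cohort, ["G0000"])
        found = {(e.partner, e.active_in) for e in edges}
        assert ("G0001", ACTIVE_IN_ALTERATION) in found

    def test_non_alteration_active_partner_detected(self, rng):
        cohort = _planted_cohort(rng, couple_non=True)
        edges = diff_coex_edges(cohort, ["G0000"])
        found = {(e.partner, e.active_in) for e in edges}
        assert ("G0001", ACTIVE_IN_NON_ALTERATION) in found

    def test_dual_threshold_rule(self):
        # strong in one class only -> edge; moderate in both -> none
        assert _classify(0.6, 0.05, 0.5, 0.1, "absolute") == ACTIVE_IN_ALTERATION
        assert _classify(0.6, 0.3, 0.5, 0.1, "absolute") is None
        assert _classify(-0.7, 0.02, 0.5, 0.1, "absolute") == ACTIVE_IN_ALTERATION
        assert _classify(-0.7, 0.02, 0.5, 0.1, "signed") is None

    def test_identical_in_both_classes_is_not_differential(self, rng):
        cohort = _planted_cohort(rng)
        # partner perfectly tracks the PDSG everywhere
        cohort.expr.iloc[2] = cohort.expr.iloc[0] * 1.5
        edges = diff_coex_edges(cohort, ["G0000"])
        assert "G0002" not in {e.partner for e in edges}

    def test_class_swap_symmetry(self, rng):
        r_alt, r_non = rng.uniform(-1, 1, 20), rng.uniform(-1, 1, 20)
        swap = {ACTIVE_IN_ALTERATION: ACTIVE_IN_NON_ALTERATION,
                ACTIVE_IN_NON_ALTERATION: ACTIVE_IN_ALTERATION}
        for a, b in zip(r_alt, r_non):
            direct = _classify(a, b, 0.5, 0.1, "absolute")
            swapped = _classify(b, a, 0.5, 0.1, "absolute")
            assert swapped == (swap[direct] if direct else None)

    def test_small_groups_skipped(self, rng):
        cohort = _planted_cohort(rng)
        edges = diff_coex_edges(cohort, ["G0000"], min_group=100)
        assert edges == []

    def test_missing_pdsg_is_error(self, tiny_cohort):
        with pytest.raises(KeyError):
            diff_coex_edges(tiny_cohort, ["NOPE"])

    def test_planted_recall_and_precision(self):
        """Balanced classes, 20 alteration-active and 5 non-alteration-active
        planted partners at |r| = 0.8: edge detection recovers the planted
        set at >= 0.9 recall and precision."""
        genes = ["G0000"]
        cfg = SimConfig(
            n_samples=600, n_genes=80, seed=3,
            blocks=(BlockSpec(n_genes=1, amplified_fraction=0.5),),
            planted_pdsg=(PlantedGene("G0000", 2.0, 0.0),),
            planted_partners=(
                PartnerSpec("G0000", 20, 0.8, ACTIVE_IN_ALTERATION),
                PartnerSpec("G0000", 5, 0.8, ACTIVE_IN_NON_ALTERATION),
            ),
        )
        cohort = simulate_cohort(cfg)
        truth = {(p, "G0000") for p in cohort.planted_partners["G0000"]}
        edges = diff_coex_edges(cohort, genes)
        detected = {(e.partner, e.pdsg) for e in edges}
        tp = len(truth & detected)
        recall = tp / len(truth)
        precision = tp / len(detected) if detected else 0.0
        assert recall >= 0.9
        assert precision >= 0.9


def union_find_components(edges):
    """Independent union-find oracle for connected-component counting."""
    parent = {}

    def find(u):
        parent.setdefault(u, u)
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for a, b in edges:
        parent[find(a)] = find(b)
    return len({find(u) for u in parent})


class TestBuildNetwork:
    def test_empty_network(self):
        net = build_network([])
        assert net.degree == {} and net.n_components == 0

    def test_star(self):
        edges = [DiffCoexEdge("P", f"X{i}", 0.8, 0.0, ACTIVE_IN_ALTERATION)
                 for i in range(5)]
        net = build_network(edges)
        assert net.degree["P"] == 5
        assert all(net.degree[f"X{i}"] == 1 for i in range(5))
        assert net.n_components == 1
        assert net.edge_counts_by_class()[ACTIVE_IN_ALTERATION] == 5

    def test_component_count_matches_union_find(self, rng):
        pairs = {tuple(sorted(rng.choice(30, size=2, replace=False)))
                 for _ in range(40)}
        edges = [DiffCoexEdge(f"N{a}", f"N{b}", 0.7, 0.0,
                              ACTIVE_IN_ALTERATION) for a, b in pairs]
        net = build_network(edges)
        assert net.n_components == union_find_components(
            [(e.pdsg, e.partner) for e in edges])

    def test_annotations_applied(self):
        edges = [DiffCoexEdge("P", "X", 0.8, 0.0, ACTIVE_IN_ALTERATION)]
        net = build_network(edges, annotations={"driver": ["X", "ZZZ"]})
        assert net.graph.nodes["X"]["driver"] is True

    def test_sif_round_trip(self, tmp_path, rng):
        cohort = _planted_cohort(rng)
        edges = diff_coex_edges(cohort, ["G0000"])
        net = build_network(edges)
        write_sif(net, tmp_path / "net.sif")
        lines = [l for l in (tmp_path / "net.sif").read_text().splitlines() if l]
        assert len(lines) == net.graph.number_of_edges()


class TestCoAlteration:
    def test_identical_rows_give_unit_matrix(self, rng):
        row = rng.normal(size=50)
        cohort = build_cohort(np.tile(row, (3, 1)), np.ones((3, 50)) + 1,
                              range(1, 51), [1] * 50)
        res = co_alteration_matrix(cohort, list(cohort.scna.index))
        assert res.matrix.to_numpy() == pytest.approx(np.ones((3, 3)))
        assert res.mean_offdiag == pytest.approx(1.0)

    def test_independent_rows_uncorrelated(self, rng):
        cohort = build_cohort(rng.normal(size=(2, 500)), np.ones((2, 500)),
                              range(1, 501), [1] * 500)
        res = co_alteration_matrix(cohort, list(cohort.scna.index))
        assert abs(res.matrix.iloc[0, 1]) < 0.2

    def test_symmetry(self, rng):
        cohort = build_cohort(rng.normal(size=(4, 60)), np.ones((4, 60)),
                              range(1, 61), [1] * 60)
        res = co_alteration_matrix(cohort, list(cohort.scna.index))
        m = res.matrix.to_numpy()
        assert m == pytest.approx(m.T)

    def test_constant_row_flagged(self, rng):
        scna = rng.normal(size=(3, 40))
        scna[1] = 0.0
        cohort = build_cohort(scna, np.ones((3, 40)), range(1, 41), [1] * 40)
        res = co_alteration_matrix(cohort, list(cohort.scna.index))
        assert res.excluded == ["G0001"]
        assert not np.isnan(res.mean_offdiag)

    def test_planted_block_highly_co_altered(self):
        cfg = SimConfig(
            n_samples=300, n_genes=8, seed=9,
            blocks=(BlockSpec(n_genes=6, amplified_fraction=0.4,
                              noise_sd=0.05),),
        )
        cohort = simulate_cohort(cfg)
        res = co_alteration_matrix(cohort, [f"G{i:04d}" for i in range(6)])
        assert res.mean_offdiag > 0.95
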