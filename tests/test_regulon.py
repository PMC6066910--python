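"""Interaction parsing, regulon set algebra, signed scoring, network assembly."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonet.regulon import (
    InteractionDatabase,
    InteractionParseError,
    Regulon,
    UnknownRegulatorError,
    build_network,
    common_regulators,
    load_interactions,
    overlap_pvalues,
    regulators_of,
    regulon_of,
    score_contrast,
    score_regulon,
)
from conftest import make_de_result


class TestLoading:
    def test_tsv_deduplicates(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text("regulator\ttarget\tsource\nGATA2\tKLF1\tx\nGATA2\tKLF1\ty\n")
        db = load_interactions(path, format="tsv")
        assert db.edges == frozenset({("GATA2", "KLF1")})

    def test_sif_multi_target_line(self, tmp_path):
        path = tmp_path / "i.sif"
        path.write_text("GATA2 regulates KLF1 NFE2\n")
        db = load_interactions(path, format="sif")
        assert db.edges == frozenset({("GATA2", "KLF1"), ("GATA2", "NFE2")})

    def test_self_edge_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "i.tsv"
        path.write_text("GATA2\tGATA2\nGATA2\tKLF1\n")
        with caplog.at_level("WARNING"):
            db = load_interactions(path)
        assert db.edges == frozenset({("GATA2", "KLF1")})
        assert "self-edge" in caplog.text

    def test_symbols_uppercased(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text("gata2\tklf1\n")
        assert load_interactions(path).edges == frozenset({("GATA2", "KLF1")})

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text("GATA2\tKLF1\nJUSTONE\n")
        with pytest.raises(InteractionParseError, match=":2"):
            load_interactions(path)

    def test_empty_file_valid_with_warning(self, tmp_path, caplog):
        path = tmp_path / "i.tsv"
        path.write_text("")
        with caplog.at_level("WARNING"):
            db = load_interactions(path)
        assert len(db) == 0


class TestSetAlgebra:
    def test_regulon_of(self, toy_db):
        assert regulon_of(toy_db, "A") == {"G1", "G2"}
        assert regulon_of(toy_db, "B") == {"G1"}

    def test_regulon_of_unknown_tf(self, toy_db):
        with pytest.raises(UnknownRegulatorError):
            regulon_of(toy_db, "NOPE")

    def test_regulators_of(self, toy_db):
        assert regulators_of(toy_db, "G1") == {"A", "B"}
        assert regulators_of(toy_db, "G9") == set()

    def test_common_regulators(self, toy_db):
        assert common_regulators(toy_db, ["G1", "G2"]) == {"A"}
        assert common_regulators(toy_db, ["G1", "G4"]) == set()
        with pytest.raises(ValueError):
            common_regulators(toy_db, [])

    @settings(deadline=None, max_examples=50)
    @given(st.sets(st.sampled_from(["G1", "G2", "G3", "G4", "G9"]), min_size=1))
    def test_singleton_identity_and_order_invariance(self, genes):
        edges = frozenset(
            {("A", "G1"), ("A", "G2"), ("B", "G1"), ("C", "G2"), ("C", "G3"), ("C", "G4")}
        )
        db = InteractionDatabase(edges=edges)
        genes = sorted(genes)
        assert common_regulators(db, genes) == common_regulators(db, genes[::-1])
        if len(genes) == 1:
            assert common_regulators(db, genes) == regulators_of(db, genes[0])


def exhaustive_upper_tail(n_universe, n_successes, n_drawn, k):
    """Enumerate every possible draw of the regulon; count overlaps >= k."""
    universe = range(n_universe)
    successes = set(range(n_successes))
    hits = total = 0
    for draw in itertools.combinations(universe, n_drawn):
        total += 1
        if len(successes & set(draw)) >= k:
            hits += 1
    return hits / total


class TestScoring:
    def test_worked_hypergeometric_example(self, de_20genes):
        # universe 20, up set 5, regulon 4 in universe, overlap 3:
        # P(X>=3) = (C(5,3)C(15,1) + C(5,4)) / C(20,4) = 155/4845
        reg = Regulon("TFX", frozenset({"G1", "G2", "G3", "G10"}))
        score = score_regulon(reg, de_20genes)
        assert score.k_up == 3
        assert score.p_up == pytest.approx(155 / 4845, abs=1e-12)
        assert score.p_up == pytest.approx(
            exhaustive_upper_tail(20, 5, 4, 3), abs=1e-12
        )

    def test_degenerate_universe_forced_overlap(self):
        de = make_de_result(["G1", "G2", "G3"], up=["G1", "G2", "G3"])
        score = score_regulon(Regulon("TFX", frozenset({"G1", "G2", "G3"})), de)
        assert score.k_up == 3
        assert score.p_up == 1.0

    def test_null_de_gives_none_direction(self, de_20genes):
        de = make_de_result([f"G{i}" for i in range(1, 21)])  # everything nc
        score = score_regulon(Regulon("TFX", frozenset({"G1", "G2", "G3"})), de)
        assert score.dominant_direction == "none"

    def test_small_regulon_skipped(self, de_20genes):
        reg = Regulon("TFX", frozenset({"G1", "ABSENT1", "ABSENT2"}))
        assert score_regulon(reg, de_20genes, min_regulon_size=3) is None

    def test_invariant_to_genes_outside_universe(self, de_20genes):
        inside = Regulon("TFX", frozenset({"G1", "G2", "G3", "G10"}))
        padded = Regulon("TFX", frozenset({"G1", "G2", "G3", "G10", "ZZZ1", "ZZZ2"}))
        s1, s2 = score_regulon(inside, de_20genes), score_regulon(padded, de_20genes)
        assert (s1.p_up, s1.p_down, s1.p_depletion) == (s2.p_up, s2.p_down, s2.p_depletion)

    def test_depletion_dominates_when_regulon_avoids_de(self):
        universe = [f"G{i}" for i in range(1, 31)]
        de = make_de_result(universe, up=universe[:15])
        reg = Regulon("TFX", frozenset(universe[15:30]))  # zero overlap with DE
        score = score_regulon(reg, de)
        assert score.dominant_direction == "depleted"
        assert score.p_depletion < score.p_up


class TestScoreContrast:
    def test_all_nc_contrast_scores_zero_nothing_selected(self, toy_db):
        de = make_de_result([f"G{i}" for i in range(1, 5)] + ["A", "B", "C"])
        scores = score_contrast(toy_db, de, min_regulon_size=1)
        assert scores
        assert all(s.signed_score == 0.0 for s in scores)
        assert not any(s.selected for s in scores)

    def test_sign_convention_matches_dominant_direction(self):
        universe = [f"G{i}" for i in range(1, 41)]
        de = make_de_result(universe, up=universe[:6], down=universe[6:12])
        edges = set()
        edges |= {("TFUP", g) for g in universe[:6]}
        edges |= {("TFDN", g) for g in universe[6:12]}
        edges |= {("TFBG", g) for g in universe[20:28]}
        db = InteractionDatabase(edges=frozenset(edges))
        scores = score_contrast(db, de)
        by_tf = {s.tf_id: s for s in scores}
        assert by_tf["TFUP"].dominant_direction == "up"
        assert by_tf["TFUP"].signed_score > 0
        assert by_tf["TFDN"].dominant_direction == "down"
        assert by_tf["TFDN"].signed_score < 0
        for s in scores:
            assert (s.signed_score > 0) == (s.dominant_direction == "up")

    def test_deterministic_ordering_by_q_then_tf(self, toy_db):
        de = make_de_result(["G1", "G2", "G3", "G4"], up=["G1", "G2"])
        scores = score_contrast(toy_db, de, min_regulon_size=1)
        keys = [(s.q_value, s.tf_id) for s in scores]
        assert keys == sorted(keys)


class TestNetwork:
    def _scored(self):
        universe = [f"G{i}" for i in range(1, 41)] + ["KLF1", "NFE2", "GFI1B", "GATA2"]
        de = make_de_result(universe, up=universe[:8] + ["KLF1"])
        edges = {("GATA2", "KLF1"), ("GATA2", "NFE2"), ("KLF1", "NFE2"), ("NFE2", "G39")}
        edges |= {("KLF1", g) for g in universe[:8]}
        edges |= {("NFE2", g) for g in universe[:8]}
        edges |= {("GFI1B", g) for g in universe[20:26]}
        db = InteractionDatabase(edges=frozenset(edges))
        scores = score_contrast(db, de)
        return db, scores, de

    def test_edges_restricted_to_included_nodes(self):
        db, scores, de = self._scored()
        net = build_network(db, scores, de, anchors={"GATA2"})
        selected = {s.tf_id for s in scores if s.selected}
        assert set(net.nodes) == selected | {"GATA2"}
        assert ("NFE2", "G39") not in net.edges  # G39 not a node
        if "KLF1" in net.nodes:
            assert ("GATA2", "KLF1") in net.edges

    def test_node_count_is_selected_union_anchors(self):
        db, scores, de = self._scored()
        net = build_network(db, scores, de, anchors={"GATA2"})
        assert net.number_of_nodes() == len({s.tf_id for s in scores if s.selected} | {"GATA2"})

    def test_zero_lfc_tf_is_nc(self):
        db, scores, de = self._scored()
        net = build_network(db, scores, de)
        assert net.nodes["GATA2"]["size_category"] == "NC"  # lfc 0 in toy table

    def test_missing_anchor_included_with_warning(self, caplog):
        db, scores, de = self._scored()
        with caplog.at_level("WARNING"):
            net = build_network(db, scores, de, anchors={"GATA2", "RUNX1"})
        assert "RUNX1" in net.nodes
        assert math.isnan(net.nodes["RUNX1"]["log2fc"])


def test_permutation_oracle_small_instances():
    """Hypergeometric tails vs a 20,000-draw permutation on random cases."""
    rng = np.random.default_rng(2024)
    n_draws = 20_000
    for _ in range(10):
        n_universe = int(rng.integers(15, 51))
        n_de = int(rng.integers(2, n_universe // 2))
        m = int(rng.integers(3, n_universe // 2))
        universe = np.arange(n_universe)
        members = set(rng.choice(universe, size=m, replace=False).tolist())
        draws = np.array(
            [rng.choice(universe, size=n_de, replace=False) for _ in range(n_draws)]
        )
        overlaps = np.array([len(members & set(d.tolist())) for d in draws])
        k = int(np.percentile(overlaps, 75))
        p_upper, p_lower = overlap_pvalues(n_universe, n_de, m, k)
        emp_upper = (overlaps >= k).mean()
        emp_lower = (overlaps <= k).mean()
        for p, emp in [(p_upper, emp_upper), (p_lower, emp_lower)]:
            se = math.sqrt(max(p * (1 - p), 1e-12) / n_draws)
            assert abs(emp - p) <= 3 * se + 1e-9
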