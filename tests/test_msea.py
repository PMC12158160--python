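from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ks_signed
from isoenrich import (AnnotationTable, BootstrapDraw, IntensityMatrix,
                       IonAnnotation, RankedList, SamplerConfig, SetCollection,
                       aggregate_terms, bootstrap_msea, enrichment_score,
                       msea_permutation_p, msea_single, rank_metric)
from isoenrich.msea import read_conditions, read_intensity_matrix


def _matrix(values, mids=None, n_a=None):
    values = np.asarray(values, dtype=float)
    mids = mids or [f"ion{i}" for i in range(values.shape[0])]
    n_a = n_a if n_a is not None else values.shape[1] // 2
    cids = [f"c{i}" for i in range(values.shape[1])]
    conds = {c: ("A" if i < n_a else "B") for i, c in enumerate(cids)}
    return IntensityMatrix(values, tuple(mids), tuple(cids), conds)


class TestIntensityMatrix:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1.0, -1.0]])

    def test_missing_condition_label_rejected(self):
        with pytest.raises(ValueError):
            IntensityMatrix(np.ones((1, 2)), ("m",), ("c0", "c1"), {"c0": "A"})

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            _matrix(np.ones((2, 2)), mids=["m", "m"])


class TestRankMetric:
    def test_difference_of_means_arithmetic(self):
        m = _matrix([[4, 4, 2, 2], [1, 1, 1, 1]])
        ranked = rank_metric(m, ("A", "B"), "diff")
        assert dict(zip(ranked.ids, ranked.metric))["ion0"] == pytest.approx(2.0)

    @pytest.mark.parametrize("metric", ["diff", "log2fc"])
    def test_identical_groups_give_zero(self, metric):
        m = _matrix([[3, 5, 3, 5], [2, 2, 2, 2]])
        ranked = rank_metric(m, ("A", "B"), metric)
        assert ranked.metric == pytest.approx([0.0, 0.0], abs=1e-9)

    @pytest.mark.parametrize("metric", ["diff", "log2fc", "tstat", "snr"])
    def test_shifted_metabolite_ranks_first(self, metric):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, size=(3, 8))
        base[1, :4] += 10.0  # ion1 up-shifted in condition A
        ranked = rank_metric(_matrix(base), ("A", "B"), metric)
        assert ranked.ids[0] == "ion1"

    @pytest.mark.parametrize("metric", ["diff", "log2fc", "tstat", "snr"])
    def test_contrast_antisymmetry_reverses_ranking(self, metric):
        rng = np.random.default_rng(1)
        m = _matrix(rng.uniform(1, 10, size=(6, 10)))
        fwd = rank_metric(m, ("A", "B"), metric)
        rev = rank_metric(m, ("B", "A"), metric)
        fwd_vals = dict(zip(fwd.ids, fwd.metric))
        rev_vals = dict(zip(rev.ids, rev.metric))
        for ion in fwd.ids:
            assert rev_vals[ion] == pytest.approx(-fwd_vals[ion], rel=1e-9, abs=1e-12)
        assert list(rev.ids) == list(reversed(fwd.ids))  # no ties here

    def test_zero_variance_warns_and_zeroes(self, caplog):
        m = _matrix([[5, 5, 1, 1], [1, 2, 3, 4]])
        with caplog.at_level("WARNING"):
            ranked = rank_metric(m, ("A", "B"), "tstat")
        assert dict(zip(ranked.ids, ranked.metric))["ion0"] == 0.0
        assert "zero-variance" in caplog.text

    def test_errors(self):
        m = _matrix(np.ones((2, 4)))
        with pytest.raises(ValueError, match="unknown metric"):
            rank_metric(m, ("A", "B"), "median")
        with pytest.raises(ValueError, match="absent"):
            rank_metric(m, ("A", "Z"), "diff")
        one_per_group = _matrix(np.ones((2, 2)), n_a=1)
        with pytest.raises(ValueError, match="2 cells"):
            rank_metric(one_per_group, ("A", "B"), "tstat")


def _ranked(n, members_at=None):
    ids = tuple(f"m{i:02d}" for i in range(n))
    metric = np.linspace(3.0, -3.0, n)
    return RankedList(ids, metric), {ids[i] for i in (members_at or [])}


class TestEnrichmentScore:
    def test_matches_ks_oracle_on_all_small_subsets(self):
        ranked, _ = _ranked(8)
        for size in range(1, 8):
            for combo in itertools.combinations(range(8), size):
                members = {ranked.ids[i] for i in combo}
                es, _ = enrichment_score(ranked, members, weight_exponent=0.0)
                mask = [i in combo for i in range(8)]
                assert es == pytest.approx(ks_signed(mask), rel=1e-12, abs=1e-12)

    def test_bottom_concentration_negative(self):
        ranked, members = _ranked(10, members_at=[7, 8, 9])
        es, _ = enrichment_score(ranked, members, weight_exponent=0.0)
        assert es < 0

    def test_set_and_complement_antisymmetric(self):
        # symmetric metric values, unweighted: complement flips the sign exactly
        ranked, members = _ranked(10, members_at=[0, 1, 5, 6])
        comp = set(ranked.ids) - members
        es_m, _ = enrichment_score(ranked, members, weight_exponent=0.0)
        es_c, _ = enrichment_score(ranked, comp, weight_exponent=0.0)
        assert es_c == pytest.approx(-es_m, rel=1e-12)

    def test_leading_edge_counts_members_before_peak(self):
        ranked, members = _ranked(10, members_at=[0, 1, 2])
        es, lead = enrichment_score(ranked, members, weight_exponent=0.0)
        assert es > 0 and lead == 3

    def test_es_bounded_by_one(self, rng):
        ranked, _ = _ranked(20)
        for _ in range(50):
            members = set(rng.choice(ranked.ids, size=6, replace=False))
            es, _ = enrichment_score(ranked, members, weight_exponent=1.0)
            assert -1.0 <= es <= 1.0

    def test_empty_or_full_membership_rejected(self):
        ranked, _ = _ranked(5)
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"}, 0.0)
        with pytest.raises(ValueError):
            enrichment_score(ranked, set(ranked.ids), 0.0)

    @given(st.sets(st.integers(0, 11), min_size=1, max_size=11))
    @settings(deadline=None, max_examples=150)
    def test_unweighted_equals_ks_property(self, idxs):
        ranked, _ = _ranked(12)
        members = {ranked.ids[i] for i in idxs}
        es, _ = enrichment_score(ranked, members, weight_exponent=0.0)
        mask = [i in idxs for i in range(12)]
        assert es == pytest.approx(ks_signed(mask), rel=1e-12, abs=1e-12)


class TestPermutationP:
    def test_minimum_p_for_maximal_concentration(self):
        # top-|S| members under a strong gradient: no permuted set can beat
        # perfect separation, and an exact tie needs the one-in-C(50,10)
        # identical subset
        ranked, members = _ranked(50, members_at=range(10))
        p = msea_permutation_p(ranked, members, n_perm=999,
                               rng=np.random.default_rng(3), weight_exponent=0.0)
        assert p == pytest.approx(1 / 1000)

    def test_p_respects_lower_bound_and_unity_cap(self, rng):
        ranked, members = _ranked(20, members_at=[2, 9, 15])
        p = msea_permutation_p(ranked, members, n_perm=199, rng=rng)
        assert 1 / 200 <= p <= 1.0

    def test_small_n_perm_rejected(self, rng):
        ranked, members = _ranked(10, members_at=[0, 1])
        with pytest.raises(ValueError):
            msea_permutation_p(ranked, members, n_perm=99, rng=rng)


def _msea_setup():
    universe = [f"M{i:02d}" for i in range(40)]
    table = AnnotationTable(tuple(
        IonAnnotation(f"ion{i}", (f"M{i:02d}",)) for i in range(20)
    ))
    sets = SetCollection.build(
        {"top": [f"M{i:02d}" for i in range(5)],
         "spread": [f"M{i:02d}" for i in (3, 9, 14, 19)]},
        universe=universe)
    ids = tuple(f"ion{i}" for i in range(20))
    ranked = RankedList(ids, np.linspace(2.0, -2.0, 20))
    draw = BootstrapDraw({f"ion{i}": f"M{i:02d}" for i in range(20)})
    return table, sets, ranked, draw


class TestMseaSingle:
    def test_deterministic_given_permutation_substream(self):
        _, sets, ranked, draw = _msea_setup()
        a = msea_single(draw, ranked, sets, n_perm=150, rng=np.random.default_rng(7))
        b = msea_single(draw, ranked, sets, n_perm=150, rng=np.random.default_rng(7))
        assert a == b

    def test_q_adjusts_across_tested_terms(self):
        _, sets, ranked, draw = _msea_setup()
        rows = msea_single(draw, ranked, sets, n_perm=150, rng=np.random.default_rng(7))
        assert {r.term for r in rows} == {"top", "spread"}
        assert all(r.q >= r.p for r in rows)

    def test_vanishing_membership_reduces_effective_bootstraps(self):
        _, sets, ranked, _ = _msea_setup()
        full = BootstrapDraw({f"ion{i}": f"M{i:02d}" for i in range(20)})
        # sampled molecules all outside "top": membership 0 < min_term_size
        vanished = BootstrapDraw(
            {f"ion{i}": f"M{(i + 20) % 40:02d}" for i in range(20)})
        rows_full = msea_single(full, ranked, sets, n_perm=150,
                                rng=np.random.default_rng(1))
        rows_gone = msea_single(vanished, ranked, sets, n_perm=150,
                                rng=np.random.default_rng(2))
        assert {r.term for r in rows_gone} == set()
        agg = aggregate_terms([rows_full, rows_gone], fdr_cutoff=0.1)
        by = {a.term: a for a in agg}
        assert by["top"].n_effective_bootstraps == 1
        assert by["top"].n_bootstraps == 2


class TestBootstrapMsea:
    def test_unambiguous_bootstraps_share_ranking_and_membership(self):
        table, sets, _, _ = _msea_setup()
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 2, size=(20, 8))
        vals[:5, :4] += 6.0  # "top" members up in condition A
        cids = tuple(f"c{i}" for i in range(8))
        conds = {c: ("A" if i < 4 else "B") for i, c in enumerate(cids)}
        matrix = IntensityMatrix(vals, table.ion_ids, cids, conds)
        ranked, per = bootstrap_msea(table, matrix, ("A", "B"), sets,
                                     SamplerConfig(5, 11), n_perm=150)
        assert set(ranked.ids[:5]) == {f"ion{i}" for i in range(5)}
        # same membership every draw; only the permutation stream varies
        assert all([r.es for r in rows] == [r.es for r in per[0]] for rows in per)


class TestMatrixIO:
    def test_dense_round_trip(self, tmp_path):
        import pandas as pd
        vals = np.arange(6, dtype=float).reshape(2, 3)
        df = pd.DataFrame(vals, index=["m1", "m2"], columns=["c1", "c2", "c3"])
        path = tmp_path / "mat.tsv"
        df.to_csv(path, sep="\t")
        conds = {"c1": "A", "c2": "A", "c3": "B"}
        m = read_intensity_matrix(path, conds)
        assert m.metabolite_ids == ("m1", "m2")
        assert np.allclose(m.values, vals)

    def test_mtx_with_label_files(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        vals = np.array([[1.0, 0.0], [0.0, 3.0]])
        mmwrite(tmp_path / "mat.mtx", csr_matrix(vals))
        (tmp_path / "rows.txt").write_text("m1\nm2\n")
        (tmp_path / "cols.txt").write_text("c1\nc2\n")
        m = read_intensity_matrix(tmp_path / "mat.mtx", {"c1": "A", "c2": "B"},
                                  row_labels=tmp_path / "rows.txt",
                                  col_labels=tmp_path / "cols.txt")
        assert np.allclose(m.values, vals)

    def test_conditions_reader_with_and_without_header(self, tmp_path):
        with_h = tmp_path / "c1.tsv"
        with_h.write_text("cell_id\tcondition\nc1\tA\nc2\tB\n")
        without = tmp_path / "c2.tsv"
        without.write_text("c1\tA\nc2\tB\n")
        assert read_conditions(with_h) == read_conditions(without) == {"c1": "A", "c2": "B"}
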