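"""Quality control, relative quantification, DE and receptor classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropod import qpcr, synthetic


def brute_force_bh(pvals):
    """Independent Benjamini-Hochberg: sort, adjust, reversed cumulative min."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] / (np.arange(1, n + 1) / n)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _toy_matrix():
    genes = ["Gapdh", "Actb1", "Slc5a1"]
    cq = pd.DataFrame(
        [
            [20.0, 21.0, 25.0],
            [np.nan, 22.0, 26.0],
            [np.nan, np.nan, 27.0],  # lacks both housekeeping genes
            [19.0, np.nan, np.nan],
            [np.nan, np.nan, np.nan],  # lacks both housekeeping genes
        ],
        index=[f"c{i}" for i in range(5)],
        columns=genes,
    )
    quality = pd.DataFrame(1.0, index=cq.index, columns=genes)
    meta = pd.DataFrame(
        {"group": ["GFP+"] * 3 + ["GFP-"] * 2, "mouse_id": ["m1"] * 5}, index=cq.index
    )
    return qpcr.CqMatrix(cq=cq, quality=quality, metadata=meta)


class TestQualityFilter:
    def test_cells_without_housekeeping_are_dropped_and_named(self):
        filtered, report = qpcr.quality_filter(_toy_matrix())
        assert filtered.cq.shape[0] == 3
        assert set(report["cell"]) == {"c2", "c4"}

    def test_identity_when_everything_passes(self):
        m = _toy_matrix()
        keep = m.cq.index[[0, 1, 3]]
        m = qpcr.CqMatrix(m.cq.loc[keep], m.quality.loc[keep], m.metadata.loc[keep])
        filtered, report = qpcr.quality_filter(m)
        assert report.empty
        pd.testing.assert_frame_equal(filtered.cq, m.cq)

    def test_low_quality_wells_become_undetected(self):
        m = _toy_matrix()
        m.quality.loc["c0", "Slc5a1"] = 0.5
        filtered, _ = qpcr.quality_filter(m)
        assert np.isnan(filtered.cq.loc["c0", "Slc5a1"])
        # threshold is inclusive at exactly 0.65
        m.quality.loc["c1", "Slc5a1"] = 0.65
        filtered, _ = qpcr.quality_filter(m)
        assert not np.isnan(filtered.cq.loc["c1", "Slc5a1"])

    def test_idempotent(self):
        once, _ = qpcr.quality_filter(_toy_matrix())
        twice, report = qpcr.quality_filter(once)
        assert report.empty
        pd.testing.assert_frame_equal(once.cq, twice.cq)

    def test_empty_matrix_rejected(self):
        empty = pd.DataFrame(columns=["Gapdh", "Actb1"])
        with pytest.raises(ValueError, match="empty"):
            qpcr.quality_filter(
                qpcr.CqMatrix(empty, empty.copy(), pd.DataFrame(index=empty.index))
            )


class TestCqToRq:
    @pytest.mark.parametrize(
        "cq,expected", [(34.0, 1.0), (24.0, 1024.0), (np.nan, 0.5), (35.0, 0.5 ** 1)]
    )
    def test_point_values(self, cq, expected):
        assert qpcr.cq_to_rq(cq) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=5.0, max_value=40.0), min_size=1, max_size=50)
    )
    @settings(max_examples=50, deadline=None)
    def test_log2_identity_and_monotonicity(self, cqs):
        cqs = np.asarray(cqs)
        rq = qpcr.cq_to_rq(cqs)
        np.testing.assert_allclose(np.log2(rq), 34.0 - cqs, rtol=1e-12)
        order = np.argsort(cqs)
        assert np.all(np.diff(rq[order]) <= 0)  # strictly decreasing in Cq


class TestNormalizePerGene:
    def test_constant_gene_becomes_zeros_with_warning(self):
        df = pd.DataFrame({"g1": [1.0, 1.0, 1.0], "g2": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="g1"):
            z = qpcr.normalize_per_gene(df)
        np.testing.assert_allclose(z["g1"], 0.0)

    def test_two_cell_gene_maps_to_plus_minus_one(self):
        # population-s.d. convention (ddof=0): (a, b) -> (-1, +1)
        z = qpcr.normalize_per_gene(pd.DataFrame({"g": [3.0, 7.0]}))
        np.testing.assert_allclose(z["g"], [-1.0, 1.0])

    def test_generated_matrix_columns_are_standardized(self):
        m, _ = synthetic.gen_cq_matrix(n_cells_per_group=(20, 15), seed=4)
        z = qpcr.normalize_per_gene(qpcr.rq_matrix(m).log2)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, rtol=1e-9)


class TestDifferentialExpression:
    def test_identical_groups_give_unit_fold_change_nothing_significant(self):
        cq = pd.DataFrame(
            np.tile(np.linspace(20, 30, 6)[:, None], (2, 4)),
            index=[f"c{i}" for i in range(12)],
            columns=["g1", "g2", "g3", "g4"],
        )
        meta = pd.DataFrame({"group": ["A"] * 6 + ["B"] * 6}, index=cq.index)
        rq = qpcr.rq_matrix(
            qpcr.CqMatrix(cq, pd.DataFrame(1.0, index=cq.index, columns=cq.columns), meta)
        )
        de = qpcr.differential_expression(rq, groups=("A", "B"))
        np.testing.assert_allclose(de["fold_change"], 1.0)
        assert not de["significant"].any()

    def test_planted_effect_detected_with_correct_fold_change(self):
        m, _ = synthetic.gen_cq_matrix(
            n_cells_per_group=(60, 30), de_genes={"Syn1": 2.0}, seed=3
        )
        de = qpcr.differential_expression(qpcr.rq_matrix(m))
        assert de.loc["Syn1", "significant"]
        assert de.loc["Syn1", "fold_change"] == pytest.approx(4.0, rel=0.25)
        others = de.drop("Syn1")
        assert not others["significant"].any()

    def test_q_values_match_brute_force_bh(self):
        m, _ = synthetic.gen_cq_matrix(
            n_cells_per_group=(15, 15),
            genes=tuple(f"g{i}" for i in range(40)) + qpcr.HOUSEKEEPING_GENES,
            dropout_prob=0.2,
            seed=12,
        )
        de = qpcr.differential_expression(qpcr.rq_matrix(m))
        np.testing.assert_allclose(
            de["q_value"], brute_force_bh(de["p_value"]), rtol=0, atol=1e-12
        )

    def test_fold_direction_agrees_with_t_sign(self):
        m, _ = synthetic.gen_cq_matrix(
            n_cells_per_group=(25, 25),
            de_genes={"Syn1": 1.5, "Snap25": -1.0},
            seed=7,
        )
        de = qpcr.differential_expression(
            qpcr.rq_matrix(m), fold_change_basis="log2"
        )
        moved = de[np.abs(np.log2(de["fold_change"])) > 1e-9]
        assert (np.sign(np.log2(moved["fold_change"])) == np.sign(moved["t"])).all()

    def test_single_cell_group_rejected(self):
        m, _ = synthetic.gen_cq_matrix(n_cells_per_group=(5, 1), seed=1)
        with pytest.raises(ValueError, match="two cells"):
            qpcr.differential_expression(qpcr.rq_matrix(m))


class TestReceptorClasses:
    @staticmethod
    def _matrix_from_detection(detect_a, detect_b, n_mice=1):
        n = len(detect_a)
        cq = pd.DataFrame({
            "Slc5a1": [25.0 if d else np.nan for d in detect_a],
            "Tas1r3": [25.0 if d else np.nan for d in detect_b],
            "Gapdh": 20.0,
            "Actb1": 20.0,
        }, index=[f"c{i}" for i in range(n)])
        meta = pd.DataFrame({
            "group": "GFP+",
            "mouse_id": [f"m{i % n_mice + 1}" for i in range(n)],
        }, index=cq.index)
        return qpcr.CqMatrix(cq, pd.DataFrame(1.0, index=cq.index, columns=cq.columns), meta)

    def test_all_cells_both_genes(self):
        m = self._matrix_from_detection([True] * 6, [True] * 6)
        cls = qpcr.classify_receptors(m)
        assert cls.mean_pct["both"] == pytest.approx(100.0)
        assert cls.sem_pct is None  # single mouse

    def test_no_cell_either_gene(self):
        m = self._matrix_from_detection([False] * 6, [False] * 6)
        cls = qpcr.classify_receptors(m)
        assert cls.mean_pct["neither"] == pytest.approx(100.0)

    def test_per_mouse_percentages_sum_to_100(self):
        m, _ = synthetic.gen_receptor_cells(n_cells_per_mouse=40, seed=5)
        cls = qpcr.classify_receptors(m)
        np.testing.assert_allclose(cls.per_mouse_pct.sum(axis=1), 100.0, atol=0.1)

    def test_designed_fractions_recovered_within_sampling_error(self):
        design = (0.20, 0.60, 0.01, 0.19)
        m, truth = synthetic.gen_receptor_cells(
            class_fracs=design, n_cells_per_mouse=50, n_mice=3, seed=5
        )
        cls = qpcr.classify_receptors(m)
        # mean percentages equal the designed multinomial counts exactly
        for label, frac in zip(["neither", "a_only", "b_only", "both"], design):
            counts = [truth.labels["per_mouse_counts"][f"m{i+1}"][label] for i in range(3)]
            expected_pct = 100.0 * np.mean(counts) / 50.0
            assert cls.mean_pct[label] == pytest.approx(expected_pct, abs=1e-9)
            # and the design is recovered within multinomial sampling error
            se = 100.0 * np.sqrt(frac * (1 - frac) / (3 * 50))
            assert abs(cls.mean_pct[label] - 100.0 * frac) < 4 * se + 1e-9
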