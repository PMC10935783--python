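import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degstrat import (
    SimulationConfig,
    recovery_report,
    simulate_expression,
    stratify_time_axis,
    stratify_treatment_axis,
    venn_partition,
)

gene_sets = st.sets(st.sampled_from([f"g{i}" for i in range(30)]), max_size=30)


class TestVennPartition:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, ({"g1"}, {"g2", "g3"}, {"g4"})),
            ({"g1"}, {"g1"}, (set(), {"g1"}, set())),
            ({"g1"}, {"g2"}, ({"g1"}, set(), {"g2"})),
            (set(), set(), (set(), set(), set())),
        ],
    )
    def test_set_algebra(self, a, b, expected):
        part = venn_partition(a, b)
        assert (set(part.only_a), set(part.common), set(part.only_b)) == expected

    @given(a=gene_sets, b=gene_sets)
    @settings(max_examples=100)
    def test_completeness_and_disjointness(self, a, b):
        part = venn_partition(a, b)
        assert len(part.only_a) + len(part.common) + len(part.only_b) == len(a | b)
        assert part.only_a | part.common == frozenset(a)
        assert part.only_b | part.common == frozenset(b)

    def test_evenness_bounds(self):
        assert venn_partition({"a"}, {"b"}).evenness() < 1.0
        even = venn_partition({"a", "c"}, {"b", "c"}).evenness()
        assert 0 < even <= 1.0
        assert np.isnan(venn_partition(set(), set()).evenness())


def exact_matrix(counts, effect=2.0, n_rep=4, baseline=8.0):
    """Zero-variance matrix: every replicate equals the exact cell mean.

    In this limit the zero-pooled-variance sign rule makes every DEG call
    deterministic (±inf where cell means differ, 0 where they agree), so
    each planted class lands exactly in its Venn cell.
    """
    import pandas as pd

    from degstrat.io import ExpressionMatrix
    from degstrat.simulate import GroundTruth, _shift

    genes, labels = [], []
    for cls, n in counts.items():
        for i in range(n):
            genes.append(f"{cls}_{i}")
            labels.append(cls)
    truth = GroundTruth(dict(zip(genes, labels)))
    cols, rows, data = [], [], {}
    for arm in ("treated", "control"):
        for day in (2, 7):
            for rep in range(1, n_rep + 1):
                sid = f"{arm}_d{day}_r{rep}"
                cols.append(sid)
                rows.append({"sample_id": sid, "arm": arm, "day": day, "replicate": rep})
                data[sid] = [
                    baseline + _shift(cls, arm, day == 7, effect) for cls in labels
                ]
    em = ExpressionMatrix(pd.DataFrame(data, index=genes), pd.DataFrame(rows))
    return em, truth


ALL_CLASS_COUNTS = {
    "common_time_up": 6, "common_time_down": 6,
    "treated_only_time": 4, "control_only_time": 4,
    "early_up": 5, "early_down": 5, "constant_up": 5, "constant_down": 5,
    "delayed_up": 5, "delayed_down": 5, "null": 10,
}


class TestExactPlantedLimits:
    def test_treatment_axis_cells(self):
        em, truth = exact_matrix(ALL_CLASS_COUNTS)
        up, down = stratify_treatment_axis(em)
        assert truth.genes_of("early_up") == up.only_a
        assert truth.genes_of("constant_up") == up.common
        assert truth.genes_of("early_down") == down.only_a
        assert truth.genes_of("constant_down") == down.common
        # an arm-exclusive day-7 shift is indistinguishable from a delayed
        # treatment effect in the treated-vs-control contrast
        assert up.only_b == truth.genes_of("delayed_up") | truth.genes_of("treated_only_time")
        assert down.only_b == truth.genes_of("delayed_down") | truth.genes_of("control_only_time")

    def test_time_axis_cells(self):
        em, truth = exact_matrix(ALL_CLASS_COUNTS)
        up, down = stratify_time_axis(em)
        assert truth.genes_of("common_time_up") == up.common
        assert truth.genes_of("common_time_down") == down.common
        # treated-arm time contrast also picks up treatment effects that
        # change between the days (early fades: up if early_down; delayed
        # arrives: up if delayed_up); constant effects cancel
        assert up.only_a == (
            truth.genes_of("treated_only_time")
            | truth.genes_of("early_down")
            | truth.genes_of("delayed_up")
        )
        assert down.only_a == truth.genes_of("early_up") | truth.genes_of("delayed_down")
        assert up.only_b == truth.genes_of("control_only_time")
        assert not (truth.genes_of("constant_up") & (up.union | down.union))

    def test_no_gene_in_both_directions(self):
        em, _ = exact_matrix(ALL_CLASS_COUNTS)
        for up, down in (stratify_time_axis(em), stratify_treatment_axis(em)):
            assert not (up.union & down.union)

    def test_recovery_perfect_recall(self):
        em, truth = exact_matrix(ALL_CLASS_COUNTS)
        up, down = stratify_treatment_axis(em)
        rep = recovery_report(up, down, truth, axis="treatment").set_index("gene_class")
        assert (rep["recall"] == 1.0).all()
        # early/constant cells are pure; delayed cells also absorb the
        # arm-exclusive temporal genes by construction
        for cls in ("early_up", "early_down", "constant_up", "constant_down"):
            assert rep.loc[cls, "precision"] == 1.0


@pytest.fixture(scope="module")
def low_noise():
    counts = {
        "common_time_up": 25, "common_time_down": 25,
        "treated_only_time": 10, "control_only_time": 10,
        "early_up": 15, "early_down": 15, "constant_up": 15,
        "constant_down": 15, "delayed_up": 15, "delayed_down": 15,
    }
    cfg = SimulationConfig(
        n_genes=400, planted_counts=counts, noise_sd=0.01,
        baseline_log_mean=8.0, seed=17,
    )
    return simulate_expression(cfg)


class TestLowNoisePlantedInclusions:
    """With tiny but nonzero noise the active-day calls are certain, while the
    inactive-day comparison keeps its scale-invariant null behaviour — so a
    planted early/delayed gene can only ever land in its own cell or common,
    never in the opposite cell or direction."""

    def test_treatment_axis_inclusions(self, low_noise):
        em, truth = low_noise
        up, down = stratify_treatment_axis(em)
        assert truth.genes_of("constant_up") <= up.common
        assert truth.genes_of("constant_down") <= down.common
        assert truth.genes_of("early_up") <= up.only_a | up.common
        assert truth.genes_of("delayed_up") <= up.only_b | up.common
        assert truth.genes_of("early_down") <= down.only_a | down.common
        assert truth.genes_of("delayed_down") <= down.only_b | down.common
        # an early-up gene is certainly up at day 2, so it can never be
        # down-called at day 2 (only its null day 7 can stray)
        assert not (truth.genes_of("early_up") & (down.only_a | down.common))
        # within one comparison up and down are mutually exclusive
        assert not (up.common & down.union)
        assert not (down.common & up.union)
        assert not (up.only_a & down.only_a)
        assert not (up.only_b & down.only_b)

    def test_time_axis_inclusions(self, low_noise):
        em, truth = low_noise
        up, down = stratify_time_axis(em)
        assert truth.genes_of("common_time_up") <= up.common
        assert truth.genes_of("common_time_down") <= down.common
        assert truth.genes_of("treated_only_time") <= up.only_a | up.common
        assert truth.genes_of("control_only_time") <= up.only_b | up.common


class TestRecoveryReport:
    def test_matches_brute_force_confusion(self, small_sim):
        _, em, truth = small_sim
        up, down = stratify_treatment_axis(em)
        rep = recovery_report(up, down, truth, axis="treatment").set_index("gene_class")
        cells = {
            "early_up": up.only_a, "constant_up": up.common, "delayed_up": up.only_b,
            "early_down": down.only_a, "constant_down": down.common,
            "delayed_down": down.only_b,
        }
        for cls, cell in cells.items():
            planted = truth.genes_of(cls)
            tp = sum(1 for g in em.gene_ids if g in cell and g in planted)
            fp = sum(1 for g in em.gene_ids if g in cell and g not in planted)
            fn = sum(1 for g in em.gene_ids if g not in cell and g in planted)
            row = rep.loc[cls]
            assert (row["tp"], row["fp"], row["fn"]) == (tp, fp, fn)
            assert row["precision"] == pytest.approx(tp / (tp + fp))
            assert row["recall"] == pytest.approx(tp / (tp + fn))

    def test_null_only_simulation_reports_nan_recall(self):
        cfg = SimulationConfig(n_genes=200, planted_counts={}, seed=23)
        em, truth = simulate_expression(cfg)
        up, down = stratify_treatment_axis(em)
        rep = recovery_report(up, down, truth, axis="treatment")
        assert rep["recall"].isna().all()
        assert (rep["n_planted"] == 0).all()

    def test_unknown_axis_is_error(self, small_sim):
        _, em, truth = small_sim
        up, down = stratify_treatment_axis(em)
        with pytest.raises(ValueError, match="axis"):
            recovery_report(up, down, truth, axis="banana")


def test_recovery_f1_monotone_in_effect_size():
    """Mean F1 across treatment-effect classes grows with the planted effect."""
    counts = {c: 30 for c in ("early_up", "early_down", "constant_up",
                              "constant_down", "delayed_up", "delayed_down")}
    mean_f1 = {}
    for effect in (0.5, 1.0, 2.0):
        f1s = []
        for seed in range(41, 46):
            cfg = SimulationConfig(
                n_genes=800, planted_counts=counts, effect_size_logfc=effect, seed=seed
            )
            em, truth = simulate_expression(cfg)
            up, down = stratify_treatment_axis(em)
            rep = recovery_report(up, down, truth, axis="treatment")
            f1s.append(np.nanmean(rep["f1"]))
        mean_f1[effect] = np.mean(f1s)
    assert mean_f1[0.5] <= mean_f1[1.0] <= mean_f1[2.0]
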