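"""The pairing decision engine: q partition, summary-statistics ANOVA,
triplet similarity, charge probes and matching inference."""

import numpy as np
import pytest
from scipy import stats

from bkrect import pairing as pr
from bkrect.errors import InferenceError
from bkrect.interface import load_evidence_table
from bkrect.occupancy import MutantSummary


@pytest.fixture(scope="module")
def table():
    return load_evidence_table()


def _single(label, q, req=1.4, sd=0.04, n=6):
    i = int(label[1])
    return MutantSummary(f"{label}S", req, sd, n, q, 0.01, n,
                         cys_labels=(label,))


def _wt():
    return MutantSummary("WT-beta2", 1.85, 0.05, 12, 0.07, 0.007, 12)


class TestPartition:
    def test_study_panel_partition(self, table):
        groups = pr.partition_by_q(table)
        conserved = {l for l, g in groups.items() if g == "conserved"}
        assert conserved == {"C1", "C5", "C6", "C8"}

    def test_constructed_split(self):
        qs = dict(zip([f"C{i}" for i in range(1, 9)],
                      [0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9]))
        rows = (_wt(),) + tuple(_single(l, q) for l, q in qs.items())
        groups = pr.partition_by_q(pr.EvidenceTable(rows))
        conserved = {l for l, g in groups.items() if g == "conserved"}
        assert conserved == {"C5", "C6", "C7", "C8"}

    def test_all_equal_refused(self):
        rows = (_wt(),) + tuple(_single(f"C{i}", 0.3) for i in range(1, 9))
        with pytest.raises(InferenceError, match="degenerate"):
            pr.partition_by_q(pr.EvidenceTable(rows))

    def test_missing_singles_refused(self):
        rows = (_wt(),) + tuple(_single(f"C{i}", 0.3) for i in range(1, 8))
        with pytest.raises(InferenceError, match="missing"):
            pr.partition_by_q(pr.EvidenceTable(rows))


class TestAnovaFromSummary:
    def test_identical_means(self):
        F, p = pr.anova_from_summary([(1.0, 0.1, 5)] * 3)
        assert F == 0.0 and p == 1.0

    def test_pooled_t_equivalence(self):
        # two equal-variance groups: F equals the squared pooled t
        F, p = pr.anova_from_summary([(0.0, 1.0, 10), (1.0, 1.0, 10)])
        assert F == pytest.approx(5.0, abs=1e-12)

    def test_zero_within_variance_flagged_p0(self):
        F, p = pr.anova_from_summary([(0.0, 0.0, 5), (1.0, 0.0, 5)])
        assert p == 0.0 and np.isinf(F)

    def test_matches_raw_data_oracle(self):
        """Reconstructing groups with exactly the stated mean/sd/n and
        running scipy's raw-data ANOVA reproduces F to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups, summaries = [], []
            for _ in range(k):
                n = int(rng.integers(3, 9))
                base = rng.normal(size=n)
                base = (base - base.mean()) / base.std(ddof=1)
                m, s = rng.normal(scale=2), rng.uniform(0.2, 2.0)
                x = m + s * base
                groups.append(x)
                summaries.append((float(np.mean(x)),
                                  float(np.std(x, ddof=1)), n))
            F_ref, p_ref = stats.f_oneway(*groups)
            F, p = pr.anova_from_summary(summaries)
            assert F == pytest.approx(F_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pr.anova_from_summary([(1.0, 0.1, 5)])
        with pytest.raises(ValueError):
            pr.anova_from_summary([(1.0, 0.1, 1), (2.0, 0.1, 5)])


class TestTripletSimilarity:
    def test_conserved_pair_similar(self, table):
        v = pr.triplet_similarity(table, "C1", "C5")
        assert v.verdict == "similar" and v.p > 0.05

    def test_cross_group_pair_dissimilar(self, table):
        v = pr.triplet_similarity(table, "C1", "C4")
        assert v.verdict == "dissimilar" and v.p < 0.05

    def test_identical_summaries_p1(self):
        rows = (_wt(), _single("C1", 0.4), _single("C2", 0.4),
                MutantSummary("C1S/C2S", 1.4, 0.04, 6,
                              cys_labels=("C1", "C2")))
        v = pr.triplet_similarity(pr.EvidenceTable(rows), "C1", "C2")
        assert v.verdict == "similar" and v.p == 1.0
        assert v.F == pytest.approx(0.0, abs=1e-12)

    def test_missing_double_untestable(self, table):
        v = pr.triplet_similarity(table, "C5", "C6")
        assert v.verdict == "untestable"


class TestChargeConsistency:
    def test_positive_probe_shifts_up(self, table):
        v = pr.charge_consistency(table, "S173K")
        assert v.direction == "up" and v.consistent

    def test_neutralized_probe_null_shift(self, table):
        v = pr.charge_consistency(table, "S173K/K141A")
        assert v.direction == "none" and v.consistent

    def test_null_shift_with_nonzero_dqe_inconsistent(self):
        rows = (_wt(),
                MutantSummary("X1K", 1.85, 0.05, 12, dq_e=1,
                              cys_labels=("C1",)))
        v = pr.charge_consistency(pr.EvidenceTable(rows), "X1K")
        assert v.direction == "none" and not v.consistent

    def test_probe_without_annotation_rejected(self, table):
        with pytest.raises(ValueError, match="dq_e"):
            pr.charge_consistency(table, "C1S")


class TestInferPairs:
    def test_study_panel_topology(self, table):
        res = pr.infer_pairs(table)
        assert res.pairs == (("C1", "C5"), ("C3", "C7"), ("C6", "C8"))
        assert res.unpaired == ("C2", "C4")

    def test_residue_numbering(self, table):
        res = pr.infer_pairs(table)
        assert set(res.residue_pairs()) == {(84, 113), (101, 148), (142, 174)}

    def test_row_order_invariance(self, table):
        rng = np.random.default_rng(0)
        rows = list(table.rows)
        rng.shuffle(rows)
        res = pr.infer_pairs(pr.EvidenceTable(tuple(rows)))
        assert res.pairs == pr.infer_pairs(table).pairs

    def test_all_dissimilar_panel_yields_no_pairs(self):
        rows = [_wt()]
        for i, lbl in enumerate(pr.CYSTEINE_MAP):
            q = 0.5 if i % 2 == 0 else 0.08
            rows.append(_single(lbl, q, req=1.3 + 0.1 * i, sd=0.01))
        # doubles wildly different from their singles
        labels = list(pr.CYSTEINE_MAP)
        for a in range(8):
            for b in range(a + 1, 8):
                if (a % 2) != (b % 2):
                    continue
                rows.append(MutantSummary(
                    f"{labels[a]}S/{labels[b]}S", 3.0, 0.01, 6,
                    cys_labels=(labels[a], labels[b])))
        res = pr.infer_pairs(pr.EvidenceTable(tuple(rows)))
        assert res.pairs == ()
        assert set(res.unpaired) == set(labels)

    def test_json_round_trip(self, table):
        import json
        payload = json.loads(pr.infer_pairs(table).to_json())
        assert payload["pairs"] == [["C1", "C5"], ["C3", "C7"], ["C6", "C8"]]


class TestPanelRecovery:
    def test_known_topology_recovered(self):
        """A non-native ground truth {C1-C2, C3-C4, C5-C6, C7-C8} is
        recovered from its simulated evidence panel."""
        rng = np.random.default_rng(7)
        truth_pairs = (("C1", "C2"), ("C3", "C4"), ("C5", "C6"), ("C7", "C8"))
        tab, truth = pr.simulate_evidence_panel(truth_pairs, rng)
        res = pr.infer_pairs(tab)
        assert res.pairs == truth

    def test_recovery_rate_over_panels(self):
        """≥95 % exact topology recovery over 200 simulated panels."""
        rng = np.random.default_rng(2024)
        truth_pairs = (("C1", "C2"), ("C3", "C4"), ("C5", "C6"), ("C7", "C8"))
        hits = 0
        for _ in range(200):
            tab, truth = pr.simulate_evidence_panel(truth_pairs, rng)
            if pr.infer_pairs(tab).pairs == truth:
                hits += 1
        assert hits >= 190

    def test_best_matching_robust_to_cohort_sampling(self):
        """With sampled cohort means the selected matching still equals the
        generating topology in ≥95 % of panels."""
        rng = np.random.default_rng(99)
        truth_pairs = (("C1", "C5"), ("C6", "C8"), ("C2", "C4"), ("C3", "C7"))
        hits = 0
        for _ in range(100):
            tab, truth = pr.simulate_evidence_panel(truth_pairs, rng,
                                                    sample_means=True)
            res = pr.infer_pairs(tab)
            best = tuple(sorted(res.best_matchings["conserved"]
                                + res.best_matchings["non-conserved"]))
            if best == truth:
                hits += 1
        assert hits >= 95
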