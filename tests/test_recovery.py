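import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import DistanceMatrix

from fastkit.community import aggregate_by_rank, relative_abundance
from fastkit.io import ManifestRow, SampleManifest
from fastkit.recovery import (
    EngraftmentRecovery,
    RecoveryConfig,
    RecoveryResult,
    abundance_captured,
    donor_matching_distances,
    inclusion_set,
    summarize_recovery,
    taxa_recovery,
    venn_partition,
)

FEATS = ["f1", "f2", "f3", "f4"]
REF = pd.Series([0.50, 0.30, 0.199, 0.001], index=FEATS)
QRY = pd.Series([0.60, 0.395, 0.0, 0.005], index=FEATS)


class TestInclusionSet:
    def test_at_least_rule_is_inclusive(self):
        included = inclusion_set([REF, QRY], tau=0.001)
        assert list(included) == FEATS  # 0.001 >= tau counts

    def test_threshold_met_in_either_sample(self):
        included = inclusion_set([REF, QRY], tau=0.002)
        assert list(included) == FEATS  # f4 qualifies through the query side

    def test_all_below_threshold_empty(self):
        a = pd.Series([1e-4, 2e-4], index=["f1", "f2"])
        assert len(inclusion_set([a, a], tau=0.001)) == 0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            inclusion_set([], tau=0.001)


class TestTaxaRecovery:
    def test_self_recovery_is_total(self):
        n_inc, n_ref, n_rec, pct = taxa_recovery(REF, [REF], tau=0.001)
        assert pct == 100.0 and n_rec == n_ref == n_inc == 4

    def test_toy_pair(self):
        n_inc, n_ref, n_rec, pct = taxa_recovery(REF, [QRY], tau=0.001)
        assert (n_inc, n_ref, n_rec) == (4, 4, 3)
        assert pct == pytest.approx(75.0)

    def test_undefined_when_reference_side_empty(self):
        ref = pd.Series([0.0, 0.0], index=["f1", "f2"])
        qry = pd.Series([0.5, 0.5], index=["f1", "f2"])
        n_inc, n_ref, n_rec, pct = taxa_recovery(ref, [qry], tau=0.001)
        assert n_ref == 0 and np.isnan(pct)

    def test_any_mouse_vs_per_mouse_mean(self):
        m1 = pd.Series([0.6, 0.0, 0.4, 0.0], index=FEATS)
        m2 = pd.Series([0.0, 0.5, 0.5, 0.0], index=FEATS)
        *_, any_pct = taxa_recovery(REF, [m1, m2], 0.001, "any_mouse")
        *_, mean_pct = taxa_recovery(REF, [m1, m2], 0.001, "per_mouse_mean")
        assert any_pct == pytest.approx(75.0)  # f1, f2, f3 in the union
        assert mean_pct == pytest.approx(50.0)  # 2 of 4 per mouse

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=500),
                st.integers(min_value=0, max_value=500),
            ),
            min_size=3,
            max_size=12,
        ),
        scale=st.integers(min_value=1, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_invariant_to_feature_order_and_count_scaling(self, counts, scale, seed):
        ref_c = np.array([c[0] for c in counts], dtype=float)
        qry_c = np.array([c[1] for c in counts], dtype=float)
        if ref_c.sum() == 0 or qry_c.sum() == 0:
            return
        idx = [f"f{i}" for i in range(len(counts))]
        ref = pd.Series(ref_c / ref_c.sum(), index=idx)
        qry = pd.Series(qry_c * scale / (qry_c.sum() * scale), index=idx)
        base = taxa_recovery(ref, [qry], 0.01)
        order = np.random.default_rng(seed).permutation(len(idx))
        shuffled = taxa_recovery(ref.iloc[order], [qry.iloc[order]], 0.01)
        assert base == shuffled

    def test_removing_globally_sub_threshold_feature_changes_nothing(self):
        ref = REF.copy()
        qry = QRY.copy()
        ref["ghost"], qry["ghost"] = 5e-4, 4e-4
        with_ghost = taxa_recovery(ref, [qry], tau=0.001)
        assert with_ghost == taxa_recovery(REF, [QRY], tau=0.001)
        assert abundance_captured(REF, [QRY]) != abundance_captured(ref, [qry])
        # venn and recovery ignore it entirely
        assert venn_partition(ref, [qry], 0.001) == venn_partition(REF, [QRY], 0.001)


class TestAbundanceCaptured:
    def test_self_capture_is_total(self):
        assert abundance_captured(REF, [REF]) == pytest.approx(100.0)

    def test_toy_pair_sums_reference_proportions(self):
        assert abundance_captured(REF, [QRY]) == pytest.approx(80.1)

    def test_no_overlap_captures_nothing(self):
        qry = pd.Series([0.0, 0.0, 0.0, 1.0], index=FEATS)
        ref = pd.Series([0.4, 0.35, 0.25, 0.0], index=FEATS)
        assert abundance_captured(ref, [qry]) == 0.0

    def test_empty_reference_rejected(self):
        ref = pd.Series([0.0] * 4, index=FEATS)
        with pytest.raises(ValueError, match="empty"):
            abundance_captured(ref, [QRY])


class TestVennPartition:
    def test_identical_samples(self):
        assert venn_partition(REF, [REF], 0.001) == (0, 4, 0)

    def test_toy_pair(self):
        assert venn_partition(REF, [QRY], 0.001) == (1, 3, 0)

    def test_disjoint_supports(self):
        ref = pd.Series([0.5, 0.5, 0.0, 0.0], index=FEATS)
        qry = pd.Series([0.0, 0.0, 0.5, 0.5], index=FEATS)
        assert venn_partition(ref, [qry], 0.001) == (2, 0, 2)

    def test_shared_count_equals_n_recovered(self, small_bundle):
        props = relative_abundance(small_bundle.table)
        s2 = props["sub1_S2"]
        mice = [props[s] for s in small_bundle.manifest.samples_for("sub1", "mouse")]
        *_, n_rec, _ = taxa_recovery(s2, mice, 0.001, "any_mouse")
        _, shared, _ = venn_partition(s2, mice, 0.001)
        assert shared == n_rec


class TestSummaries:
    @staticmethod
    def _result(subject, pct):
        return RecoveryResult(
            subject, "S2_vs_mouse", "any_mouse", "OTU", 10, 10, pct / 10,
            pct, pct, (0, int(pct / 10), 0),
        )

    def test_degenerate_spread(self):
        sf = summarize_recovery([self._result(f"s{i}", 100.0) for i in range(3)])
        assert sf["mean_recovery_pct"].iloc[0] == 100.0
        assert sf["se_recovery_pct"].iloc[0] == 0.0

    def test_mean_and_standard_error(self):
        sf = summarize_recovery(
            [self._result("a", 70.0), self._result("b", 80.0), self._result("c", 90.0)]
        )
        assert sf["mean_recovery_pct"].iloc[0] == pytest.approx(80.0)
        assert sf["se_recovery_pct"].iloc[0] == pytest.approx(5.7735, abs=1e-4)
        assert sf["n_subjects"].iloc[0] == 3

    def test_single_subject_has_undefined_se(self):
        sf = summarize_recovery([self._result("a", 75.0)])
        assert np.isnan(sf["se_recovery_pct"].iloc[0])


class TestDonorMatching:
    def test_counts_for_two_subject_design(self):
        manifest = SampleManifest(
            [
                ManifestRow("h1", "sub1", "S2", 1),
                ManifestRow("m1", "sub1", "mouse", 1),
                ManifestRow("h2", "sub2", "S2", 1),
                ManifestRow("m2", "sub2", "mouse", 1),
            ]
        )
        data = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.75],
                [0.9, 0.85, 0.0, 0.1],
                [0.8, 0.75, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(data, ids=["h1", "m1", "h2", "m2"])
        groups = donor_matching_distances(dm, manifest)
        assert len(groups["DONOR"]) == 2
        assert len(groups["OTHER"]) == 2
        assert np.median(groups["DONOR"]) < np.median(groups["OTHER"])

    def test_mice_without_human_samples_skipped(self):
        manifest = SampleManifest(
            [
                ManifestRow("h1", "sub1", "S2", 1),
                ManifestRow("m1", "sub1", "mouse", 1),
                ManifestRow("m2", "sub2", "mouse", 1),
            ]
        )
        dm = DistanceMatrix(
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.5], [0.4, 0.5, 0]]),
            ids=["h1", "m1", "m2"],
        )
        with pytest.warns(UserWarning, match="m2"):
            groups = donor_matching_distances(dm, manifest)
        assert len(groups["DONOR"]) == 1 and len(groups["OTHER"]) == 0


class TestModelResults:
    def test_fit_produces_defined_results_everywhere(self, small_bundle):
        results = EngraftmentRecovery(
            small_bundle.table, small_bundle.taxonomy, small_bundle.manifest
        ).fit()
        frame = results.frame
        assert not frame["recovery_pct"].isna().any()
        assert (frame["n_recovered"] <= frame["n_reference"]).all()
        assert (frame["n_reference"] <= frame["n_included"]).all()
        assert frame["recovery_pct"].between(0, 100).all()
        assert frame["abundance_captured_pct"].between(0, 100).all()

    def test_self_recovery_at_every_rank(self, small_bundle):
        # a subject compared against itself must recover 100% at all ranks
        for rank in ("phylum", "order", "family", "genus", "OTU"):
            agg = aggregate_by_rank(small_bundle.table, small_bundle.taxonomy, rank)
            props = relative_abundance(agg)
            ref = props["sub1_S2"]
            *_, pct = taxa_recovery(ref, [ref], 0.001)
            assert pct == 100.0
            assert abundance_captured(ref, [ref]) == pytest.approx(100.0)

    def test_summary_renders(self, small_bundle):
        results = EngraftmentRecovery(
            small_bundle.table, small_bundle.taxonomy, small_bundle.manifest
        ).fit()
        text = results.summary()
        assert "S2_vs_mouse" in text and "recovery %" in text

    def test_config_validation(self):
        with pytest.raises(ValueError, match="tau"):
            RecoveryConfig(tau=0.0)
        with pytest.raises(ValueError, match="ranks"):
            RecoveryConfig(ranks=("species",))
        with pytest.raises(ValueError, match="pooling"):
            RecoveryConfig(pooling="median")
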