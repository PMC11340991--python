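import numpy as np
import pandas as pd
import pytest

from numtpipe.callset import (
    exclusive_calls, filter_population, merge_callsets, per_sample_counts,
)
from numtpipe.simulate import CohortDesign, TissueSpec, simulate_cohort


def frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos"])


class TestMerge:
    def test_window_boundary(self):
        calls = frame([("s1", "chr1", 100), ("s2", "chr1", 150)])
        assert merge_callsets(calls, window=50).n_loci == 1
        calls = frame([("s1", "chr1", 100), ("s2", "chr1", 151)])
        assert merge_callsets(calls, window=50).n_loci == 2

    def test_single_sample_identity(self):
        calls = frame([("s1", "chr1", 100), ("s1", "chr1", 5000), ("s1", "chr2", 100)])
        unified = merge_callsets(calls)
        assert unified.n_loci == 3
        assert sorted(unified.loci["pos"]) == [100, 100, 5000]

    def test_matches_bruteforce_and_order_invariant(self, rng):
        """Merging equals brute-force single-linkage closure and ignores
        input row order."""
        positions = rng.integers(0, 5000, 60)
        calls = frame([(f"s{i % 4}", "chr1", int(p)) for i, p in enumerate(positions)])
        unified = merge_callsets(calls, window=50)
        # brute-force closure
        pos = sorted(set(positions.tolist()) | set())
        pos = sorted(positions.tolist())
        labels = list(range(len(pos)))
        changed = True
        while changed:
            changed = False
            for i in range(len(pos)):
                for j in range(len(pos)):
                    if abs(pos[i] - pos[j]) <= 50 and labels[i] != labels[j]:
                        a, b = labels[i], labels[j]
                        labels = [a if l == b else l for l in labels]
                        changed = True
        assert unified.n_loci == len(set(labels))
        shuffled = calls.sample(frac=1, random_state=1).reset_index(drop=True)
        again = merge_callsets(shuffled, window=50)
        pd.testing.assert_frame_equal(unified.loci, again.loci)

    def test_idempotence(self):
        calls = frame([("s1", "chr1", 100), ("s2", "chr1", 140), ("s1", "chr1", 400)])
        once = merge_callsets(calls, window=50)
        again = merge_callsets(
            once.loci.assign(sample_id="merged")[["sample_id", "chrom", "pos"]],
            window=50,
        )
        assert again.n_loci == once.n_loci

    def test_mixed_builds_rejected(self):
        calls = frame([("s1", "chr1", 100), ("s2", "chr1", 200)])
        calls["genome_build"] = ["GRCh37", "GRCh38"]
        with pytest.raises(ValueError, match="build"):
            merge_callsets(calls)

    def test_every_call_in_exactly_one_locus(self, rng):
        positions = rng.integers(0, 3000, 40)
        calls = frame([("s0", "chr1", int(p)) for p in positions])
        unified = merge_callsets(calls)
        assert len(unified.members) == len(calls)
        assert unified.members["locus_id"].isin(unified.loci["locus_id"]).all()


class TestPopulationFilter:
    def refs(self):
        return pd.DataFrame({"chrom": ["chr1"], "pos": [1000], "id": ["POP_0"]})

    def test_window_boundary(self):
        unified = merge_callsets(frame([("s1", "chr1", 1050), ("s1", "chr1", 2000)]))
        kept, removed = filter_population(unified, self.refs(), window=50)
        assert removed == 1 and kept.n_loci == 1
        unified = merge_callsets(frame([("s1", "chr1", 1051)]))
        kept, removed = filter_population(unified, self.refs(), window=50)
        assert removed == 0 and kept.n_loci == 1

    def test_empty_reference_is_identity_with_warning(self):
        unified = merge_callsets(frame([("s1", "chr1", 100)]))
        with pytest.warns(UserWarning):
            kept, removed = filter_population(unified, pd.DataFrame())
        assert removed == 0 and kept.n_loci == 1

    def test_idempotence(self):
        unified = merge_callsets(frame([("s1", "chr1", 990), ("s1", "chr1", 5000)]))
        once, r1 = filter_population(unified, self.refs())
        twice, r2 = filter_population(once, self.refs())
        assert r1 == 1 and r2 == 0
        pd.testing.assert_frame_equal(once.loci, twice.loci)

    def test_planted_overlap_removed_exactly(self, rng, plain_model):
        """Loci matching the planted population reference are removed and
        only those (ground-truth bookkeeping)."""
        design = CohortDesign(
            tissues=(TissueSpec("A", 10, 1.0), TissueSpec("B", 10, 1.0)),
            germline_loci=10, population_overlap=0.3, germline_carrier_prob=1.0,
        )
        cohort = simulate_cohort(rng, plain_model, design)
        unified = merge_callsets(cohort.calls)
        kept, removed = filter_population(unified, cohort.population_reference)
        assert removed == 3


class TestExclusive:
    def meta(self):
        return pd.DataFrame(
            {"sample_id": ["a1", "a2", "a3", "b1"],
             "tissue": ["DLPFC", "DLPFC", "DLPFC", "WB"]}
        )

    def test_multi_tissue_locus_dropped(self):
        calls = frame([("a1", "chr1", 100), ("a2", "chr1", 110), ("a3", "chr1", 95),
                       ("a1", "chr2", 500), ("b1", "chr2", 510)])
        unified = merge_callsets(calls, samples=self.meta()["sample_id"].tolist())
        exc = exclusive_calls(unified, self.meta())
        assert exc.n_loci == 1
        assert exc.loci["chrom"].iloc[0] == "chr1"

    def test_single_group_cohort_retains_everything(self):
        meta = pd.DataFrame({"sample_id": ["a1", "a2"], "tissue": ["DLPFC", "DLPFC"]})
        calls = frame([("a1", "chr1", 100), ("a2", "chr1", 5000)])
        unified = merge_callsets(calls)
        assert exclusive_calls(unified, meta).n_loci == 2

    def test_unlabeled_sample_errors(self):
        calls = frame([("mystery", "chr1", 100)])
        unified = merge_callsets(calls)
        with pytest.raises(ValueError, match="mystery"):
            exclusive_calls(unified, self.meta())

    def test_stable_under_sample_reordering_and_empty_samples(self):
        calls = frame([("a1", "chr1", 100), ("b1", "chr2", 500)])
        meta = self.meta()
        u1 = merge_callsets(calls, samples=["a1", "a2", "a3", "b1"])
        u2 = merge_callsets(calls, samples=["b1", "a3", "a1", "a2"])
        e1 = exclusive_calls(u1, meta)
        e2 = exclusive_calls(u2, meta)
        assert sorted(e1.loci["pos"]) == sorted(e2.loci["pos"])

    def test_max_carriers_option(self):
        calls = frame([("a1", "chr1", 100), ("a2", "chr1", 105), ("a3", "chr1", 95)])
        unified = merge_callsets(calls, samples=self.meta()["sample_id"].tolist())
        assert exclusive_calls(unified, self.meta()).n_loci == 1
        assert exclusive_calls(unified, self.meta(), max_carriers=2).n_loci == 0

    def test_recovers_planted_somatic_set(self, rng, plain_model):
        """Population filtering plus tissue exclusivity recovers exactly the
        planted somatic events (germline is shared across tissues)."""
        design = CohortDesign(
            tissues=(TissueSpec("A", 20, 2.0), TissueSpec("B", 20, 2.0)),
            germline_loci=8, germline_carrier_prob=1.0, population_overlap=0.25,
        )
        cohort = simulate_cohort(rng, plain_model, design)
        unified = merge_callsets(
            cohort.calls, samples=cohort.samples["sample_id"].tolist()
        )
        filtered, _ = filter_population(unified, cohort.population_reference)
        exc = exclusive_calls(filtered, cohort.samples)
        somatic_truth = cohort.calls[cohort.calls["origin"] == "somatic"]
        assert exc.n_loci == len(somatic_truth)
        assert set(exc.loci["pos"]) == set(somatic_truth["pos"])


class TestCounts:
    def test_empty_callset_zero_counts(self):
        unified = merge_callsets(frame([]), samples=["s1", "s2"])
        counts = per_sample_counts(unified)
        assert (counts["total"] == 0).all() and len(counts) == 2

    def test_counts_equal_matrix_margins(self):
        calls = frame([("s1", "chr1", 1), ("s1", "chr1", 5000), ("s2", "chr1", 2),
                       ("s3", "chr2", 9)])
        unified = merge_callsets(calls, samples=["s1", "s2", "s3"])
        counts = per_sample_counts(unified).set_index("sample_id")["total"]
        assert counts["s1"] == 2 and counts["s2"] == 1 and counts["s3"] == 1

    def test_dlpfc_exclusive_mean_matches_design_rate(self, plain_model):
        """DLPFC-preset exclusive counts average ~4.13 per sample."""
        rng = np.random.default_rng(2024)
        design = CohortDesign(
            tissues=(TissueSpec("DLPFC", 200, 4.13), TissueSpec("cerebellum", 100, 0.75)),
            germline_loci=8, germline_carrier_prob=1.0,
        )
        cohort = simulate_cohort(rng, plain_model, design)
        unified = merge_callsets(
            cohort.calls, samples=cohort.samples["sample_id"].tolist()
        )
        exc = exclusive_calls(unified, cohort.samples)
        counts = per_sample_counts(unified, exc, cohort.samples)
        dlpfc = counts[counts["tissue"] == "DLPFC"]["exclusive"]
        assert dlpfc.mean() == pytest.approx(4.13, abs=0.4)
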