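import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from numtpipe.genome import GenomeModel, demo_genome
from numtpipe.simulate import (
    COHORT_FRAGMENTS, COHORT_VAF, FIBROBLAST_VAF, LIFESPAN_FRAGMENTS,
    CohortDesign, FragmentModel, LengthModel, LongitudinalDesign, NumtEvent,
    SeriesSpec, TissueSpec, sample_lengths, sample_numt_event,
    simulate_cohort, simulate_longitudinal, simulate_molecules,
    simulate_read_evidence, lifespan_design,
)


class TestEventSampling:
    def test_degenerate_length_model(self, rng, plain_model):
        lm = LengthModel(fixed=100)
        lengths = sample_lengths(rng, plain_model, lm, 50)
        assert (lengths == 100).all()

    def test_fixed_length_must_fit_mtdna(self, rng):
        model = GenomeModel(chromosomes={"chr1": 1000}, mt_length=500)
        with pytest.raises(ValueError):
            sample_lengths(rng, model, LengthModel(fixed=500), 1)

    def test_positions_proportional_to_chromosome_lengths(self, rng):
        model = GenomeModel(chromosomes={"chr1": 60_000_000, "chr2": 30_000_000,
                                         "chr3": 10_000_000})
        events = [sample_numt_event(rng, model) for _ in range(10_000)]
        counts = pd.Series([e.chrom for e in events]).value_counts()
        expected = np.array([0.6, 0.3, 0.1]) * 10_000
        stat, p = sps.chisquare(
            [counts["chr1"], counts["chr2"], counts["chr3"]], expected
        )
        assert p > 0.01

    def test_default_length_distribution_matches_reported_summaries(self, rng, plain_model):
        """Large samples reproduce the observed Numt length profile:
        median ~73 bp with a heavy tail pulling the mean to ~1,169 bp."""
        lengths = sample_lengths(rng, plain_model, None, 10_000)
        assert abs(np.median(lengths) - 73) <= 15
        assert abs(lengths.mean() - 1169) <= 150
        assert lengths.min() >= 22

    def test_event_geometry_valid_on_circular_mtdna(self, rng, plain_model):
        for _ in range(200):
            ev = sample_numt_event(rng, plain_model)
            ev.validate(plain_model)

    def test_vaf_preset_medians(self, rng):
        cohort = COHORT_VAF.sample(rng, 10_000)
        fibro = FIBROBLAST_VAF.sample(rng, 10_000)
        assert np.median(cohort) == pytest.approx(0.044, abs=0.01)
        assert np.median(fibro) == pytest.approx(0.091, abs=0.015)


class TestCohort:
    def test_zero_somatic_rates_leave_only_germline(self, rng, plain_model):
        design = CohortDesign(
            tissues=(TissueSpec("A", 5, 0.0), TissueSpec("B", 5, 0.0)),
            germline_carrier_prob=1.0, germline_loci=6,
        )
        cohort = simulate_cohort(rng, plain_model, design)
        per_sample = cohort.calls.groupby("sample_id").size()
        assert (per_sample == 6).all()
        assert (cohort.calls["origin"] == "germline").all()

    def test_poisson_mean_recovery(self, rng, plain_model):
        design = CohortDesign(
            tissues=(TissueSpec("DLPFC", 200, 4.13),),
            germline_loci=0, dispersion=None, age_effect={},
        )
        cohort = simulate_cohort(rng, plain_model, design)
        mean = cohort.calls.groupby("sample_id").size().reindex(
            cohort.samples["sample_id"], fill_value=0
        ).mean()
        assert mean == pytest.approx(4.13, abs=0.4)

    def test_default_cohort_total_mean_near_observed(self, rng, plain_model):
        """Germline (~7.4) plus tissue-specific (~3.0) events give the
        cohort-wide ~10.4 Numts per sample."""
        cohort = simulate_cohort(rng, plain_model, CohortDesign())
        totals = cohort.calls.groupby("sample_id").size().reindex(
            cohort.samples["sample_id"], fill_value=0
        )
        assert totals.mean() == pytest.approx(10.4, abs=0.4)

    def test_unknown_tissue_rate_lookup_errors(self):
        with pytest.raises(KeyError):
            CohortDesign().rate("kidney")

    def test_population_overlap_fraction(self, rng, plain_model):
        design = CohortDesign(
            tissues=(TissueSpec("A", 3, 1.0),), germline_loci=10,
            population_overlap=0.3,
        )
        cohort = simulate_cohort(rng, plain_model, design)
        assert cohort.germline["in_population"].sum() == 3
        assert len(cohort.population_reference) == 3


class TestLongitudinal:
    def test_zero_rate_counts_constant(self, rng, plain_model):
        design = LongitudinalDesign(
            series=(SeriesSpec("d1", "none", (5, 50, 100), 0.0),)
        )
        out = simulate_longitudinal(rng, plain_model, design)
        assert (out.counts["count"] == 0).all()

    def test_poisson_accumulation_mean(self, plain_model):
        """λ=0.2/day over 100 days accumulates 20 events on average."""
        totals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            design = LongitudinalDesign(
                series=(SeriesSpec("d1", "none", (100,), 0.2),)
            )
            out = simulate_longitudinal(rng, plain_model, design)
            totals.append(out.counts["true_total"].iloc[-1])
        assert abs(np.mean(totals) - 20) < 2 * np.sqrt(20 / 50)

    def test_lifespan_preset_structure(self):
        design = lifespan_design()
        assert len(design.series) == 12
        by_label = {s.label: s for s in design.series}
        d1 = by_label["Donor1:none"]
        assert d1.days[0] == 7 and d1.days[-1] == 211 and len(d1.days) == 8
        p2 = by_label["Patient2:SURF1"]
        assert p2.days[0] == 8 and p2.days[-1] == 152 and len(p2.days) == 8
        assert {s.treatment for s in design.series} == {"none", "Dex", "Oligo", "SURF1"}

    def test_all_events_unique(self, rng, plain_model):
        out = simulate_longitudinal(rng, plain_model, lifespan_design())
        keys = out.events[["chrom", "pos"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_detection_dropout_reduces_counts(self, plain_model):
        design_full = lifespan_design(arms=("SURF1",))
        design_half = lifespan_design(arms=("SURF1",), detection_prob=0.5)
        full = simulate_longitudinal(np.random.default_rng(7), plain_model, design_full)
        half = simulate_longitudinal(np.random.default_rng(7), plain_model, design_half)
        assert half.counts["count"].sum() < full.counts["count"].sum()
        assert (half.counts["count"] <= half.counts["true_total"]).all()


def _map_interval_oracle(event, model, a, b):
    """Independent re-derivation of carrier-allele read mapping."""
    p, L = event.position, event.length
    overlaps = {
        "left": max(0, min(b, p) - a),
        "ins": max(0, min(b, p + L) - max(a, p)),
        "right": max(0, b - max(a, p + L)),
    }
    best = max(overlaps, key=lambda k: (overlaps[k], -["left", "ins", "right"].index(k)))
    return best


class TestReadEvidence:
    def test_depth_zero_gives_no_records(self, rng, demo_model):
        ev = NumtEvent("chr1", 500_000, 0, 2000, 2000)
        assert simulate_read_evidence(rng, ev, 0, demo_model) == []

    def test_supporting_pairs_match_molecule_enumeration(self, demo_model):
        """Discordant-pair count equals a brute-force count over the
        simulated molecules (same seed drives both draws)."""
        ev = NumtEvent("chr1", 1_000_000, 100, 2100, 2000, vaf=0.5)
        mols = simulate_molecules(np.random.default_rng(3), ev, 30, FragmentModel())
        recs = simulate_read_evidence(np.random.default_rng(3), ev, 30, demo_model)
        fm = FragmentModel()
        expected = 0
        for mol in mols:
            if not mol.carrier:
                continue
            s1 = _map_interval_oracle(ev, demo_model, mol.start, mol.start + fm.read_len)
            s2 = _map_interval_oracle(
                ev, demo_model, mol.start + mol.length - fm.read_len,
                mol.start + mol.length,
            )
            if (s1 == "ins") != (s2 == "ins"):
                expected += 1
        observed = {
            r.qname for r in recs
            if r.chrom != demo_model.mt_name and r.mate_chrom == demo_model.mt_name
        }
        assert len(observed) == expected

    def test_read_length_presets(self):
        assert COHORT_FRAGMENTS.read_len == 151
        assert LIFESPAN_FRAGMENTS.read_len == 149

    def test_noncarrier_pairs_are_concordant(self, rng, demo_model):
        ev = NumtEvent("chr2", 1_000_000, 0, 3000, 3000, vaf=0.0)
        recs = simulate_read_evidence(rng, ev, 20, demo_model)
        assert recs and all(r.mate_chrom == r.chrom for r in recs)

    def test_determinism(self, demo_model):
        ev = NumtEvent("chr1", 1_000_000, 100, 1100, 1000, vaf=0.4)
        a = simulate_read_evidence(np.random.default_rng(9), ev, 25, demo_model)
        b = simulate_read_evidence(np.random.default_rng(9), ev, 25, demo_model)
        assert a == b


def test_cohort_determinism(plain_model):
    design = CohortDesign(tissues=(TissueSpec("A", 10, 2.0),), germline_loci=3)
    a = simulate_cohort(np.random.default_rng(5), plain_model, design)
    b = simulate_cohort(np.random.default_rng(5), plain_model, design)
    pd.testing.assert_frame_equal(a.calls, b.calls)
    pd.testing.assert_frame_equal(a.samples, b.samples)
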