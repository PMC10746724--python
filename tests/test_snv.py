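import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magpop import (
    ValidationError,
    call_snvs,
    consensus_and_departure,
    core_positions,
    coverage_summary,
    select_mags,
    snv_density,
)
from magpop.simulate import MagSpec, SimulationConfig, SiteSpec, simulate_bundle
from magpop.simulate import Horizon

from conftest import make_counts


class TestConsensusAndDeparture:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((90, 10, 0, 0), ("A", 0.10)),
            ((25, 25, 25, 25), ("A", 0.75)),  # four-way tie resolves to A
            ((0, 0, 0, 12), ("T", 0.0)),
            ((0, 7, 7, 0), ("C", 0.5)),  # two-way tie resolves to earlier base
        ],
    )
    def test_examples(self, counts, expected):
        base, departure = consensus_and_departure(*counts)
        assert base == expected[0]
        assert departure == pytest.approx(expected[1])

    def test_zero_coverage_is_undefined(self):
        with pytest.raises(ValidationError):
            consensus_and_departure(0, 0, 0, 0)

    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4).filter(lambda c: sum(c) > 0))
    def test_consensus_is_a_plurality_and_departure_bounded(self, counts):
        base, departure = consensus_and_departure(*counts)
        idx = "ACGT".index(base)
        assert counts[idx] == max(counts)
        assert 0.0 <= departure <= 0.75


class TestCallSnvs:
    def test_departure_boundary_inclusive(self):
        counts = make_counts([("M", "c", 0, "s", 90, 10, 0, 0)])
        assert len(call_snvs(counts, 10, 0.1)) == 1  # departure exactly 0.1 retained

    def test_below_departure_dropped(self):
        counts = make_counts([("M", "c", 0, "s", 95, 5, 0, 0)])
        assert len(call_snvs(counts, 10, 0.1)) == 0

    def test_coverage_boundary(self):
        # coverage thresholds are uniformly inclusive: 10x kept, 9x dropped
        kept = make_counts([("M", "c", 0, "s", 8, 2, 0, 0)])
        dropped = make_counts([("M", "c", 0, "s", 7, 2, 0, 0)])
        assert len(call_snvs(kept, 10, 0.1)) == 1
        assert len(call_snvs(dropped, 10, 0.1)) == 0

    def test_empty_input_gives_empty_output(self):
        empty = make_counts([])
        out = call_snvs(empty, 10, 0.1)
        assert len(out) == 0
        assert "departure" in out.columns

    def test_idempotence(self, tiny_counts):
        once = call_snvs(tiny_counts, 10, 0.1)
        again = call_snvs(once[make_counts([]).columns.tolist()], 10, 0.1)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), again.reset_index(drop=True)
        )

    def test_recall_on_simulated_truth(self):
        """Sites with true minor-allele frequency >= 0.2 are recovered in
        samples covered >= 30x at better than 95% recall."""
        mag = MagSpec(
            mag_id="M",
            genome_length_bp=4000,
            n_variable_sites=2000,
            maf_low=0.2,
            maf_high=0.5,
            f_realm=0, f_trench=0, f_site=0, f_core=0,
            coverage_peak=50, coverage_floor=50,
        )
        site = SiteSpec("S", "Atacama", "abyssal", 5000, n_cores=1,
                        horizons=[Horizon(0, 1, "oxic")])
        truth, counts, _ = simulate_bundle(SimulationConfig(seed=11, sites=[site], mags=[mag]))
        cov = counts[["A", "C", "G", "T"]].sum(axis=1)
        eligible = counts[cov >= 30]
        snvs = call_snvs(counts, 10, 0.1)
        called = set(zip(snvs["contig_id"], snvs["position"]))
        hits = sum(1 for c, p in zip(eligible["contig_id"], eligible["position"]) if (c, p) in called)
        recall = hits / len(eligible)
        assert recall > 0.95


class TestCorePositions:
    def test_position_failing_in_one_sample_excluded(self):
        counts = make_counts(
            [("M", "c", 0, "s1", 12, 0, 0, 0), ("M", "c", 0, "s2", 8, 0, 0, 0)]
        )
        assert len(core_positions(counts, ["s1", "s2"], 10)) == 0

    def test_single_sample_equals_its_covered_positions(self, tiny_counts):
        core = core_positions(tiny_counts, ["s2"], 10)
        assert set(core["position"]) == {0, 5}

    def test_missing_sample_named_in_error(self, tiny_counts):
        with pytest.raises(ValidationError, match="s3"):
            core_positions(tiny_counts, ["s1", "s3"], 10)

    def test_matches_exhaustive_scan_on_random_fixture(self):
        """Independent oracle: per-position scan over a random 50-position,
        4-sample fixture."""
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(4)]
        rows = []
        cov = {}
        for p in range(50):
            for s in samples:
                if rng.random() < 0.8:  # some positions absent in some samples
                    a = int(rng.integers(0, 30))
                    rows.append(("M", "c", p, s, a, 0, 0, 0))
                    cov[(p, s)] = a
        counts = make_counts(rows)
        expected = {
            p for p in range(50) if all(cov.get((p, s), 0) >= 10 for s in samples)
        }
        got = set(core_positions(counts, samples, 10)["position"])
        assert got == expected

    def test_monotone_in_sample_set(self, tiny_counts):
        one = set(core_positions(tiny_counts, ["s1"], 10)["position"])
        both = set(core_positions(tiny_counts, ["s1", "s2"], 10)["position"])
        assert both <= one


class TestCoverageSummary:
    def test_arithmetic(self):
        rows = [("M", "c", p, "s", 20, 0, 0, 0) for p in range(80)]
        summary = coverage_summary(make_counts(rows), {"M": 100})
        row = summary.iloc[0]
        assert row["detection"] == pytest.approx(0.8)
        assert row["mean_coverage"] == pytest.approx(16.0)
        assert row["reported_coverage"] == pytest.approx(16.0)

    def test_detection_exactly_at_threshold_reports_zero(self):
        # the abundance-proxy rule requires detection strictly over 0.7
        rows = [("M", "c", p, "s", 20, 0, 0, 0) for p in range(70)]
        summary = coverage_summary(make_counts(rows), {"M": 100})
        assert summary.iloc[0]["detection"] == pytest.approx(0.7)
        assert summary.iloc[0]["reported_coverage"] == 0.0

    def test_position_beyond_length_rejected(self):
        counts = make_counts([("M", "c", 100, "s", 5, 0, 0, 0)])
        with pytest.raises(ValidationError, match="length"):
            coverage_summary(counts, {"M": 100})


class TestDensityAndSelection:
    def test_density_arithmetic(self):
        assert snv_density(50, 10_000) == pytest.approx(5.0)
        assert snv_density(0, 1000) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            snv_density(5, 0)

    def test_density_recovers_generator_truth(self):
        """At high coverage the estimated density matches the configured
        number of variable sites per covered kilobase."""
        mag = MagSpec(
            mag_id="M", genome_length_bp=10_000, n_variable_sites=60,
            maf_low=0.25, maf_high=0.5,
            f_realm=0, f_trench=0, f_site=0, f_core=0,
            coverage_peak=200, coverage_floor=200,
        )
        site = SiteSpec("S", "Atacama", "abyssal", 5000, n_cores=1,
                        horizons=[Horizon(0, 1, "oxic")])
        truth, counts, _ = simulate_bundle(SimulationConfig(seed=3, sites=[site], mags=[mag]))
        snvs = call_snvs(counts, 10, 0.1)
        est = snv_density(snvs, 10_000)
        assert est == pytest.approx(6.0, abs=0.5)

    def test_select_mags_boundaries(self):
        rows = [
            {"mag_id": "M1", "sample_id": f"s{i}", "mean_coverage": 12.0, "detection": 1.0,
             "reported_coverage": 12.0}
            for i in range(41)
        ]
        coverage = pd.DataFrame(rows)
        assert select_mags(coverage, 10, 40) == ["M1"]
        assert select_mags(coverage, 10, 42) == []
        assert select_mags(pd.DataFrame(columns=coverage.columns), 10, 40) == []
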