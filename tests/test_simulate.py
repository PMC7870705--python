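"""Seeded population generators: reproducibility, moments, and model agreement."""

import numpy as np
import pytest
from scipy import stats

from segdist.core import TransmissionModel, expected_selfing_freqs
from segdist.mapping import MarkerMap
from segdist.simulate import (
    SimulationConfig,
    expected_complementation_freqs,
    expected_rescued_k,
    recovery_experiment,
    simulate_backcross_counts,
    simulate_complementation_t1,
    simulate_marker_population,
    simulate_selfing_counts,
)

MM = MarkerMap(names=("M1", "M2", "M3", "M4"), rec_fractions=(0.05, 0.05, 0.05))


class TestSelfingCounts:
    def test_bit_reproducible(self):
        assert simulate_selfing_counts(0.11, 90, seed=3) == simulate_selfing_counts(
            0.11, 90, seed=3
        )

    def test_counts_sum_to_n(self):
        counts = simulate_selfing_counts(0.3, 250, seed=1)
        assert counts.total == 250

    def test_zero_k_never_yields_gg(self):
        for seed in range(50):
            assert simulate_selfing_counts(0.0, 200, seed=seed).n_GG == 0

    def test_gg_mean_matches_binomial_moments(self):
        # k=0.11, n=90: E[n_GG] = 90 * 0.055; mean over 5000 replicates
        # within 2 standard errors.
        reps = 5000
        values = np.array(
            [simulate_selfing_counts(0.11, 90, seed=s).n_GG for s in range(reps)]
        )
        expect = 90 * 0.055
        se = np.sqrt(90 * 0.055 * 0.945 / reps)
        assert abs(values.mean() - expect) < 2 * se

    def test_large_n_frequencies_fit_model(self):
        # Pinned-seed chi-square GOF of one n=1e5 draw against the
        # model frequencies.
        counts = simulate_selfing_counts(0.11, 100_000, seed=42)
        probs = expected_selfing_freqs(TransmissionModel(0.11)).as_array()
        _, p = stats.chisquare(counts.as_array(), f_exp=100_000 * probs)
        assert p > 0.001

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            simulate_selfing_counts(0.5, 0, seed=1)


class TestBackcrossCounts:
    def test_reproducible_and_sized(self):
        a = simulate_backcross_counts(0.2, 100, seed=5)
        assert a == simulate_backcross_counts(0.2, 100, seed=5)
        assert sum(a) == 100

    def test_zero_k(self):
        assert simulate_backcross_counts(0.0, 50, seed=2) == (50, 0)


class TestMarkerPopulation:
    def test_bit_reproducible(self):
        a = simulate_marker_population(MM, 1.5, k=0.0, n=50, seed=9)
        b = simulate_marker_population(MM, 1.5, k=0.0, n=50, seed=9)
        assert a == b

    def test_no_recombination_no_recombinants(self):
        mm0 = MarkerMap(names=MM.names, rec_fractions=(0.0, 0.0, 0.0))
        for r in simulate_marker_population(mm0, 1.5, k=0.5, n=200, seed=4):
            assert len(set(r.calls)) == 1

    def test_phenotype_follows_locus_model(self):
        # With r=0 the marker calls equal the locus genotype, so SS
        # plants must be all-H and N plants all-T.
        mm0 = MarkerMap(names=MM.names, rec_fractions=(0.0, 0.0, 0.0))
        for r in simulate_marker_population(mm0, 1.5, k=0.3, n=300, seed=8):
            assert r.calls == (("H",) * 4 if r.phenotype == "SS" else ("T",) * 4)

    def test_marker_recombinant_fraction_matches_map_distance(self):
        # Two-marker map at r=0.1, no selection (k=0.5): a plant shows a
        # genotype change between the markers unless neither gamete
        # recombined or both recombined in cancelling directions:
        # P(change) = 1 - (1-r)^2 - r^2/2.
        r = 0.1
        mm2 = MarkerMap(names=("L", "R"), rec_fractions=(r,))
        records = simulate_marker_population(mm2, 0.5, k=0.5, n=5000, seed=11)
        changed = sum(rec.calls[0] != rec.calls[1] for rec in records) / len(records)
        expect = 1 - (1 - r) ** 2 - r**2 / 2
        se = np.sqrt(expect * (1 - expect) / 5000)
        assert abs(changed - expect) < 2.5 * se

    def test_selection_distorts_marker_frequencies(self):
        # At k=0 every plant carries at least one cultivated allele at
        # the locus; tightly linked markers show no GG calls.
        mm_tight = MarkerMap(names=("L", "R"), rec_fractions=(0.01,))
        records = simulate_marker_population(mm_tight, 0.5, k=0.0, n=500, seed=13)
        g_calls = sum(c == "G" for rec in records for c in rec.calls)
        assert g_calls == 0 or g_calls < 10  # only via rare double recombination

    def test_locus_position_validated(self):
        with pytest.raises(ValueError, match="locus_position"):
            simulate_marker_population(MM, 5.0, k=0.0, n=10, seed=1)
        with pytest.raises(ValueError, match="locus_position"):
            simulate_marker_population(MM, 2.0, k=0.0, n=10, seed=1)

    def test_requires_rec_fractions(self):
        with pytest.raises(ValueError, match="rec_fractions"):
            simulate_marker_population(
                MarkerMap(names=("A", "B")), 0.5, k=0.0, n=10, seed=1
            )


class TestComplementation:
    def test_bit_reproducible(self):
        a = simulate_complementation_t1(k=0.11, rescue=1.0, zygosity="hemizygous",
                                        n=100, seed=6)
        b = simulate_complementation_t1(k=0.11, rescue=1.0, zygosity="hemizygous",
                                        n=100, seed=6)
        assert a.counts == b.counts
        assert a.plants.equals(b.plants)

    def test_no_rescue_matches_plain_selfing_model(self):
        # A transgene with rescue=0 is a no-op: expected frequencies
        # equal the plain selfing model at the base k.
        freqs = expected_complementation_freqs(k=0.11, rescue=0.0)
        base = expected_selfing_freqs(TransmissionModel(0.11))
        assert freqs.as_array() == pytest.approx(base.as_array(), abs=1e-12)

    def test_full_rescue_homozygous_restores_mendelian(self):
        # Every male gamete carries the transgene: transmission returns
        # to 0.5 and large-n frequencies approach (1/4, 1/2, 1/4).
        assert expected_rescued_k(0.11, rescue=1.0, zygosity="homozygous") == pytest.approx(0.5)
        sample = simulate_complementation_t1(
            k=0.11, rescue=1.0, zygosity="homozygous", n=5000, seed=3
        )
        props = sample.counts.as_array() / 5000
        assert props == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_sample_frequencies_match_enumeration(self):
        freqs = expected_complementation_freqs(k=0.11, rescue=1.0, zygosity="hemizygous")
        sample = simulate_complementation_t1(
            k=0.11, rescue=1.0, zygosity="hemizygous", n=8000, seed=17
        )
        props = sample.counts.as_array() / 8000
        assert props == pytest.approx(freqs.as_array(), abs=0.02)

    def test_hemizygous_transgene_segregates(self):
        sample = simulate_complementation_t1(
            k=0.11, rescue=0.0, zygosity="hemizygous", n=2000, seed=2
        )
        copy_freqs = sample.plants["transgene_copies"].value_counts(normalize=True)
        # unselected hemizygous x hemizygous: copies ~ Binomial(2, 1/2)
        assert copy_freqs.get(1, 0.0) == pytest.approx(0.5, abs=0.03)

    def test_linked_transgene_validation(self):
        with pytest.raises(ValueError):
            simulate_complementation_t1(
                k=0.1, rescue=1.0, zygosity="hemizygous", linkage_r=0.7, n=10, seed=1
            )


class TestRecoveryExperiment:
    def test_consistency_and_boundary(self):
        table = recovery_experiment([0.0, 0.5], n=1000, reps=500, seed=20)
        at0 = table[table.k_true == 0.0].iloc[0]
        at5 = table[table.k_true == 0.5].iloc[0]
        assert at0.mean_k_hat == 0.0 and at0.rmse == 0.0  # k=0: no GG ever
        assert abs(at5.bias) < 0.02

    def test_deterministic(self):
        a = recovery_experiment([0.2], n=100, reps=100, seed=1)
        b = recovery_experiment([0.2], n=100, reps=100, seed=1)
        assert a.equals(b)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            recovery_experiment([0.2], n=100, reps=10, seed=1)


class TestSimulationConfig:
    def test_dispatch_and_reproducibility(self):
        cfg = SimulationConfig(seed=5, n_plants=80, design="selfing_T1",
                               params={"k": 0.11})
        assert cfg.run() == simulate_selfing_counts(k=0.11, n=80, seed=5)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_plants=10, design="field_trial")

    def test_substreams_independent(self):
        # The selfing draw is unchanged by what other stages consume.
        before = simulate_selfing_counts(0.2, 100, seed=33)
        simulate_complementation_t1(k=0.2, rescue=1.0, zygosity="hemizygous",
                                    n=50, seed=33)
        simulate_marker_population(MM, 1.5, k=0.0, n=20, seed=33)
        assert simulate_selfing_counts(0.2, 100, seed=33) == before
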