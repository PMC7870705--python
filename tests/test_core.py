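"""Deterministic genetic-model checks: segregation, two-locus, fertility, sigma/k."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdist.core import (
    PollenViabilityModel,
    SegregationCounts,
    TransgeneInsertion,
    TransgeneSpec,
    TransmissionModel,
    TwoLocusModel,
    expected_backcross_freqs,
    expected_pollen_fertility,
    expected_selfing_freqs,
    k_from_sigma,
    sigma_from_k,
    two_locus_pollen_transmission,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestSelfingFreqs:
    @pytest.mark.parametrize(
        "k,f,expected",
        [
            (0.5, 0.5, (0.25, 0.5, 0.25)),  # Mendelian 1:2:1
            (0.0, 0.5, (0.5, 0.5, 0.0)),  # fully penetrant sterility: 1:1:0
            (0.11, 0.5, (0.445, 0.5, 0.055)),
        ],
    )
    def test_examples(self, k, f, expected):
        freqs = expected_selfing_freqs(TransmissionModel(k=k, f=f))
        assert freqs.as_array() == pytest.approx(expected, abs=1e-15)

    @given(k=probs, f=probs)
    @settings(max_examples=200, derandomize=True)
    def test_sums_to_one_and_pgg_is_fk(self, k, f):
        freqs = expected_selfing_freqs(TransmissionModel(k=k, f=f))
        assert abs(freqs.as_array().sum() - 1.0) < 1e-12
        assert freqs.p_GG == pytest.approx(f * k, abs=1e-15)

    @given(f=st.floats(0.05, 0.95), k1=st.floats(0, 1), k2=st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_k(self, f, k1, k2):
        lo, hi = sorted([k1, k2])
        if hi - lo < 1e-9:  # below float resolution of 1-k
            return
        a = expected_selfing_freqs(TransmissionModel(k=lo, f=f))
        b = expected_selfing_freqs(TransmissionModel(k=hi, f=f))
        assert b.p_GG > a.p_GG
        assert b.p_TT < a.p_TT

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TransmissionModel(k=1.2)
        with pytest.raises(ValueError):
            TransmissionModel(k=0.5, f=-0.1)


class TestBackcrossFreqs:
    @pytest.mark.parametrize("k,expected", [(0.5, (0.5, 0.5)), (0.0, (1.0, 0.0)), (0.2, (0.8, 0.2))])
    def test_pollen_parent_het(self, k, expected):
        assert expected_backcross_freqs(TransmissionModel(k=k)) == pytest.approx(expected)

    def test_seed_parent_het_uses_f(self):
        model = TransmissionModel(k=0.1, f=0.4)
        assert expected_backcross_freqs(model, pollen_parent_is_het=False) == pytest.approx(
            (0.6, 0.4)
        )


class TestTwoLocus:
    def test_complete_linkage_no_distortion(self):
        freqs = two_locus_pollen_transmission(TwoLocusModel(kA=0.5, kB=0.5, r=0.0))
        assert freqs == pytest.approx([0.5, 0.0, 0.0, 0.5])

    def test_complete_linkage_full_sterility(self):
        freqs = two_locus_pollen_transmission(TwoLocusModel(kA=0.0, kB=0.0, r=0.0))
        assert freqs == pytest.approx([1.0, 0.0, 0.0, 0.0])

    def test_partial_linkage_one_lethal_locus(self):
        freqs = two_locus_pollen_transmission(TwoLocusModel(kA=0.0, kB=0.5, r=0.2))
        assert freqs == pytest.approx([0.8, 0.2, 0.0, 0.0])

    @given(r=st.floats(0.0, 0.5), phase=st.sampled_from(["coupling", "repulsion"]))
    @settings(max_examples=100, derandomize=True)
    def test_mendelian_loci_recover_meiotic_freqs(self, r, phase):
        freqs = two_locus_pollen_transmission(
            TwoLocusModel(kA=0.5, kB=0.5, r=r, phase=phase)
        )
        if phase == "coupling":
            expected = [(1 - r) / 2, r / 2, r / 2, (1 - r) / 2]
        else:
            expected = [r / 2, (1 - r) / 2, (1 - r) / 2, r / 2]
        assert freqs == pytest.approx(expected, abs=1e-12)

    @given(
        kA=st.floats(0.01, 0.99),
        kB=st.floats(0.01, 0.99),
        r=st.floats(0.0, 0.5),
        rule=st.sampled_from(["multiplicative", "minimum"]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_normalized(self, kA, kB, r, rule):
        freqs = two_locus_pollen_transmission(
            TwoLocusModel(kA=kA, kB=kB, r=r, viability_rule=rule)
        )
        assert abs(freqs.sum() - 1.0) < 1e-12
        assert (freqs >= 0).all()

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            TwoLocusModel(kA=0.5, kB=0.5, r=0.7)


def _fertility_by_enumeration(n_loci, sigma, rescue, insertions):
    """Independent brute-force oracle: explicit sum over every gamete class."""
    total = 0.0
    for alleles in itertools.product([0, 1], repeat=n_loci):
        p_a = 0.5 ** n_loci
        sterile = any(alleles)
        for pattern in itertools.product([0, 1], repeat=len(insertions)):
            p_t = 1.0
            for ins, here in zip(insertions, pattern):
                q = ins.transmission_prob(with_sterile_allele=bool(sterile))
                p_t *= q if here else 1.0 - q
            copies = sum(pattern)
            p_rescued = 1.0 - (1.0 - rescue) ** copies
            viable = (1.0 - sigma * (1.0 - p_rescued)) ** sum(alleles)
            total += p_a * p_t * viable
    return total


class TestPollenFertility:
    @pytest.mark.parametrize(
        "insertions,expected",
        [
            ((), 0.50),  # unrescued heterozygote: semi-sterility
            ((TransgeneInsertion("hemizygous"),), 0.75),
            ((TransgeneInsertion("homozygous"),), 1.0),
        ],
    )
    def test_dosage_series(self, insertions, expected):
        fertility = expected_pollen_fertility(
            1, PollenViabilityModel(sigma=1.0), TransgeneSpec(insertions)
        )
        assert fertility == pytest.approx(expected, abs=1e-15)

    def test_two_hemizygous_copies(self):
        # Two unlinked single-copy insertions: the sterile gamete escapes
        # rescue only when it misses both, so fertility = 1 - 1/2 * 1/4.
        fert = expected_pollen_fertility(
            1,
            PollenViabilityModel(sigma=1.0),
            TransgeneSpec((TransgeneInsertion("hemizygous"), TransgeneInsertion("hemizygous"))),
        )
        assert fert == pytest.approx(0.875)

    def test_linked_insertion_coupling_with_sterile_allele(self):
        # Transgene in coupling with the sterile allele at r=0.1: the
        # sterile gamete co-inherits it with probability 0.9.
        fert = expected_pollen_fertility(
            1,
            PollenViabilityModel(sigma=1.0),
            TransgeneSpec((TransgeneInsertion("hemizygous", r=0.1, phase="coupling"),)),
        )
        assert fert == pytest.approx(1.0 - 0.5 * 0.1)

    @given(
        n_loci=st.integers(0, 2),
        sigma=probs,
        rescue=probs,
        zygosities=st.lists(st.sampled_from(["hemizygous", "homozygous"]), max_size=3),
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_brute_force_enumeration(self, n_loci, sigma, rescue, zygosities):
        insertions = tuple(TransgeneInsertion(z) for z in zygosities)
        got = expected_pollen_fertility(
            n_loci,
            PollenViabilityModel(sigma=sigma, rescue_efficiency=rescue),
            TransgeneSpec(insertions),
        )
        want = _fertility_by_enumeration(n_loci, sigma, rescue, insertions)
        assert got == pytest.approx(want, abs=1e-12)

    def test_invalid_linkage_rejected(self):
        with pytest.raises(ValueError):
            TransgeneInsertion("hemizygous", r=0.8)


class TestSigmaKMap:
    @pytest.mark.parametrize(
        "k,sigma", [(0.0, 1.0), (0.5, 0.0), (0.11, (1 - 0.22) / 0.89)]
    )
    def test_examples(self, k, sigma):
        assert sigma_from_k(k) == pytest.approx(sigma, abs=1e-12)
        assert k_from_sigma(sigma) == pytest.approx(k, abs=1e-12)

    @given(k=st.floats(0.0, 0.5))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, k):
        assert k_from_sigma(sigma_from_k(k)) == pytest.approx(k, abs=1e-12)

    def test_enhanced_transmission_rejected(self):
        with pytest.raises(ValueError, match="abortion"):
            sigma_from_k(0.6)


class TestSegregationCounts:
    def test_totals(self):
        c = SegregationCounts(42, 43, 5)
        assert c.total == 90
        assert c.informative_n == 47

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SegregationCounts(-1, 0, 0)

    def test_non_integer_rejected(self):
        with pytest.raises(TypeError):
            SegregationCounts(1.5, 0, 0)
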