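"""Gap-codon removal, JC distances and NG86 dN/dS counting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aqpflux.molevo import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    GroupAssignment,
    SaturationError,
    group_mean_dn_ds,
    jc_distance,
    ng86_pair,
    p_distance,
    pathway_differences,
    remove_gap_codons,
    synonymous_sites,
    translate,
)
from aqpflux.seqio import Alignment, SeqRecord
from aqpflux.synthetic import simulate_two_group_codons


def _rand_codons(rng, n):
    return "".join(SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n))


class TestGapCodonRemoval:
    def test_gap_free_alignment_unchanged(self, rng):
        recs = [SeqRecord(f"s{i}", _rand_codons(rng, 10)) for i in range(3)]
        caln = remove_gap_codons(Alignment(recs))
        assert caln.alignment.records[0].residues == recs[0].residues

    def test_single_gap_removes_whole_codon_for_all(self):
        a = SeqRecord("a", "ATGA-AGGG")
        b = SeqRecord("b", "ATGAAAGGG")
        caln = remove_gap_codons(Alignment([a, b]))
        assert caln.alignment["a"].residues == "ATGGGG"
        assert caln.alignment["b"].residues == "ATGGGG"

    def test_matches_independent_column_filter(self, rng):
        n_codons = 40
        rows = []
        for i in range(4):
            s = list(_rand_codons(rng, n_codons))
            for j in rng.choice(3 * n_codons, size=8, replace=False):
                s[j] = "-"
            rows.append("".join(s))
        aln = Alignment([SeqRecord(f"s{i}", r) for i, r in enumerate(rows)])
        caln = remove_gap_codons(aln)
        # oracle: brute-force triplet filter
        keep = [k for k in range(n_codons)
                if all("-" not in row[3 * k:3 * k + 3] for row in rows)]
        for i, row in enumerate(rows):
            expected = "".join(row[3 * k:3 * k + 3] for k in keep)
            assert caln.alignment[f"s{i}"].residues == expected

    def test_non_triplet_length_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            remove_gap_codons(Alignment([SeqRecord("a", "ACGT")]))


class TestJukesCantor:
    def test_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    def test_inverts_expected_difference_curve(self):
        for d in (0.01, 0.1, 0.5, 1.0, 2.0):
            p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            assert jc_distance(p) == pytest.approx(d, abs=1e-12)


class TestNG86Counting:
    def test_identity_gives_zero_differences(self, rng):
        s = _rand_codons(rng, 50)
        r = ng86_pair(s, s)
        assert r.Sd == 0 and r.Nd == 0 and r.dN == 0 and r.dS == 0

    def test_spec_example_counts(self):
        r = ng86_pair("TTTAAA", "TTCAAA")
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert synonymous_sites("TTT") == pytest.approx(1 / 3)
        assert synonymous_sites("AAA") == pytest.approx(1 / 3)
        assert r.S == pytest.approx(2 / 3)

    def test_two_position_pathway_average(self):
        # TTT -> GTC via TTC (syn then nonsyn) or GTT (nonsyn then syn)
        assert pathway_differences("TTT", "GTC") == (1.0, 1.0)

    def test_symmetry_and_site_total(self, rng):
        a = _rand_codons(rng, 60)
        b = _rand_codons(rng, 60)
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert r1.S == pytest.approx(r2.S)
        assert r1.Sd == pytest.approx(r2.Sd)
        assert r1.Nd == pytest.approx(r2.Nd)
        assert r1.S + r1.N == pytest.approx(3 * r1.n_codons)

    def test_difference_total_matches_pathway_count(self, rng):
        a = _rand_codons(rng, 40)
        b = _rand_codons(rng, 40)
        r = ng86_pair(a, b)
        expected = sum(
            sum(pathway_differences(a[i:i + 3], b[i:i + 3]))
            for i in range(0, len(a), 3)
            if a[i:i + 3] not in STOP_CODONS and b[i:i + 3] not in STOP_CODONS
        )
        assert r.Sd + r.Nd == pytest.approx(expected)

    def test_stop_codons_excluded(self):
        r = ng86_pair("TAAAAA", "TAAAAG")   # first codon is a stop in both
        assert r.n_codons == 1
        assert r.S == pytest.approx(synonymous_sites("AAA") / 2 + synonymous_sites("AAG") / 2)

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            ng86_pair("AT-", "ATG")


class TestGroupMean:
    def test_single_identical_sequence_zero(self):
        aln = CodonAlignment(Alignment([SeqRecord("a", "ATGAAA"),
                                        SeqRecord("b", "ATGAAA")]))
        groups = GroupAssignment({"a": "g1", "b": "g2"})
        r = group_mean_dn_ds(aln, groups, "g1", "g2", n_boot=50, seed=0)
        assert r.dN == 0 and r.dS == 0
        assert r.dN_se == 0 and r.dS_se == 0

    def test_empty_group_rejected(self):
        aln = CodonAlignment(Alignment([SeqRecord("a", "ATG")]))
        with pytest.raises(ValueError, match="nonempty"):
            group_mean_dn_ds(aln, GroupAssignment({"a": "g1"}), "g1", "g2", n_boot=0)

    def test_bootstrap_requires_seed(self):
        aln = CodonAlignment(Alignment([SeqRecord("a", "ATGAAA" * 20),
                                        SeqRecord("b", "ATGAAA" * 19 + "ATGAAG")]))
        groups = GroupAssignment({"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match="seed"):
            group_mean_dn_ds(aln, groups, "g1", "g2", n_boot=10)

    def test_bootstrap_se_shrinks_with_alignment_length(self):
        ses = []
        for n_codons in (300, 3000):
            sim, groups = simulate_two_group_codons(5, n_codons=n_codons)
            r = group_mean_dn_ds(sim.alignment, groups, "N20", "Gp2",
                                 n_boot=100, seed=1)
            ses.append(r.dN_se)
        assert ses[1] < ses[0] / 2   # ~sqrt(10) expected


class TestSimulationCalibration:
    def test_neutral_simulation_ratio_near_one(self):
        # mean estimated dN/dS over replicates should bracket 1 under
        # omega = 1 simulation
        ratios = []
        for seed in range(50):
            sim, groups = simulate_two_group_codons(
                seed, n_codons=300, omega_gp1=1.0, omega_gp2=1.0)
            r = group_mean_dn_ds(sim.alignment, groups, "N20", "Gp2", n_boot=0)
            ratios.append(r.ratio)
        mean = np.mean(ratios)
        mc_se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(mean - 1.0) < 2 * mc_se + 0.05

    def test_ratio_monotone_in_omega(self):
        means = []
        for omega in (0.05, 0.5):
            vals = []
            for seed in range(10):
                sim, groups = simulate_two_group_codons(
                    seed, n_codons=300, omega_gp1=omega, omega_gp2=omega)
                vals.append(group_mean_dn_ds(sim.alignment, groups, "N20",
                                             "Gp2", n_boot=0).ratio)
            means.append(np.mean(vals))
        assert means[0] < means[1]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.74))
def test_jc_distance_nonnegative_monotone(p):
    d = jc_distance(p)
    assert d >= p - 1e-12   # correction never shrinks the proportion


def test_translate_standard_code():
    assert translate("ATGTTTTAA") == "MF*"
    assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3
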