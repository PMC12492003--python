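"""Forward simulators: swelling ODE, codon evolution, clock trees, fixtures."""

import math

import numpy as np
import pytest

from aqpflux.molevo import STOP_CODONS, ng86_pair, translate
from aqpflux.permeability import hypoosmotic_design, solute_design, sphere_geometry
from aqpflux.seqio import parse_fasta
from aqpflux.synthetic import (
    CodonSimConfig,
    SwellingSimConfig,
    make_filter_alignment,
    make_fixture_suite,
    simulate_clock_tree,
    simulate_codon_alignment,
    simulate_swelling,
    simulate_swelling_path,
    simulate_two_group_codons,
    two_group_tree,
)

GEOM = sphere_geometry(0.12)


class TestSwellingSimulator:
    def test_zero_permeability_flat_trace(self):
        cfg = SwellingSimConfig(GEOM, hypoosmotic_design(), true_P_water=0.0)
        tr = simulate_swelling(cfg)
        assert np.allclose(tr.rel_volume, 1.0)

    def test_hypoosmotic_swelling_monotone(self):
        cfg = SwellingSimConfig(GEOM, hypoosmotic_design(), true_P_water=5e-3,
                                duration=120.0)
        tr = simulate_swelling(cfg)
        assert (np.diff(tr.rel_volume) > 0).all()

    def test_step_size_convergence(self):
        base = dict(geometry=GEOM, design=hypoosmotic_design(),
                    true_P_water=2e-2, duration=120.0)
        v1 = simulate_swelling_path(SwellingSimConfig(dt=0.05, **base))[1][-1]
        v2 = simulate_swelling_path(SwellingSimConfig(dt=0.025, **base))[1][-1]
        assert abs(v1 - v2) < 1e-6

    def test_conservation_without_gradients(self):
        # solute mode, no water permeability, no solute gradient from the
        # oocyte's point of view once sol_in = sol_out is impossible by
        # construction, so use P_solute = 0 instead
        cfg = SwellingSimConfig(GEOM, solute_design("urea"), true_P_water=0.0,
                                true_P_solute=0.0, duration=120.0)
        tr = simulate_swelling(cfg)
        assert np.allclose(tr.rel_volume, 1.0, atol=1e-12)

    def test_hypoosmotic_equilibrium_asymptote(self):
        # n_osm/V -> osm_out: V/V0 -> osm_in/osm_out = 2
        cfg = SwellingSimConfig(GEOM, hypoosmotic_design(), true_P_water=5e-2,
                                duration=4000.0, obs_dt=2.0)
        _, rel = simulate_swelling_path(cfg)
        assert rel[-1] == pytest.approx(2.0, rel=0.01)

    def test_seeded_noise_deterministic(self):
        cfg = SwellingSimConfig(GEOM, hypoosmotic_design(), true_P_water=5e-3,
                                noise_sd=0.005, seed=77)
        a = simulate_swelling(cfg).rel_volume
        b = simulate_swelling(cfg).rel_volume
        assert np.array_equal(a, b)

    def test_quasi_static_solute_limit(self):
        # with infinite water permeability the volume tracks internal
        # osmoles exactly; finite-P_water traces lag behind
        common = dict(geometry=GEOM, design=solute_design("urea"),
                      true_P_solute=1e-5, duration=120.0)
        fast = simulate_swelling_path(
            SwellingSimConfig(true_P_water=float("inf"), **common))[1]
        slow = simulate_swelling_path(
            SwellingSimConfig(true_P_water=2e-2, **common))[1]
        assert fast[-1] > slow[-1]
        assert (fast[1:] >= slow[1:] - 1e-12).all()

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            SwellingSimConfig(GEOM, hypoosmotic_design(), noise_sd=0.01)


class TestCodonSimulator:
    def test_zero_branch_lengths_leaves_equal_root(self):
        tree = two_group_tree(stem=0.0, tip=0.0)
        sim = simulate_codon_alignment(CodonSimConfig(tree=tree, n_codons=100, seed=1))
        for rec in sim.alignment.alignment.records:
            assert rec.residues == sim.root_sequence

    def test_omega_zero_means_no_nonsynonymous_change(self):
        tree = two_group_tree(stem=0.05, tip=0.05)
        sim = simulate_codon_alignment(
            CodonSimConfig(tree=tree, n_codons=200, omega=0.0, seed=2))
        assert all(n == 0 for (_s, n) in sim.branch_events.values())
        root_aa = translate(sim.root_sequence)
        for rec in sim.alignment.alignment.records:
            assert translate(rec.residues) == root_aa
            r = ng86_pair(sim.root_sequence, rec.residues)
            assert r.Nd == 0 and r.dN == 0

    def test_no_stop_codons_generated(self):
        sim = simulate_codon_alignment(
            CodonSimConfig(tree=two_group_tree(), n_codons=300, seed=3))
        for rec in sim.alignment.alignment.records:
            s = rec.residues
            assert not any(s[i:i + 3] in STOP_CODONS for i in range(0, len(s), 3))

    def test_deterministic_given_seed(self):
        cfg = lambda: CodonSimConfig(tree=two_group_tree(), n_codons=100, seed=9)
        a = simulate_codon_alignment(cfg())
        b = simulate_codon_alignment(cfg())
        assert [r.residues for r in a.alignment.alignment.records] == \
               [r.residues for r in b.alignment.alignment.records]

    def test_event_counts_scale_with_omega(self):
        sims = {}
        for om in (0.05, 1.0):
            sims[om] = simulate_codon_alignment(CodonSimConfig(
                tree=two_group_tree(stem=0.05, tip=0.05), n_codons=400,
                omega=om, seed=4))
        n_low = sum(n for (_s, n) in sims[0.05].branch_events.values())
        n_high = sum(n for (_s, n) in sims[1.0].branch_events.values())
        assert n_low < n_high


class TestClockTree:
    def test_true_ages_are_ultrametric_and_bounded(self):
        tree, ages = simulate_clock_tree(9, seed=5, root_age=100.0)
        assert max(ages.values()) == pytest.approx(100.0)
        assert len(ages) == 8      # n - 1 internal joins
        tree.is_rooted = True
        # every clade's age exceeds its subclades'
        for ls, age in ages.items():
            for ls2, age2 in ages.items():
                if ls2 < ls:
                    assert age > age2

    def test_branch_lengths_match_clock_rate(self):
        rate = 2e-3
        tree, ages = simulate_clock_tree(6, seed=6, root_age=50.0, rate=rate)
        # root-to-leaf path length is root_age * rate for every leaf
        tree.is_rooted = True
        for leaf in tree.leaf_node_iter():
            total, node = 0.0, leaf
            while node.parent_node is not None:
                total += node.edge.length
                node = node.parent_node
            assert total == pytest.approx(50.0 * rate, rel=1e-9)


class TestFixtures:
    def test_filter_alignment_is_deterministic(self):
        a = make_filter_alignment(seed=3)
        b = make_filter_alignment(seed=3)
        assert [(r.id, r.residues) for r in a.records] == \
               [(r.id, r.residues) for r in b.records]

    def test_two_group_sim_contains_ancestor(self):
        sim, groups = simulate_two_group_codons(1, n_codons=50)
        assert "N20" in sim.alignment.ids
        assert groups.members("Gp1") and groups.members("Gp2")
        assert sim.alignment.alignment["N20"].residues == sim.root_sequence

    def test_fixture_suite_same_seed_byte_identical(self, tmp_path):
        m1 = make_fixture_suite(21, tmp_path / "a", n_oocytes=2)
        m2 = make_fixture_suite(21, tmp_path / "b", n_oocytes=2)
        assert m1 == m2
        for name in ("filters.fasta", "traces.csv", "design.yaml",
                     "codons.fasta", "groups.tsv", "tree.nwk", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_fixture_bundle_contents(self, fixture_bundle):
        out, manifest = fixture_bundle
        filters = parse_fasta(out / "filters.fasta", alphabet="protein")
        assert len(filters) == 10
        assert set(manifest["filter_calls"].values()) == {"broad", "narrow"}
        codons = parse_fasta(out / "codons.fasta")
        assert {r.id for r in codons} >= {"N20"}
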