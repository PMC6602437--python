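"""Normalized energies, erf quality transform, aggregation and bands."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from tessqa.geometry import BurialWeights, ContactSet, compute_contacts
from tessqa.potential import ContactCategory, PotentialTable
from tessqa.scoring import (
    atom_normalized_energies,
    atom_quality,
    global_score,
    reference_band,
    residue_scores,
    score_structure,
    smooth_residue_scores,
)
from tessqa.structure import AtomBall, Structure


def _mini_structure(registry, specs):
    """specs: (chain, resseq, residue, atom_name, xyz) tuples."""
    atoms = []
    for idx, (chain, resseq, res, name, xyz) in enumerate(specs):
        tid, radius, canonical = registry.lookup(res, name)
        atoms.append(AtomBall(idx, chain, resseq, "", res, canonical,
                              np.array(xyz, dtype=float), radius, tid,
                              canonical[0]))
    return Structure(atoms, label="mini")


def _flat_potential(registry, energy_map, mu=0.0, sigma=1.0):
    """Potential with explicit energies for the given canonical types."""
    return PotentialTable(
        dict(energy_map), mu={}, sigma={}, global_mu=mu, global_sigma=sigma
    )


class TestAtomEnergy:
    def test_single_contact_equals_its_energy(self, registry):
        s = _mini_structure(registry, [
            ("A", 1, "ALA", "CA", (0, 0, 0)),
            ("A", 1, "ALA", "CB", (1.5, 0, 0)),
        ])
        key = (min(s.atoms[0].atom_type, s.atoms[1].atom_type),
               max(s.atoms[0].atom_type, s.atoms[1].atom_type),
               ContactCategory.SEQ_NEAR)
        pot = _flat_potential(registry, {key: -0.75})
        contacts = ContactSet({(0, 1): 8.0}, {}, 1.4, n_atoms=2)
        energies = atom_normalized_energies(s, contacts, pot)
        assert energies[0] == -0.75
        assert energies[1] == -0.75

    def test_weighted_mean_matches_bruteforce(self, peptide, peptide_contacts,
                                              potential):
        energies = atom_normalized_energies(peptide, peptide_contacts, potential)
        # Brute-force recomputation for a handful of atoms.
        from tessqa.potential import categorize_contact

        for i in (0, 7, 40, 100):
            pairs, solvent = peptide_contacts.atom_contacts(i)
            num = den = 0.0
            for j, area in pairs:
                e = potential.energies[
                    categorize_contact(peptide.atoms[i], peptide.atoms[j])]
                num += e * area
                den += area
            if solvent > 0:
                e = potential.energies[categorize_contact(peptide.atoms[i])]
                num += e * solvent
                den += solvent
            assert energies[i] == pytest.approx(num / den, rel=1e-12)

    def test_zero_contact_atom_is_unscored(self, registry):
        s = _mini_structure(registry, [("A", 1, "ALA", "CA", (0, 0, 0))])
        contacts = ContactSet({}, {}, 1.4, n_atoms=1)
        assert atom_normalized_energies(s, contacts,
                                        _flat_potential(registry, {})) == {}

    def test_scheme_mismatch_rejected(self, registry):
        pot = _flat_potential(registry, {})
        pot.metadata["scheme"] = "other/v9"
        s = _mini_structure(registry, [("A", 1, "ALA", "CA", (0, 0, 0))])
        with pytest.raises(ValueError, match="scheme"):
            atom_normalized_energies(s, ContactSet({}, {}, 1.4), pot)


class TestQualityTransform:
    def test_half_exactly_at_mu(self, registry):
        pot = _flat_potential(registry, {}, mu=0.3, sigma=0.9)
        assert atom_quality(0.3, 1, pot) == 0.5

    @pytest.mark.parametrize("offset,expected", [
        (-1.0, norm.cdf(1.0)),   # one sigma *better* than the mean
        (+1.0, norm.cdf(-1.0)),  # one sigma worse
    ])
    def test_one_sigma_offsets_hit_normal_cdf(self, registry, offset, expected):
        pot = _flat_potential(registry, {}, mu=0.0, sigma=1.0)
        assert atom_quality(offset, 1, pot) == pytest.approx(expected, abs=1e-10)

    def test_favorable_limit_approaches_one(self, registry):
        pot = _flat_potential(registry, {}, mu=0.0, sigma=1.0)
        assert atom_quality(-50.0, 1, pot) == pytest.approx(1.0, abs=1e-12)
        assert atom_quality(+50.0, 1, pot) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_energy(self, registry):
        pot = _flat_potential(registry, {}, mu=0.1, sigma=0.5)
        values = [atom_quality(e, 1, pot) for e in np.linspace(-2, 2, 9)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_type_specific_params_take_precedence(self, registry):
        pot = PotentialTable({}, mu={5: 1.0}, sigma={5: 2.0},
                             global_mu=0.0, global_sigma=1.0)
        assert atom_quality(1.0, 5, pot) == 0.5       # type params
        assert atom_quality(0.0, 6, pot) == 0.5       # global fallback


class TestAggregation:
    def test_residue_mean(self, registry):
        s = _mini_structure(registry, [
            ("A", 1, "ALA", "CA", (0, 0, 0)),
            ("A", 1, "ALA", "CB", (1.5, 0, 0)),
            ("A", 2, "GLY", "CA", (3.8, 0, 0)),
        ])
        raw = residue_scores({0: 0.2, 1: 0.4, 2: 0.9}, s)
        assert raw[("A", 1, "")] == pytest.approx(0.3)
        assert raw[("A", 2, "")] == pytest.approx(0.9)

    def test_residue_without_scored_atoms_is_omitted(self, registry):
        s = _mini_structure(registry, [
            ("A", 1, "ALA", "CA", (0, 0, 0)),
            ("A", 2, "GLY", "CA", (3.8, 0, 0)),
        ])
        raw = residue_scores({0: 0.2}, s)
        assert ("A", 2, "") not in raw

    def test_global_weighted_mean(self):
        q = {0: 1.0, 1: 0.0}
        w = BurialWeights({0: 3, 1: 1})
        assert global_score(q, w) == pytest.approx(0.75)

    def test_global_is_fixed_point_for_constant_quality(self):
        rng = np.random.default_rng(0)
        q = {i: 0.37 for i in range(20)}
        w = BurialWeights({i: int(d) for i, d in
                           enumerate(rng.integers(1, 9, 20))})
        assert global_score(q, w) == pytest.approx(0.37, abs=1e-12)

    def test_no_scored_atoms_is_an_error(self):
        with pytest.raises(ValueError):
            global_score({}, BurialWeights({}))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
           st.integers(0, 7), st.floats(0.001, 1))
    def test_raising_one_quality_never_lowers_global(self, qualities, idx, bump):
        idx = idx % len(qualities)
        w = BurialWeights({i: 1 + (i % 3) for i in range(len(qualities))})
        q1 = dict(enumerate(qualities))
        q2 = dict(q1)
        q2[idx] = min(1.0, q2[idx] + bump)
        assert global_score(q2, w) >= global_score(q1, w) - 1e-12


class TestSmoothing:
    def _chain(self, registry, scores):
        specs = [("A", i + 1, "GLY", "CA", (3.8 * i, 0, 0))
                 for i in range(len(scores))]
        s = _mini_structure(registry, specs)
        raw = {("A", i + 1, ""): v for i, v in enumerate(scores)}
        return s, raw

    def test_constant_profile_unchanged(self, registry):
        s, raw = self._chain(registry, [0.4] * 6)
        assert smooth_residue_scores(raw, s, 5) == pytest.approx(raw)

    def test_window_one_is_identity(self, registry):
        s, raw = self._chain(registry, [0.1, 0.9, 0.2])
        assert smooth_residue_scores(raw, s, 1) == raw

    def test_shrinking_edge_rule(self, registry):
        s, raw = self._chain(registry, [0.0, 1.0, 0.0])
        sm = smooth_residue_scores(raw, s, 3)
        assert sm[("A", 1, "")] == pytest.approx(0.5)
        assert sm[("A", 2, "")] == pytest.approx(1 / 3)
        assert sm[("A", 3, "")] == pytest.approx(0.5)

    def test_even_window_rejected(self, registry):
        s, raw = self._chain(registry, [0.5, 0.5])
        with pytest.raises(ValueError):
            smooth_residue_scores(raw, s, 4)

    def test_no_smoothing_across_numbering_gaps(self, registry):
        specs = [("A", n, "GLY", "CA", (3.8 * i, 0, 0))
                 for i, n in enumerate([1, 2, 10, 11])]
        s = _mini_structure(registry, specs)
        raw = {("A", 1, ""): 0.0, ("A", 2, ""): 0.0,
               ("A", 10, ""): 1.0, ("A", 11, ""): 1.0}
        sm = smooth_residue_scores(raw, s, 3)
        assert sm[("A", 2, "")] == 0.0   # the gap isolates the two runs
        assert sm[("A", 10, "")] == 1.0

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.sampled_from([1, 3, 5, 7]))
    def test_smoothed_values_stay_within_raw_range(self, scores, window):
        from tessqa.structure import default_registry

        s, raw = self._chain(default_registry(), scores)
        sm = smooth_residue_scores(raw, s, window)
        assert min(sm.values()) >= min(raw.values()) - 1e-12
        assert max(sm.values()) <= max(raw.values()) + 1e-12


class TestReferenceBand:
    def test_identical_scores_collapse_all_curves(self):
        obs = [(50 + i, 0.42) for i in range(40)]
        band = reference_band(obs)
        for q, pts in band.items():
            assert all(v == pytest.approx(0.42) for _, v in pts)

    def test_uniform_scores_recover_order_statistics(self):
        rng = np.random.default_rng(13)
        obs = [(int(n), float(s)) for n, s in
               zip(rng.integers(30, 300, 4000), rng.random(4000))]
        band = reference_band(obs, n_bins=4)
        for q, pts in band.items():
            for _, v in pts:
                assert v == pytest.approx(q, abs=0.06)

    def test_quantiles_shift_with_constant_offset(self):
        rng = np.random.default_rng(14)
        obs = [(int(n), float(s)) for n, s in
               zip(rng.integers(30, 300, 500), rng.random(500))]
        shifted = [(n, s + 0.1) for n, s in obs]
        b1 = reference_band(obs, n_bins=3)
        b2 = reference_band(shifted, n_bins=3)
        for q in b1:
            for (x1, v1), (x2, v2) in zip(b1[q], b2[q]):
                assert x1 == x2
                assert v2 == pytest.approx(v1 + 0.1)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            reference_band([(100, 0.5)] * 19)


class TestFullProfile:
    def test_all_scores_in_unit_interval(self, peptide, peptide_contacts,
                                         potential):
        profile = score_structure(peptide, potential, contacts=peptide_contacts)
        values = (list(profile.atom_quality.values())
                  + list(profile.residue_raw.values())
                  + list(profile.residue_smoothed.values())
                  + [profile.global_score])
        assert all(0.0 <= v <= 1.0 for v in values)
        assert profile.n_atoms == len(peptide)
        assert profile.n_residues == len(peptide.residues())

    def test_residue_raw_equals_mean_of_atom_qualities(self, peptide,
                                                       peptide_contacts,
                                                       potential):
        profile = score_structure(peptide, potential, contacts=peptide_contacts)
        for key, atoms in peptide.residues().items():
            vals = [profile.atom_quality[a.atom_index] for a in atoms
                    if a.atom_index in profile.atom_quality]
            assert profile.residue_raw[key] == pytest.approx(np.mean(vals))

    def test_scoring_is_deterministic(self, small_peptide, potential):
        p1 = score_structure(small_peptide, potential)
        p2 = score_structure(small_peptide, potential)
        assert p1.global_score == p2.global_score
        assert p1.atom_quality == p2.atom_quality

    def test_rigid_motion_leaves_scores_invariant(self, small_peptide, potential):
        from dataclasses import replace

        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = Structure(
            [replace(a, center=rot @ a.center + np.array([3.0, -7.0, 1.0]))
             for a in small_peptide.atoms],
            label="moved",
        )
        p1 = score_structure(small_peptide, potential)
        p2 = score_structure(moved, potential)
        assert p2.global_score == pytest.approx(p1.global_score, abs=1e-6)
        for i, q in p1.atom_quality.items():
            assert p2.atom_quality[i] == pytest.approx(q, abs=1e-6)
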