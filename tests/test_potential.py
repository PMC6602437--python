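"""Contact typing, observation accumulation, training and serialization."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from tessqa.fixtures import make_synthetic_observations, make_toy_polypeptide
from tessqa.geometry import compute_contacts
from tessqa.potential import (
    ContactCategory,
    ObservationTable,
    PotentialFormatError,
    PotentialTable,
    categorize_contact,
    estimate_quality_params,
    independence_null,
    load_potential,
    realizable_types,
    save_potential,
    train_potential,
)


def _atom(chain, resseq, residue, name, registry):
    from tessqa.structure import AtomBall

    tid, radius, canonical = registry.lookup(residue, name)
    return AtomBall(0, chain, resseq, "", residue, canonical,
                    np.zeros(3), radius, tid, canonical[0])


class TestCategorize:
    def test_same_residue_is_sequence_near(self, registry):
        a = _atom("A", 5, "ALA", "CA", registry)
        b = _atom("A", 5, "ALA", "CB", registry)
        assert categorize_contact(a, b)[2] == ContactCategory.SEQ_NEAR

    def test_adjacent_residues_are_sequence_near(self, registry):
        a = _atom("A", 5, "ALA", "C", registry)
        b = _atom("A", 6, "GLY", "N", registry)
        assert categorize_contact(a, b)[2] == ContactCategory.SEQ_NEAR

    def test_separation_two_is_sequence_far(self, registry):
        a = _atom("A", 5, "ALA", "CA", registry)
        b = _atom("A", 7, "GLY", "CA", registry)
        assert categorize_contact(a, b)[2] == ContactCategory.SEQ_FAR

    def test_interchain_is_sequence_far_and_canonical(self, registry):
        a = _atom("A", 5, "ALA", "CA", registry)
        b = _atom("B", 5, "GLY", "CA", registry)
        ta, tb, cat = categorize_contact(a, b)
        assert cat == ContactCategory.SEQ_FAR
        assert ta <= tb
        assert categorize_contact(b, a) == (ta, tb, cat)

    def test_solvent_partner(self, registry):
        a = _atom("A", 5, "ALA", "CA", registry)
        assert categorize_contact(a) == (0, a.atom_type, ContactCategory.SOLVENT)


class TestObservations:
    def test_single_contact_accumulates_its_area(self, registry):
        obs = ObservationTable()
        obs.add(3, 1, ContactCategory.SEQ_FAR, 5.0)
        assert obs.areas == {(1, 3, ContactCategory.SEQ_FAR): 5.0}
        assert obs.grand_total == 5.0

    def test_double_accumulation_doubles_totals(self, small_peptide):
        contacts = compute_contacts(small_peptide)
        once = ObservationTable()
        once.add_contact_set(small_peptide, contacts)
        twice = ObservationTable()
        twice.add_contact_set(small_peptide, contacts)
        twice.add_contact_set(small_peptide, contacts)
        for key, area in once.areas.items():
            assert twice.areas[key] == pytest.approx(2 * area, rel=1e-12)

    def test_merge_equals_joint_accumulation(self, small_peptide, helix):
        ca = compute_contacts(small_peptide)
        cb = compute_contacts(helix)
        joint = ObservationTable()
        joint.add_contact_set(small_peptide, ca)
        joint.add_contact_set(helix, cb)
        left = ObservationTable()
        left.add_contact_set(small_peptide, ca)
        right = ObservationTable()
        right.add_contact_set(helix, cb)
        left.merge(right)
        assert left.areas.keys() == joint.areas.keys()
        for key in joint.areas:
            assert left.areas[key] == pytest.approx(joint.areas[key], rel=1e-12)


def _product_form_distribution(registry, n_types=3):
    types = registry.protein_types[:n_types]
    f0 = dict(zip(types, [0.5, 0.3, 0.2]))
    g0 = {ContactCategory.SEQ_NEAR: 0.45, ContactCategory.SEQ_FAR: 0.35,
          ContactCategory.SOLVENT: 0.2}
    probs = {}
    for a, b in itertools.combinations_with_replacement(types, 2):
        for cat in (ContactCategory.SEQ_NEAR, ContactCategory.SEQ_FAR):
            probs[(a, b, cat)] = g0[cat] * f0[a] * f0[b] * (1 if a == b else 2)
    for a in types:
        probs[(0, a, ContactCategory.SOLVENT)] = g0[ContactCategory.SOLVENT] * f0[a]
    return probs, types


class TestTraining:
    def test_observed_equal_to_expected_gives_zero_energies(self, registry):
        probs, _ = _product_form_distribution(registry)
        assert sum(probs.values()) == pytest.approx(1.0)
        obs = ObservationTable({k: 1000.0 * p for k, p in probs.items()})
        pot = train_potential(obs, pseudocount=0.0, type_space="observed")
        assert max(abs(e) for e in pot.energies.values()) < 1e-9

    def test_independence_null_hand_computed(self):
        # One self-pair plus one solvent type: the endpoint marginal is
        # concentrated on a single atom type (f = 1), so the null equals
        # the category marginals; both energies are ln(1) = 0.
        near, solv = ContactCategory.SEQ_NEAR, ContactCategory.SOLVENT
        probs = {(1, 1, near): 0.5, (0, 1, solv): 0.5}
        null = independence_null(probs)
        assert null[(1, 1, near)] == pytest.approx(0.5)
        assert null[(0, 1, solv)] == pytest.approx(0.5)

    def test_recovers_known_energies_from_sampled_quanta(self, registry):
        probs, types = _product_form_distribution(registry)
        near = ContactCategory.SEQ_NEAR
        far = ContactCategory.SEQ_FAR
        probs[(types[0], types[1], near)] *= 1.6
        probs[(types[1], types[2], far)] *= 0.55
        z = sum(probs.values())
        probs = {k: v / z for k, v in probs.items()}
        obs, truth = make_synthetic_observations(probs, n_quanta=100_000, seed=5)
        pot = train_potential(obs, pseudocount=1.0, type_space="observed")
        for key, e_true in truth.items():
            assert pot.energies[key] == pytest.approx(e_true, abs=0.05)
        # Over-represented types get negative energies, depleted ones positive
        # (the tilt also shifts the null's marginals, so magnitudes differ
        # from the bare log factors).
        assert truth[(types[0], types[1], near)] < 0
        assert truth[(types[1], types[2], far)] > 0

    def test_scale_invariance_is_bit_exact(self, registry):
        probs, _ = _product_form_distribution(registry)
        obs, _ = make_synthetic_observations(probs, n_quanta=20_000, seed=9)
        pot1 = train_potential(obs, pseudocount=1.0, type_space="observed")
        doubled = ObservationTable({k: 2.0 * v for k, v in obs.areas.items()})
        pot2 = train_potential(doubled, pseudocount=2.0, type_space="observed")
        assert pot1.energies == pot2.energies

    def test_zero_area_types_require_positive_pseudocount(self, registry):
        obs = ObservationTable()
        obs.add(1, 2, ContactCategory.SEQ_FAR, 10.0)
        with pytest.raises(ValueError, match="pseudocount"):
            train_potential(obs, pseudocount=0.0)  # registry space has zeros

    def test_registry_space_covers_every_realizable_type(self, registry, potential):
        assert set(potential.energies) == set(realizable_types(registry))

    def test_energy_lookup_is_symmetric(self, potential):
        (a, b, cat) = next(iter(potential.energies))
        assert potential.energy(b, a, cat) == potential.energy(a, b, cat)


class TestQualityParams:
    def test_two_point_sample_statistics(self):
        mu, sigma, gmu, gsigma = estimate_quality_params({7: [0.0, 2.0]})
        assert mu[7] == pytest.approx(1.0)
        assert sigma[7] == pytest.approx(math.sqrt(2.0))

    def test_constant_values_fall_back_to_global(self):
        mu, sigma, gmu, gsigma = estimate_quality_params(
            {1: [0.5, 0.5, 0.5], 2: [0.0, 1.0]}
        )
        assert sigma[1] == gsigma > 0
        assert mu[1] == gmu

    def test_all_identical_energies_rejected(self):
        with pytest.raises(ValueError):
            estimate_quality_params({1: [0.3, 0.3], 2: [0.3, 0.3]})

    def test_normal_parameter_recovery(self):
        rng = np.random.default_rng(21)
        mu0, sigma0, n = -0.4, 0.7, 10_000
        values = rng.normal(mu0, sigma0, n)
        mu, sigma, _, _ = estimate_quality_params({3: values.tolist()})
        assert mu[3] == pytest.approx(mu0, abs=3 * sigma0 / math.sqrt(n))
        assert sigma[3] == pytest.approx(sigma0, abs=3 * sigma0 / math.sqrt(2 * n))


class TestSerialization:
    def test_save_load_roundtrip(self, potential, tmp_path):
        path = tmp_path / "potential.tsv"
        save_potential(potential, path)
        back = load_potential(path)
        assert back.metadata["scheme"] == potential.metadata["scheme"]
        assert set(back.energies) == set(potential.energies)
        for key, e in potential.energies.items():
            assert back.energies[key] == pytest.approx(e, abs=1e-7)
        for t in potential.mu:
            assert back.mu[t] == pytest.approx(potential.mu[t], abs=1e-7)
            assert back.sigma[t] == pytest.approx(potential.sigma[t], abs=1e-7)
        assert back.global_sigma == pytest.approx(potential.global_sigma, abs=1e-7)

    def test_truncated_file_is_a_parse_error(self, potential, tmp_path):
        path = tmp_path / "potential.tsv"
        save_potential(potential, path)
        text = path.read_text()
        path.write_text(text[: text.index("[quality_params]")])
        with pytest.raises(PotentialFormatError, match="quality_params"):
            load_potential(path)

    def test_zero_sigma_row_is_rejected(self, tmp_path, registry):
        tname = registry.type_name(1)
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#version 1\n[energies]\ntype_a\ttype_b\tcategory\tE\n"
            f"{tname}\t{tname}\tseq_near\t0.5\n"
            "[quality_params]\natom_type\tmu\tsigma\n"
            "GLOBAL\t0.0\t1.0\n"
            f"{tname}\t0.10000000\t0.00000000\n"
        )
        with pytest.raises(PotentialFormatError, match="sigma"):
            load_potential(path)

    def test_nonfinite_energy_names_the_row(self, tmp_path, registry):
        tname = registry.type_name(1)
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#version 1\n[energies]\ntype_a\ttype_b\tcategory\tE\n"
            f"{tname}\t{tname}\tseq_near\tnan\n"
            "[quality_params]\natom_type\tmu\tsigma\nGLOBAL\t0.0\t1.0\n"
        )
        with pytest.raises(PotentialFormatError, match=":4"):
            load_potential(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#version 99\n[energies]\n")
        with pytest.raises(PotentialFormatError, match="version"):
            load_potential(path)
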