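"""Corpus filtering, tokenization, QED and activity-domain partitioning."""

import math

import numpy as np
import pytest

from moldesign.corpus import (
    FilterCriteria,
    MoleculeRecord,
    PartitionThresholds,
    build_alphabet,
    compute_qed,
    detokenize,
    filter_corpus,
    partition_target_domain,
    smiles_tokens,
    tokenize,
)
from moldesign.fixtures import generate_smiles_corpus


class TestFilterCorpus:
    @pytest.mark.parametrize(
        "smiles, rule",
        [
            ("CCO", "heavy_atom_range"),  # 2 heavy atoms, below minimum 5
            ("CP(=O)(O)O", "allowed_atomic_numbers"),  # phosphorus not allowed
            ("C((", "parse"),
        ],
    )
    def test_rejection_rules(self, smiles, rule):
        _, rejections = filter_corpus([smiles])
        assert rejections[rule] == 1
        assert sum(rejections.values()) == 1

    def test_retained_molecule(self):
        retained, rejections = filter_corpus(["c1ccccc1CCN"])
        assert len(retained) == 1
        assert sum(rejections.values()) == 0
        assert retained[0].canonical_smiles == "NCCc1ccccc1"

    def test_raw_length_measured_on_input_string(self):
        crit = FilterCriteria(max_smiles_length=10)
        _, rej = filter_corpus(["C/C=C/" + "C" * 10], crit)
        assert rej["smiles_length"] == 1

    def test_exclude_set_matches_canonical_form(self):
        crit = FilterCriteria(exclude_set=frozenset({"NCCc1ccccc1"}))
        _, rej = filter_corpus(["c1ccccc1CCN"], crit)
        assert rej["exclude_set"] == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_corpus([])

    def test_idempotent_on_retained(self, fixture_corpus):
        retained, _ = filter_corpus(fixture_corpus)
        again, rejections = filter_corpus([r.raw_smiles for r in retained])
        assert len(again) == len(retained)
        assert sum(rejections.values()) == 0


class TestTokenization:
    def test_alphabet_covers_corpora_plus_specials(self):
        alpha = build_alphabet([["CCO", "CCN"]])
        assert set(alpha.tokens) == {"<pad>", "<s>", "</s>", "C", "O", "N"}
        assert len(alpha) == 6

    def test_two_character_elements_are_single_tokens(self):
        assert smiles_tokens("Brc1ccccc1") == ["Br", "c", "1", "c", "c", "c", "c", "c", "1"]
        alpha = build_alphabet([["Brc1ccccc1", "Clc1ccccc1"]])
        assert "Br" in alpha.tokens and "Cl" in alpha.tokens

    def test_framing_and_round_trip(self):
        alpha = build_alphabet([["CCO"]])
        ids = tokenize("CCO", alpha)
        assert ids[0] == alpha.start_id and ids[-1] == alpha.end_id
        assert len(ids) == 5
        assert detokenize(ids, alpha) == "CCO"

    def test_empty_smiles(self):
        alpha = build_alphabet([["C"]])
        assert tokenize("", alpha) == [alpha.start_id, alpha.end_id]

    def test_padding(self):
        alpha = build_alphabet([["CCO"]])
        ids = tokenize("CCO", alpha, pad_to=8)
        assert len(ids) == 8 and ids[5:] == [alpha.pad_id] * 3

    def test_unknown_token_named_in_error(self):
        alpha = build_alphabet([["CCO"]])
        with pytest.raises(KeyError, match="Br"):
            tokenize("BrCC", alpha)

    def test_round_trip_over_fixture_corpus(self):
        corpus = generate_smiles_corpus(1000, seed=5)
        alpha = build_alphabet([corpus])
        assert all(detokenize(tokenize(s, alpha), alpha) == s for s in corpus)


class TestQed:
    def test_spelling_invariance_and_bounds(self):
        assert compute_qed("CCO") == compute_qed("OCC")
        assert 0.0 <= compute_qed("CCO") <= 1.0

    def test_caffeine_more_druglike_than_benzene(self):
        caffeine = "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"
        assert compute_qed(caffeine) > compute_qed("c1ccccc1")

    def test_invalid_molecule_errors(self):
        with pytest.raises(ValueError):
            compute_qed("not-a-smiles")


def _rec(qed, ic50):
    return MoleculeRecord("C", "C", qed=qed, ic50=ic50, pic50=-math.log10(ic50 * 1e-6))


class TestPartition:
    @pytest.mark.parametrize(
        "qed, ic50, subset",
        [
            (0.7, 0.5, "A"),
            (0.7, 5.0, "B"),
            (0.3, 0.5, "C"),
            (0.3, 5.0, "D"),
            # boundaries: QED at the split is non-drug-like; IC50 at the split
            # falls in the low-activity branch
            (0.6, 1.0, "D"),
            (0.7, 1.0, "B"),
            (0.6, 0.5, "C"),
        ],
    )
    def test_crc_boundary_cases(self, qed, ic50, subset):
        subsets, _ = partition_target_domain([_rec(qed, ic50)], PartitionThresholds.CRC)
        assert [len(v) for k, v in subsets.items() if k == subset] == [1]
        assert sum(len(v) for v in subsets.values()) == 1

    def test_out_of_range_reported_not_dropped(self):
        subsets, oor = partition_target_domain([_rec(0.7, 50.0)], PartitionThresholds.CRC)
        assert sum(len(v) for v in subsets.values()) == 0
        assert len(oor) == 1

    def test_empty_input(self):
        subsets, oor = partition_target_domain([], PartitionThresholds.CRC)
        assert all(len(v) == 0 for v in subsets.values()) and oor == []

    def test_missing_fields_error(self):
        with pytest.raises(ValueError, match="missing"):
            partition_target_domain([MoleculeRecord("C", "C")])

    def test_disjoint_and_covering_on_fixture_records(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(qed=float(rng.uniform(0, 1)), ic50=float(rng.uniform(0.01, 20)))
            for _ in range(1000)
        ]
        t = PartitionThresholds.CRC
        subsets, oor = partition_target_domain(records, t)
        counted = sum(len(v) for v in subsets.values())
        in_range = [r for r in records if t.ic50_min < r.ic50 <= t.ic50_max]
        assert counted == len(in_range)
        assert counted + len(oor) == len(records)
        ids = [id(r) for v in subsets.values() for r in v]
        assert len(ids) == len(set(ids))  # pairwise disjoint

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            PartitionThresholds(ic50_split=5.0, ic50_max=1.0)


class TestMoleculeRecord:
    def test_pic50_ic50_consistency(self):
        r = MoleculeRecord.from_smiles("c1ccccc1CCN", ic50=1.0)
        assert r.pic50 == pytest.approx(6.0, abs=1e-9)
        r2 = MoleculeRecord.from_smiles("c1ccccc1CCN", pic50=7.0)
        assert r2.ic50 == pytest.approx(0.1, abs=1e-9)

    def test_invalid_smiles_raises(self):
        with pytest.raises(ValueError):
            MoleculeRecord.from_smiles("((")
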