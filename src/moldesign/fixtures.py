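"""Deterministic synthetic chemistry data.

Molecules are assembled from a small fragment grammar (aromatic and aliphatic
ring cores with drug-like substituents over C/N/O/F/S/Cl/Br) so that every
generated SMILES is valid by construction and satisfies the default corpus
filter criteria. Activity datasets carry a known structure-activity rule
(pIC50 is a weighted sum of substructure counts plus Gaussian noise), so
recovery tests can score models against ground truth.

These generators emulate the *structural and statistical assumptions* the
pipeline needs (valid strings, a learnable token distribution, a substructure-
driven activity signal); they do not emulate the property distributions of a
real screening database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .corpus import (
    FilterCriteria,
    MoleculeRecord,
    compute_qed,
    ic50_uM_from_pic50,
)

__all__ = [
    "ActivityRule",
    "generate_smiles_corpus",
    "generate_activity_dataset",
    "DEFAULT_ACTIVITY_RULE",
]

# ring cores written with substitution slots; every slot sits on an aromatic
# carbon (or sp3 ring carbon), so any substituent below splices in validly
_CORES_1 = [
    "c1ccc({R0})cc1",
    "c1ccc({R0})nc1",
    "c1cc({R0})cco1",
    "C1CCC({R0})CC1",
    "C1CCN({R0})CC1",
]
_CORES_2 = [
    "c1cc({R0})ccc1{R1}",
    "c1cc({R0})cc({R1})c1",
    "c1nc({R0})ccc1{R1}",
    "C1CC({R0})CCC1{R1}",
]

# substituents; the "sulfur" entries are the transfer-learning marker fragments
_PLAIN_SUBS = [
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "NC",
    "N(C)C",
    "F",
    "Cl",
    "Br",
    "C#N",
    "C(F)(F)F",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)N",
    "C(=O)NC",
    "CO",
    "CN",
    "CCO",
    "C=C",
    "c1ccccc1",
    "c1ccncc1",
]
_SULFUR_SUBS = ["SC", "SCC", "S(=O)(=O)C", "c1cccs1", "CSC"]


def _assemble(rng: np.random.Generator, subs: list[str], force_marker: bool) -> str:
    if rng.random() < 0.45:
        core = _CORES_1[rng.integers(len(_CORES_1))]
        n_slots = 1
    else:
        core = _CORES_2[rng.integers(len(_CORES_2))]
        n_slots = 2
    chosen = [subs[rng.integers(len(subs))] for _ in range(n_slots)]
    if force_marker:
        chosen[rng.integers(n_slots)] = _SULFUR_SUBS[rng.integers(len(_SULFUR_SUBS))]
    smiles = core
    for i, sub in enumerate(chosen):
        smiles = smiles.replace("{R%d}" % i, sub)
    return smiles


def generate_smiles_corpus(
    n: int,
    seed: int,
    constraints: FilterCriteria | None = None,
    marker_fraction: float = 0.1,
    unique: bool = False,
) -> list[str]:
    """Generate ``n`` valid SMILES within the filter constraints.

    ``marker_fraction`` of the molecules are forced to carry a sulfur-bearing
    marker fragment (used by the transfer-learning tests); set it to 1.0 for a
    marker-only target domain. With ``unique=True`` duplicates are resampled
    until exhausted, after which duplicates are allowed with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    constraints = constraints or FilterCriteria()
    lo, hi = constraints.heavy_atom_range
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            if unique:
                warnings.warn(
                    "fragment-grammar capacity exhausted; allowing duplicates"
                )
                unique = False
                continue
            raise ValueError("constraints unsatisfiable for fragment grammar")
        force = rng.random() < marker_fraction
        smiles = _assemble(rng, _PLAIN_SUBS, force)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees validity; guard anyway
            continue
        if not (lo <= mol.GetNumHeavyAtoms() <= hi):
            continue
        if len(smiles) > constraints.max_smiles_length:
            continue
        if any(
            a.GetAtomicNum() not in constraints.allowed_atomic_numbers
            for a in mol.GetAtoms()
        ):
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in constraints.exclude_set:
            continue
        if unique and canonical in seen:
            continue
        seen.add(canonical)
        out.append(smiles)
    return out


@dataclass
class ActivityRule:
    """Ground-truth structure-activity rule for synthetic datasets.

    pIC50 = base + sum_f weight_f * count(substructure_f) + N(0, noise_sigma).
    ``active_ic50_uM`` thresholds the binary label (active := IC50 below it).
    """

    base: float = 5.5
    substructure_weights: dict[str, float] = field(
        default_factory=lambda: {
            "[OX2H]": 0.45,  # hydroxyl
            "F": 0.35,
            "Cl": 0.35,
            "C(=O)N": 0.5,
            "n": 0.25,  # aromatic nitrogen
            "[#16]": 0.6,  # sulfur marker
        }
    )
    active_ic50_uM: float = 1.0

    def pic50_mean(self, smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid molecule: {smiles!r}")
        total = self.base
        for smarts, w in self.substructure_weights.items():
            patt = Chem.MolFromSmarts(smarts)
            total += w * len(mol.GetSubstructMatches(patt))
        return total


DEFAULT_ACTIVITY_RULE = ActivityRule()


def generate_activity_dataset(
    n: int,
    seed: int,
    noise_sigma: float = 0.3,
    rule_spec: ActivityRule | None = None,
) -> tuple[list[MoleculeRecord], ActivityRule]:
    """Records with pIC50/IC50/labels drawn from a known substructure rule.

    Returns the records and the generating rule so tests can score models
    against the truth.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rule = rule_spec or DEFAULT_ACTIVITY_RULE
    rng = np.random.default_rng(seed)
    smiles = generate_smiles_corpus(n, seed=int(rng.integers(2**31)), unique=True)
    records = []
    for s in smiles:
        pic50 = rule.pic50_mean(s) + rng.normal(0.0, noise_sigma)
        ic50 = ic50_uM_from_pic50(pic50)
        records.append(
            MoleculeRecord(
                raw_smiles=s,
                canonical_smiles=Chem.MolToSmiles(Chem.MolFromSmiles(s)),
                qed=compute_qed(s),
                ic50=ic50,
                pic50=pic50,
                active_label=int(ic50 < rule.active_ic50_uM),
            )
        )
    return records, rule
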