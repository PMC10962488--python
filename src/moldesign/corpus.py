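"""SMILES corpus handling: parsing, filtering, tokenization and activity partitions.

A pretraining corpus is cleaned with structural filter criteria (parseable,
raw-string length, heavy-atom count, an element whitelist, exclusion of known
actives), tokenized over a corpus-derived alphabet, and activity datasets are
split into the four drug-likeness x potency sub-domains used as transfer
targets:

    A: QED > split and ic50_min < IC50 < ic50_split   (drug-like, high activity)
    B: QED > split and ic50_split <= IC50 <= ic50_max (drug-like, low activity)
    C: QED <= split and ic50_min < IC50 < ic50_split
    D: QED <= split and ic50_split <= IC50 <= ic50_max

IC50 is in micromolar throughout; pIC50 = -log10 of the molar IC50.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import QED

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "FilterCriteria",
    "TokenAlphabet",
    "PartitionThresholds",
    "canonicalize",
    "compute_qed",
    "filter_corpus",
    "build_alphabet",
    "tokenize",
    "detokenize",
    "partition_target_domain",
    "pic50_from_ic50_uM",
    "ic50_uM_from_pic50",
]

#: default element whitelist (atomic numbers; 0 = unspecified/dummy atom)
DEFAULT_ALLOWED_ATOMS = frozenset({0, 6, 7, 8, 9, 16, 17, 35})

#: two-character element symbols kept as single tokens
TWO_CHAR_TOKENS = ("Cl", "Br")


def pic50_from_ic50_uM(ic50_uM: float) -> float:
    """pIC50 from a micromolar IC50 (pIC50 = -log10(IC50 * 1e-6))."""
    return -math.log10(ic50_uM * 1e-6)


def ic50_uM_from_pic50(pic50: float) -> float:
    return 10.0 ** (-pic50) * 1e6


def canonicalize(smiles: str) -> str | None:
    """Toolkit-canonical aromatic SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass
class MoleculeRecord:
    """One molecule with its drug-likeness and (optional) activity annotations."""

    raw_smiles: str
    canonical_smiles: str
    qed: float | None = None
    ic50: float | None = None  # micromolar
    pic50: float | None = None
    active_label: int | None = None

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        ic50: float | None = None,
        pic50: float | None = None,
        active_label: int | None = None,
        with_qed: bool = True,
    ) -> "MoleculeRecord":
        canonical = canonicalize(smiles)
        if canonical is None:
            raise ValueError(f"SMILES does not parse: {smiles!r}")
        if ic50 is not None and pic50 is None:
            pic50 = pic50_from_ic50_uM(ic50)
        elif pic50 is not None and ic50 is None:
            ic50 = ic50_uM_from_pic50(pic50)
        qed = compute_qed(canonical) if with_qed else None
        return cls(smiles, canonical, qed, ic50, pic50, active_label)


def compute_qed(smiles_or_record) -> float:
    """Quantitative estimate of drug-likeness in [0, 1] for a molecule."""
    smiles = (
        smiles_or_record.canonical_smiles
        if isinstance(smiles_or_record, MoleculeRecord)
        else smiles_or_record
    )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return float(QED.qed(mol))


@dataclass
class FilterCriteria:
    """Structural admission rules for the pretraining corpus."""

    max_smiles_length: int = 120
    heavy_atom_range: tuple[int, int] = (5, 70)
    allowed_atomic_numbers: frozenset[int] = DEFAULT_ALLOWED_ATOMS
    exclude_set: frozenset[str] = frozenset()  # canonical SMILES of known actives

    def __post_init__(self):
        lo, hi = self.heavy_atom_range
        if lo > hi:
            raise ValueError("heavy_atom_range must be a nonempty interval")
        if self.max_smiles_length <= 0:
            raise ValueError("max_smiles_length must be positive")
        self.allowed_atomic_numbers = frozenset(self.allowed_atomic_numbers)
        self.exclude_set = frozenset(self.exclude_set)


def filter_corpus(
    smiles_list: Sequence[str], criteria: FilterCriteria | None = None
) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Apply the admission rules; return retained records and per-rule rejections.

    Rules are checked in a fixed order (parse, smiles_length, heavy_atom_range,
    allowed_atomic_numbers, exclude_set) and a dropped molecule is counted under
    the first rule it fails. The raw input string, not the canonical form, is
    measured against the length cap.
    """
    if not smiles_list:
        raise ValueError("empty SMILES list")
    criteria = criteria or FilterCriteria()
    retained: list[MoleculeRecord] = []
    rejections = {
        "parse": 0,
        "smiles_length": 0,
        "heavy_atom_range": 0,
        "allowed_atomic_numbers": 0,
        "exclude_set": 0,
    }
    lo, hi = criteria.heavy_atom_range
    for raw in smiles_list:
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            rejections["parse"] += 1
            continue
        if len(raw) > criteria.max_smiles_length:
            rejections["smiles_length"] += 1
            continue
        if not (lo <= mol.GetNumHeavyAtoms() <= hi):
            rejections["heavy_atom_range"] += 1
            continue
        if any(
            a.GetAtomicNum() not in criteria.allowed_atomic_numbers
            for a in mol.GetAtoms()
        ):
            rejections["allowed_atomic_numbers"] += 1
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in criteria.exclude_set:
            rejections["exclude_set"] += 1
            continue
        retained.append(
            MoleculeRecord(raw, canonical, qed=float(QED.qed(mol)))
        )
    return retained, rejections


# ---------------------------------------------------------------------------
# tokenization


def smiles_tokens(smiles: str) -> list[str]:
    """Character tokens, with two-character elements (Cl, Br) kept whole."""
    tokens = []
    i = 0
    n = len(smiles)
    while i < n:
        if smiles[i : i + 2] in TWO_CHAR_TOKENS:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@dataclass
class TokenAlphabet:
    """Ordered token set with pad/start/end specials for sequence encoding."""

    tokens: list[str]
    pad: str = "<pad>"
    start: str = "<s>"
    end: str = "</s>"
    index_of: dict[str, int] = field(init=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("alphabet tokens must be unique")
        for s in (self.pad, self.start, self.end):
            if s not in self.tokens:
                raise ValueError(f"special token {s!r} missing from alphabet")
        self.index_of = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index_of[self.pad]

    @property
    def start_id(self) -> int:
        return self.index_of[self.start]

    @property
    def end_id(self) -> int:
        return self.index_of[self.end]

    def to_json(self) -> str:
        return json.dumps(
            {"tokens": self.tokens, "pad": self.pad, "start": self.start, "end": self.end}
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenAlphabet":
        d = json.loads(text)
        return cls(d["tokens"], pad=d["pad"], start=d["start"], end=d["end"])


def build_alphabet(corpora: Iterable[Sequence[str]]) -> TokenAlphabet:
    """Alphabet covering every token in every corpus, plus the three specials.

    Content tokens are sorted so the alphabet (hence model input encoding) is
    independent of corpus order.
    """
    corpora = list(corpora)
    if not corpora:
        raise ValueError("no corpora supplied")
    seen: set[str] = set()
    for corpus in corpora:
        for s in corpus:
            seen.update(smiles_tokens(s))
    tokens = ["<pad>", "<s>", "</s>"] + sorted(seen)
    return TokenAlphabet(tokens)


def tokenize(smiles: str, alphabet: TokenAlphabet, pad_to: int | None = None) -> list[int]:
    """Encode a SMILES as [start, ...content..., end] ids, optionally padded."""
    ids = [alphabet.start_id]
    for tok in smiles_tokens(smiles):
        if tok not in alphabet.index_of:
            raise KeyError(f"token {tok!r} not in alphabet")
        ids.append(alphabet.index_of[tok])
    ids.append(alphabet.end_id)
    if pad_to is not None:
        if len(ids) > pad_to:
            raise ValueError(f"sequence length {len(ids)} exceeds pad_to={pad_to}")
        ids = ids + [alphabet.pad_id] * (pad_to - len(ids))
    return ids


def detokenize(ids: Sequence[int], alphabet: TokenAlphabet) -> str:
    """Inverse of :func:`tokenize`; specials are stripped, decoding stops at end."""
    out = []
    specials = {alphabet.pad_id, alphabet.start_id}
    for i in ids:
        if i == alphabet.end_id:
            break
        if i in specials:
            continue
        out.append(alphabet.tokens[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# activity-domain partition


@dataclass
class PartitionThresholds:
    """QED and IC50 cut points for the A/B/C/D sub-domains (IC50 in µM)."""

    qed_split: float = 0.6
    ic50_min: float = 0.0
    ic50_split: float = 1.0
    ic50_max: float = 10.0

    CRC = None  # set below
    AD = None

    def __post_init__(self):
        if not (self.ic50_min < self.ic50_split <= self.ic50_max):
            raise ValueError("need ic50_min < ic50_split <= ic50_max")
        if not (0.0 < self.qed_split < 1.0):
            raise ValueError("qed_split must lie in (0, 1)")


PartitionThresholds.CRC = PartitionThresholds(0.6, 0.0, 1.0, 10.0)
PartitionThresholds.AD = PartitionThresholds(0.6, 0.0, 50.0, 100.0)


def partition_target_domain(
    records: Sequence[MoleculeRecord],
    thresholds: PartitionThresholds | None = None,
) -> tuple[dict[str, list[MoleculeRecord]], list[MoleculeRecord]]:
    """Split records into the A/B/C/D sub-domains; out-of-range records returned
    separately (IC50 outside (ic50_min, ic50_max]), never silently dropped."""
    t = thresholds or PartitionThresholds()
    missing = [r for r in records if r.qed is None or r.ic50 is None]
    if missing:
        names = ", ".join(r.canonical_smiles for r in missing[:5])
        raise ValueError(f"records missing qed/ic50: {names}" + ("..." if len(missing) > 5 else ""))
    subsets: dict[str, list[MoleculeRecord]] = {"A": [], "B": [], "C": [], "D": []}
    out_of_range: list[MoleculeRecord] = []
    for r in records:
        high = t.ic50_min < r.ic50 < t.ic50_split
        low = t.ic50_split <= r.ic50 <= t.ic50_max
        druglike = r.qed > t.qed_split
        if high:
            subsets["A" if druglike else "C"].append(r)
        elif low:
            subsets["B" if druglike else "D"].append(r)
        else:
            out_of_range.append(r)
    return subsets, out_of_range
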