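"""Generation-quality metrics, similarity, chemical-space maps and SA scores.

For each sampling repetition of N_sample strings the cascade of metrics is:

    Validity    = N_valid / N_sample
    Uniqueness  = N_unique_valid / N_valid
    QEDrequest  = |unique valid with QED > threshold| / N_unique_valid
    Leadrequest = |of those, predicted active| / |QED-qualified|
    Novelty     = |of those, outside training+finetune sets| / |active-qualified|

with the companion counts Num_QEDrequest, Num_Lead, Num_NovelLead given by the
product identities (N_sample x Validity x Uniqueness x ... ), which equal the
direct counts exactly per repetition. A report averages the per-repetition
values. Degenerate denominators (e.g. no valid molecule) define the downstream
ratio as 0 with a logged warning.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, DataStructs

from .corpus import MoleculeRecord, compute_qed

logger = logging.getLogger(__name__)

__all__ = [
    "RepetitionMetrics",
    "GenerationReport",
    "evaluate_generation",
    "tanimoto_similarity",
    "embed_chemical_space",
    "sa_score",
]


@dataclass
class RepetitionMetrics:
    """Counts and percentage metrics for one sampling repetition."""

    n_sample: int
    n_valid: int
    n_unique_valid: int
    n_qed: int
    n_lead: int | None
    n_novel_lead: int | None
    validity: float
    uniqueness: float
    qed_request: float
    lead_request: float | None
    novelty: float | None


@dataclass
class GenerationReport:
    """Averaged metric bundle over sampling repetitions (percentages in [0,100])."""

    n_sample: int
    repetitions: int
    validity: float
    uniqueness: float
    qed_request: float
    lead_request: float | None
    novelty: float | None
    num_qed_request: float
    num_lead: float | None
    num_novel_lead: float | None
    per_repetition: list[RepetitionMetrics] = field(default_factory=list)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("no molecules in denominator of %s; defining it as 0", name)
        return 0.0
    return num / den


def evaluate_generation(
    samples_by_repetition: Sequence[Sequence[str]],
    training_set: set[str],
    finetune_set: set[str],
    qed_threshold: float = 0.6,
    activity_model=None,
) -> GenerationReport:
    """Compute the metric cascade per repetition and average over repetitions.

    ``activity_model`` must expose ``predict(list_of_smiles) -> 0/1``; without
    one the lead/novelty fields are None (logged warning). Reference sets are
    canonical-SMILES sets; uniqueness also compares canonical forms.
    """
    if not samples_by_repetition or any(len(r) == 0 for r in samples_by_repetition):
        raise ValueError("each repetition must be nonempty")
    if activity_model is None:
        logger.warning("no activity model; lead/novelty metrics unavailable")
    known = set(training_set) | set(finetune_set)
    reps: list[RepetitionMetrics] = []
    for rep in samples_by_repetition:
        n_sample = len(rep)
        canon = []
        for s in rep:
            mol = Chem.MolFromSmiles(s) if s else None
            if mol is not None:
                canon.append(Chem.MolToSmiles(mol))
        n_valid = len(canon)
        unique = list(dict.fromkeys(canon))
        n_unique = len(unique)
        qed_ok = [s for s in unique if compute_qed(s) > qed_threshold]
        n_qed = len(qed_ok)
        if activity_model is not None:
            if qed_ok:
                preds = np.asarray(activity_model.predict(qed_ok)).astype(bool)
                leads = [s for s, p in zip(qed_ok, preds) if p]
            else:
                leads = []
            novel = [s for s in leads if s not in known]
            n_lead, n_novel = len(leads), len(novel)
            lead_request = 100.0 * _ratio(n_lead, n_qed, "Leadrequest")
            novelty = 100.0 * _ratio(n_novel, n_lead, "Novelty")
        else:
            n_lead = n_novel = None
            lead_request = novelty = None
        reps.append(
            RepetitionMetrics(
                n_sample=n_sample,
                n_valid=n_valid,
                n_unique_valid=n_unique,
                n_qed=n_qed,
                n_lead=n_lead,
                n_novel_lead=n_novel,
                validity=100.0 * _ratio(n_valid, n_sample, "Validity"),
                uniqueness=100.0 * _ratio(n_unique, n_valid, "Uniqueness"),
                qed_request=100.0 * _ratio(n_qed, n_unique, "QEDrequest"),
                lead_request=lead_request,
                novelty=novelty,
            )
        )

    def avg(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    has_model = activity_model is not None
    return GenerationReport(
        n_sample=reps[0].n_sample,
        repetitions=len(reps),
        validity=avg([r.validity for r in reps]),
        uniqueness=avg([r.uniqueness for r in reps]),
        qed_request=avg([r.qed_request for r in reps]),
        lead_request=avg([r.lead_request for r in reps]) if has_model else None,
        novelty=avg([r.novelty for r in reps]) if has_model else None,
        num_qed_request=avg([r.n_qed for r in reps]),
        num_lead=avg([r.n_lead for r in reps]) if has_model else None,
        num_novel_lead=avg([r.n_novel_lead for r in reps]) if has_model else None,
        per_repetition=reps,
    )


def _mol(x) -> Chem.Mol:
    smiles = x.canonical_smiles if isinstance(x, MoleculeRecord) else x
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    return mol


def _morgan2048(mol: Chem.Mol):
    return AllChem.GetMorganFingerprintAsBitVect(mol, radius=2, nBits=2048)


def tanimoto_similarity(a, b) -> float:
    """Tanimoto similarity on 2048-bit Morgan (radius 2) fingerprints."""
    return float(DataStructs.TanimotoSimilarity(_morgan2048(_mol(a)), _morgan2048(_mol(b))))


def embed_chemical_space(records, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding of Morgan-2048 fingerprints; one (x, y) row per record."""
    from sklearn.manifold import TSNE

    records = list(records)
    if len(records) < 5:
        raise ValueError("need at least 5 records to embed")
    if len(records) <= perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {len(records)} records; "
            "pass a smaller perplexity"
        )
    X = np.array([np.asarray(_morgan2048(_mol(r)), dtype=float) for r in records])
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(X)


_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        path = f"{RDConfig.RDContribDir}/SA_Score"
        if path not in sys.path:
            sys.path.append(path)
        import sascorer

        _sascorer = sascorer
    return _sascorer


def sa_score(record) -> float:
    """Synthetic-accessibility score in [1, 10] (fragment contributions plus a
    complexity penalty); lower means easier to synthesise."""
    return float(_get_sascorer().calculateScore(_mol(record)))
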