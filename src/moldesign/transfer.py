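"""Partitioned (recurrent) transfer learning onto activity target domains.

PTL finetunes a pretrained generator through an ordered sequence of target
sub-domains (high-activity branch: C then A; low-activity branch: D then B of
the QED x IC50 partition), each stage stopping when the mean epoch loss has
plateaued and restoring the minimum-loss parameters. PRTL wraps PTL in a
recurrence: sample, keep only the novel qualifying molecules (valid, unique,
drug-like, predicted active, absent from the training and finetune sets),
fold them back into the target domain, carry the parameters forward, and
repeat until no molecule qualifies or a recurrence cap is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from rdkit import Chem

from .corpus import MoleculeRecord, compute_qed
from .generator import ConditionalSmilesVAE

logger = logging.getLogger(__name__)

__all__ = ["TransferConfig", "PrtlResult", "ptl_finetune", "qualify_generated", "prtl_run"]


@dataclass
class TransferConfig:
    """Knobs of the transfer stage.

    impatience_n: epochs of non-decreasing mean loss before a stage stops.
    max_recurrences: hard cap on PRTL cycles.
    samples_per_repetition x repetitions: molecules drawn per cycle.
    sample_condition: condition value handed to the generator when sampling
    (a requested drug-likeness; defaults just above the QED threshold).
    """

    impatience_n: int = 5
    max_recurrences: int = 50
    samples_per_repetition: int = 64
    repetitions: int = 10
    qed_threshold: float = 0.6
    domain_update_mode: str = "append"  # or "replace"
    stage_epoch_cap: int = 100
    sample_condition: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.max_recurrences < 1 or self.repetitions < 1:
            raise ValueError("max_recurrences and repetitions must be >= 1")
        if self.domain_update_mode not in ("append", "replace"):
            raise ValueError("domain_update_mode must be 'append' or 'replace'")


@dataclass
class PrtlResult:
    """Accumulated outcome of a PRTL run."""

    novel_molecules: list[MoleculeRecord]
    recurrence_count: int
    reports: list = field(default_factory=list)  # per-recurrence GenerationReport
    model: ConditionalSmilesVAE | None = None


def _domain_smiles(domain) -> list[str]:
    return [
        r.canonical_smiles if isinstance(r, MoleculeRecord) else str(r) for r in domain
    ]


def ptl_finetune(
    model: ConditionalSmilesVAE,
    stage_domains: Sequence[Sequence],
    config: TransferConfig | None = None,
    inplace: bool = False,
) -> ConditionalSmilesVAE:
    """Finetune sequentially through the given stage domains.

    Each stage runs until its mean epoch loss stops decreasing for
    ``impatience_n`` consecutive epochs (or the epoch cap), then restores the
    minimum-mean-loss parameters; the optimizer is re-initialised per stage.
    A single-stage call is a plain finetune.
    """
    config = config or TransferConfig()
    if not stage_domains or any(len(d) == 0 for d in stage_domains):
        raise ValueError("every stage domain must be nonempty")
    out = model if inplace else model.clone_fitted()
    for domain in stage_domains:
        smiles = _domain_smiles(domain)
        missing = [
            s
            for s in smiles
            if any(t not in out.alphabet_.index_of for t in _tokens(s))
        ]
        if missing:
            bad = sorted(
                {
                    t
                    for s in missing
                    for t in _tokens(s)
                    if t not in out.alphabet_.index_of
                }
            )
            raise KeyError(f"stage domain tokens outside model alphabet: {bad}")
        out.finetune(
            smiles,
            epochs=config.stage_epoch_cap,
            plateau_patience=config.impatience_n,
        )
    return out


def _tokens(smiles: str):
    from .corpus import smiles_tokens

    return smiles_tokens(smiles)


def qualify_generated(
    raw_samples: Sequence[str],
    training_set: set[str],
    finetune_set: set[str],
    qed_threshold: float = 0.6,
    activity_model=None,
) -> list[MoleculeRecord]:
    """Keep the novel qualifying molecules from a batch of raw samples.

    Criteria, in order: parses to a valid molecule; unique by canonical
    SMILES; QED above the threshold; predicted active (skipped with a warning
    when no activity model is supplied); absent from both reference sets.
    Output preserves input order.
    """
    seen: set[str] = set()
    stage: list[MoleculeRecord] = []
    for raw in raw_samples:
        mol = Chem.MolFromSmiles(raw) if raw else None
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        qed = compute_qed(canonical)
        if qed <= qed_threshold:
            continue
        stage.append(MoleculeRecord(raw, canonical, qed=qed))
    if activity_model is None:
        logger.warning("no activity model supplied; skipping the activity criterion")
    elif stage:
        preds = activity_model.predict([r.canonical_smiles for r in stage])
        stage = [r for r, p in zip(stage, preds) if p]
        for r in stage:
            r.active_label = 1
    return [
        r
        for r in stage
        if r.canonical_smiles not in training_set
        and r.canonical_smiles not in finetune_set
    ]


def prtl_run(
    model: ConditionalSmilesVAE,
    initial_stage_domains: Sequence[Sequence],
    config: TransferConfig | None = None,
    activity_model=None,
    training_set: set[str] | None = None,
    sampler: Callable | None = None,
    finetune: bool = True,
) -> PrtlResult:
    """Run recurrent transfer learning until no novel molecule qualifies
    (the target domain does not update) or the recurrence cap is hit.

    ``sampler(model, n, seed) -> list[str]`` may override the generator's own
    sampling (used by contract tests); ``finetune=False`` skips the PTL stage
    inside each recurrence while keeping the accumulation/stop logic.
    """
    from .genmetrics import evaluate_generation

    config = config or TransferConfig()
    stage_domains = [list(d) for d in initial_stage_domains]
    training_set = set(training_set or ())
    finetune_set = {s for d in stage_domains for s in _domain_smiles(d)}
    novel: list[MoleculeRecord] = []
    novel_keys: set[str] = set()
    reports = []
    current = model.clone_fitted() if finetune else model
    recurrence = 0
    while recurrence < config.max_recurrences:
        recurrence += 1
        if finetune:
            current = ptl_finetune(current, stage_domains, config, inplace=True)
        seed = config.seed + 1000 * recurrence
        per_rep: list[list[str]] = []
        for rep in range(config.repetitions):
            if sampler is not None:
                batch = sampler(current, config.samples_per_repetition, seed + rep)
            else:
                batch = current.sample(
                    config.samples_per_repetition,
                    condition=config.sample_condition,
                    seed=seed + rep,
                )
            per_rep.append(batch)
        reports.append(
            evaluate_generation(
                per_rep,
                training_set,
                finetune_set,
                qed_threshold=config.qed_threshold,
                activity_model=activity_model,
            )
        )
        flat = [s for rep in per_rep for s in rep]
        qualified = qualify_generated(
            flat,
            training_set | novel_keys,
            finetune_set,
            qed_threshold=config.qed_threshold,
            activity_model=activity_model,
        )
        if not qualified:
            break
        novel.extend(qualified)
        novel_keys.update(r.canonical_smiles for r in qualified)
        new_smiles = [r.canonical_smiles for r in qualified]
        if config.domain_update_mode == "append":
            stage_domains[-1] = stage_domains[-1] + new_smiles
        else:
            stage_domains[-1] = new_smiles
        finetune_set.update(new_smiles)
    return PrtlResult(novel, recurrence, reports, current)
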