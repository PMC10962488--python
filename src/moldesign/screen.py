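"""Candidate screening: novelty filtering, ranking, SA-based selection.

Novelty is judged against user-supplied local reference sets of canonical
SMILES (e.g. the training corpus plus exported known-compound lists) -- a
surrogate for a commercial registry lookup, not an equivalent. Candidates are
ranked by predicted activity (descending pIC50) or by an externally computed
docking score (ascending; docking itself is never run here), and one
candidate is picked per rank window (Top 1-10, Top 11-20) by minimum
synthetic-accessibility score.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .corpus import MoleculeRecord, canonicalize
from .genmetrics import sa_score

logger = logging.getLogger(__name__)

__all__ = ["novelty_filter", "rank_candidates", "pick_by_sa"]


def _canonical(candidate) -> str:
    if isinstance(candidate, MoleculeRecord):
        return candidate.canonical_smiles
    c = canonicalize(str(candidate))
    if c is None:
        raise ValueError(f"invalid candidate SMILES: {candidate!r}")
    return c


def novelty_filter(
    candidates: Sequence, reference_sets: Sequence[set[str]]
) -> tuple[list, list]:
    """Split candidates into (novel, known), preserving order.

    A candidate is known iff its canonical SMILES appears in any reference set
    (reference sets must themselves hold canonical SMILES).
    """
    novel, known = [], []
    for cand in candidates:
        c = _canonical(cand)
        (known if any(c in ref for ref in reference_sets) else novel).append(cand)
    return novel, known


def rank_candidates(
    candidates: Sequence, mode: str, scores: Mapping[str, float]
) -> list:
    """Order candidates by score: ``activity_desc`` (higher predicted pIC50
    first) or ``docking_asc`` (more negative docking score first).

    Ties break by canonical-SMILES lexicographic order, so the ranking is
    deterministic. ``scores`` maps canonical SMILES to the score.
    """
    if mode not in ("activity_desc", "docking_asc"):
        raise ValueError(f"unknown ranking mode: {mode}")
    keyed = []
    for cand in candidates:
        c = _canonical(cand)
        if c not in scores:
            raise KeyError(f"no score for candidate {c!r}")
        keyed.append((cand, c, float(scores[c])))
    sign = -1.0 if mode == "activity_desc" else 1.0
    keyed.sort(key=lambda t: (sign * t[2], t[1]))
    return [cand for cand, _, _ in keyed]


def pick_by_sa(
    ranked: Sequence, windows: Sequence[tuple[int, int]] = ((1, 10), (11, 20))
) -> list:
    """From each 1-based rank window, pick the candidate with the lowest
    synthetic-accessibility score (ties by canonical SMILES order).

    Windows extending past the list are truncated with a warning; a window
    left empty is skipped with a warning.
    """
    ranked = list(ranked)
    picks = []
    for lo, hi in windows:
        if hi > len(ranked):
            logger.warning("window [%d, %d] truncated to %d candidates", lo, hi, len(ranked))
            hi = len(ranked)
        if lo > hi:
            logger.warning("window [%d, %d] empty after truncation; skipped", lo, hi)
            continue
        window = ranked[lo - 1 : hi]
        picks.append(min(window, key=lambda c: (sa_score(_canonical(c)), _canonical(c))))
    return picks
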