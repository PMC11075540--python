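"""Terminal inverted repeat (TIR) detection and structural classification.

DNA transposons carry a short motif at the 5' end whose reverse complement
closes the 3' end.  The curation rules use TIR presence as a boolean gate:
class II (DNA/TIR) candidates must carry one, and short TIR-bearing
consensus sequences without a transposase ORF are MITEs.  The search here
anchors candidate repeat pairs inside configurable windows at both termini
and extends each anchor pair, keeping the longest pair within the mismatch
budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from tecurate.seqio import SequenceRecord, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_TIR_LENGTH = 8
MITE_MIN_BP = 50
MITE_MAX_BP = 1_000
DNA_TIR_MIN_BP = 1_000
DNA_TIR_MAX_BP = 17_000

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class TIRFeature:
    """A detected terminal inverted repeat pair on a consensus.

    Coordinates are 0-based half-open on the consensus; ``length`` is the
    repeat arm length and ``mismatches`` the number of non-complementary
    positions tolerated in the pairing.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.left_end > self.right_start:
            raise ValueError("TIR arms overlap")
        if self.left_end - self.left_start != self.length:
            raise ValueError("left arm length inconsistent")
        if self.right_end - self.right_start != self.length:
            raise ValueError("right arm length inconsistent")


def detect_tirs(
    record: SequenceRecord,
    min_len: int = DEFAULT_MIN_TIR_LENGTH,
    max_len: int = 1_000,
    max_mismatch_frac: float = 0.1,
    edge_window: int = 50,
) -> Optional[TIRFeature]:
    """Longest terminal inverted repeat within the edge windows, or None.

    The left arm must start within ``edge_window`` nt of the 5' terminus and
    the right arm must end within ``edge_window`` nt of the 3' terminus.
    A pair of arms of length L qualifies when the left arm equals the
    reverse complement of the right arm with at most
    ``floor(max_mismatch_frac * L)`` mismatches.  Ties on length are broken
    by fewer mismatches, then by outermost placement.
    """
    seq = record.seq
    n = len(seq)
    if n < 2 * min_len:
        logger.info("%s shorter than 2*min_len, no TIR search", record.id)
        return None

    best: Optional[TIRFeature] = None
    for left_start in range(min(edge_window, n)):
        for right_end in range(n, max(n - edge_window, left_start + 2 * min_len - 1), -1):
            # extend the anchor pair inward
            limit = min(max_len, (right_end - left_start) // 2)
            mism = 0
            best_l = 0
            best_l_mism = 0
            mism_budget = int(max_mismatch_frac * limit)
            for i in range(limit):
                a = seq[left_start + i]
                b = seq[right_end - 1 - i]
                if _PAIR.get(a) != b or a not in _PAIR:
                    mism += 1
                    if mism > mism_budget:
                        break  # no longer arm can come back under budget
                length = i + 1
                if length >= min_len and mism <= int(max_mismatch_frac * length):
                    best_l = length
                    best_l_mism = mism
            if best_l >= min_len:
                feat = TIRFeature(
                    left_start=left_start,
                    left_end=left_start + best_l,
                    right_start=right_end - best_l,
                    right_end=right_end,
                    length=best_l,
                    mismatches=best_l_mism,
                )
                if best is None or (
                    (feat.length, -feat.mismatches, -feat.left_start, feat.right_end)
                    > (best.length, -best.mismatches, -best.left_start, best.right_end)
                ):
                    best = feat
    return best


def classify_structural(
    record: SequenceRecord,
    tir: Optional[TIRFeature],
    has_transposase: bool,
) -> str:
    """Apply the structural size rules that gate class II calls.

    Returns "MITE" for TIR-bearing 50 bp - 1 kb records lacking a
    transposase domain, "DNA_TIR_CANDIDATE" for TIR-bearing 1 - 17 kb
    records with a transposase, and "NONE" otherwise.  Both size windows
    are read as inclusive: a 1,000-bp record with a transposase falls in
    the DNA/TIR branch and without one in the MITE branch.
    """
    if tir is None:
        return "NONE"
    n = len(record)
    if not has_transposase and MITE_MIN_BP <= n <= MITE_MAX_BP:
        return "MITE"
    if has_transposase and DNA_TIR_MIN_BP <= n <= DNA_TIR_MAX_BP:
        return "DNA_TIR_CANDIDATE"
    return "NONE"
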