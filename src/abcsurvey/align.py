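"""Global pairwise protein alignment used across the survey.

One scoring scheme everywhere (BLOSUM62, gap open 10, extend 0.5) so that
homology calls, subfamily distances and codon alignments are mutually
consistent. Thin wrapper over Biopython's PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = make_aligner()


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """One global alignment: gapped rows plus summary scores."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float  # identical columns / aligned (non-double-gap) columns

    @property
    def p_distance(self) -> float:
        return 1.0 - self.identity_pct / 100.0


def _sanitize(seq: str) -> str:
    # BLOSUM62 lacks 'U'/'O'; X is present in the matrix. Strip stops.
    return seq.replace("*", "").replace("U", "X").replace("O", "X")


def align_pair(seq_a: str, seq_b: str) -> PairwiseAlignmentResult:
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _ALIGNER.align(_sanitize(seq_a), _sanitize(seq_b))[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    columns = len(row_a)
    identity = 100.0 * identical / columns if columns else 0.0
    return PairwiseAlignmentResult(row_a, row_b, float(alignment.score), identity)


def percent_identity(seq_a: str, seq_b: str) -> float:
    return align_pair(seq_a, seq_b).identity_pct
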