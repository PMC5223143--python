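"""Position-weight-matrix scanning and motif enrichment/strength statistics.

Motif strength of a sequence is defined as the best log2-odds score of the
PWM over all offsets on both strands.  Occurrence enrichment between a
foreground and background sequence set uses a hypergeometric tail on
best-score threshold calls; strength comparison across sets uses two-sided
Wilcoxon rank-sum tests (scores are bounded and non-normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

PROB_FLOOR = 1e-3
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A 4 x L base-probability matrix (rows A, C, G, T) with background.

    Columns must sum to 1 (tolerance 1e-6).  Probabilities are floored at
    1e-3 before taking log-odds, so a zero count never produces an
    infinitely bad score.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds matrix; the 5th row (N) contributes zero."""
        probs = np.clip(self.matrix, PROB_FLOOR, None)
        bg = np.clip(self.background, PROB_FLOOR, None)
        lo = np.log2(probs / bg[:, None])
        return np.vstack([lo, np.zeros((1, self.length))])

    def max_score(self) -> float:
        return float(self.log_odds()[:4].max(axis=0).sum())

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, background=None
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=0, keepdims=True), background)


@dataclass(frozen=True)
class MotifHit:
    """Best PWM match in one sequence."""

    region_id: str
    position: int
    strand: str
    score: float


def read_pfm(path: str) -> list[PWM]:
    """Read JASPAR-style PFM motifs (counts or probabilities, one or more).

    Uses Biopython's JASPAR parser; counts are normalized per column.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        out.append(PWM.from_counts(m.matrix_id or m.name, counts))
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Sequences keyed by record id, upper-cased."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_scores(lo5: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score of the motif at every offset of an encoded sequence."""
    L = lo5.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_best(pwm: PWM, sequence: str, region_id: str = "") -> MotifHit:
    """Best log2-odds match over all offsets and both strands.

    ``N`` bases contribute zero (background odds).  Ties are broken toward
    the smallest position, forward strand preferred.  Positions refer to
    the forward sequence; a reverse-strand hit at position ``i`` means the
    motif matches the reverse complement of ``sequence[i:i+L]``.
    """
    seq = sequence.upper()
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than motif")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    codes = np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=len(seq))

    lo5 = pwm.log_odds()
    # reverse-strand scores at forward offsets: score with the
    # reverse-complemented PWM (complement rows A<->T, C<->G; reverse cols)
    lo5_rc = np.vstack([lo5[[3, 2, 1, 0], ::-1], lo5[4:5, ::-1]])

    fwd = _window_scores(lo5, codes)
    rev = _window_scores(lo5_rc, codes)
    # interleave so argmax prefers smaller positions, forward before reverse
    both = np.stack([fwd, rev], axis=1).ravel()
    best = int(np.argmax(np.round(both, 12)))
    pos, strand_idx = divmod(best, 2)
    return MotifHit(
        region_id=region_id,
        position=pos,
        strand="+" if strand_idx == 0 else "-",
        score=float(both[best]),
    )


def occurrence_enrichment(
    fg: Sequence[str],
    bg: Sequence[str],
    pwm: PWM,
    score_min: float,
) -> tuple[float, float, float]:
    """Fraction of motif-containing sequences in fg vs bg plus a
    hypergeometric enrichment p-value.

    A sequence contains the motif when its best score is >= ``score_min``.
    The p-value is the upper hypergeometric tail of foreground hits given
    the pooled hit total.
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both sequence sets must be non-empty")
    if not np.isfinite(score_min):
        raise ValueError("score_min must be finite")
    fg_hits = sum(scan_best(pwm, s).score >= score_min for s in fg)
    bg_hits = sum(scan_best(pwm, s).score >= score_min for s in bg)
    N = len(fg) + len(bg)
    K = fg_hits + bg_hits
    p = float(stats.hypergeom.sf(fg_hits - 1, N, K, len(fg)))
    return fg_hits / len(fg), bg_hits / len(bg), p


@dataclass
class StrengthComparison:
    """Best-score distributions per set and pairwise rank-sum p-values."""

    scores: dict[str, np.ndarray]
    summary: dict[str, dict[str, float]]
    pairwise_p: dict[tuple[str, str], float]


def strength_comparison(
    sets: Mapping[str, Sequence[str]], pwm: PWM
) -> StrengthComparison:
    """Compare motif strength (best log2-odds score) across sequence sets.

    Emits per-set quartiles and a two-sided Wilcoxon rank-sum p-value for
    every pair of sets.  Each set must hold at least 2 sequences.
    """
    scores: dict[str, np.ndarray] = {}
    for name, seqs in sets.items():
        if len(seqs) < 2:
            raise ValueError(f"set {name!r} must have >= 2 sequences")
        scores[name] = np.array([scan_best(pwm, s).score for s in seqs])
    summary = {}
    for name, v in scores.items():
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        summary[name] = {
            "n": float(v.size),
            "q1": float(q1),
            "median": float(q2),
            "q3": float(q3),
        }
    pairwise = {}
    for a, b in combinations(scores, 2):
        pairwise[(a, b)] = float(stats.ranksums(scores[a], scores[b]).pvalue)
    return StrengthComparison(scores=scores, summary=summary, pairwise_p=pairwise)


def example_pwm(motif_id: str = "SYN1", dominant: float = 0.95) -> PWM:
    """A synthetic 10-bp informative PWM used by the simulator and examples.

    Each column puts ``dominant`` probability on the consensus base and
    splits the remainder uniformly; the consensus is TGACCAATGG.
    """
    consensus = "TGACCAATGG"
    L = len(consensus)
    rest = (1.0 - dominant) / 3.0
    matrix = np.full((4, L), rest)
    for j, b in enumerate(consensus):
        matrix[_CODE[b], j] = dominant
    return PWM(motif_id, matrix)
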