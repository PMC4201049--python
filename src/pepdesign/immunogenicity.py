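"""Sliding-window enumeration and immunogenicity (Ig) scoring.

Every contiguous window of the chosen peptide length L is a candidate
immunogen. Each window receives an Ig-score, the product of three factors
mapped to a 0–10-ish band:

    ig = 10 * hydrophilicity * turn_propensity * tail_bonus

* hydrophilicity in [0, 1]: how hydrophilic the window is on the
  Kyte-Doolittle scale — (4.5 - meanKD) / 9, clamped. Hydrophilic peptides
  favor surface exposure in the native protein and solubility as synthetic
  peptides.
* turn_propensity in [0, 1]: the window's mean Chou-Fasman beta-turn
  parameter, rescaled over the attainable range — (meanPt - 0.47) / 1.09,
  clamped. Turn-rich stretches tend to be disordered loops where linear
  epitopes work.
* tail_bonus in {1, B}: windows lying entirely within T residues of either
  terminus get a multiplier B, reflecting the accessibility and disorder of
  protein tails.

A score of ``high_ig_threshold`` (default 7) or more is flagged as high
immunogenicity. Windows are ranked by competition ranking (ties share the
best rank).
"""

from __future__ import annotations

from dataclasses import dataclass

from .propensity import CF_TURN, KD_MAX, KD_MIN, KYTE_DOOLITTLE, PT_MAX, PT_MIN
from .sequence_io import ParameterError, ProteinRecord


@dataclass(frozen=True)
class DesignParams:
    """Run parameters for a design.

    peptide_length (L) and epitope_length (E) are what a user chooses per
    run; tail_length (T), tail_bonus_factor (B) and high_ig_threshold are
    frozen package defaults.
    """

    peptide_length: int = 18
    epitope_length: int = 7
    tail_length: int = 60
    tail_bonus_factor: float = 2.0
    high_ig_threshold: float = 7.0

    def __post_init__(self):
        if self.epitope_length < 1:
            raise ParameterError(
                f"epitope_length must be >= 1, got {self.epitope_length}")
        if self.peptide_length < self.epitope_length:
            raise ParameterError(
                f"peptide_length ({self.peptide_length}) must be >= "
                f"epitope_length ({self.epitope_length})")
        if self.tail_length < 0:
            raise ParameterError(
                f"tail_length must be >= 0, got {self.tail_length}")
        if self.tail_bonus_factor < 1:
            raise ParameterError(
                f"tail_bonus_factor must be >= 1, got {self.tail_bonus_factor}")


@dataclass
class PeptideWindow:
    """One candidate immunogen window, 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str
    hydrophilicity_component: float = 0.0
    turn_component: float = 0.0
    tail_bonus: float = 1.0
    ig_score: float = 0.0
    rank: int = 0


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


def in_tail(start: int, length: int, protein_length: int, tail_length: int) -> bool:
    """True iff the whole window lies within ``tail_length`` residues of a
    terminus (mere overlap with the tail region does not count)."""
    end = start + length - 1
    return end <= tail_length or start >= protein_length - tail_length + 1


def enumerate_windows(protein: ProteinRecord, peptide_length: int) -> list[PeptideWindow]:
    """All n - L + 1 candidate windows of length L, in position order."""
    n = len(protein.sequence)
    if peptide_length > n:
        raise ParameterError(
            f"peptide_length {peptide_length} exceeds protein length {n}")
    if peptide_length < 1:
        raise ParameterError(f"peptide_length must be >= 1, got {peptide_length}")
    return [
        PeptideWindow(start=s, end=s + peptide_length - 1,
                      sequence=protein.sequence[s - 1:s + peptide_length - 1])
        for s in range(1, n - peptide_length + 2)
    ]


def ig_score(sequence: str, start: int, protein_length: int,
             params: DesignParams) -> PeptideWindow:
    """Score one window; returns the window with all score components set."""
    L = len(sequence)
    mean_kd = sum(KYTE_DOOLITTLE[a] for a in sequence) / L
    mean_pt = sum(CF_TURN[a] for a in sequence) / L
    hydro = _clamp01((KD_MAX - mean_kd) / (KD_MAX - KD_MIN))
    turn = _clamp01((mean_pt - PT_MIN) / (PT_MAX - PT_MIN))
    bonus = (params.tail_bonus_factor
             if in_tail(start, L, protein_length, params.tail_length) else 1.0)
    return PeptideWindow(
        start=start, end=start + L - 1, sequence=sequence,
        hydrophilicity_component=hydro, turn_component=turn,
        tail_bonus=bonus, ig_score=10.0 * hydro * turn * bonus,
    )


def score_windows(protein: ProteinRecord, params: DesignParams) -> list[PeptideWindow]:
    """Enumerate, score, and rank every window of the protein."""
    windows = [
        ig_score(w.sequence, w.start, len(protein.sequence), params)
        for w in enumerate_windows(protein, params.peptide_length)
    ]
    return rank_windows(windows)


def rank_windows(windows: list[PeptideWindow]) -> list[PeptideWindow]:
    """Assign competition ranks on descending ig_score.

    Equal scores share the smallest rank; the next distinct score gets
    rank = (number of strictly better windows) + 1. The returned list keeps
    the input (position) order; rank is a field.
    """
    if not windows:
        raise ParameterError("cannot rank an empty window list")
    scores = sorted((w.ig_score for w in windows), reverse=True)
    # rank of score s = index of its first occurrence in the sorted list + 1
    first_index: dict[float, int] = {}
    for i, s in enumerate(scores):
        first_index.setdefault(s, i + 1)
    for w in windows:
        w.rank = first_index[w.ig_score]
    return windows


def top_windows(windows: list[PeptideWindow], n: int) -> list[PeptideWindow]:
    """The n best windows, rank ascending, ties by start ascending."""
    return sorted(windows, key=lambda w: (w.rank, w.start))[:n]
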