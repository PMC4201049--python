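"""k-mer epitope index: proteome uniqueness and cross-species conservation.

An antibody raised against a peptide recognises short contiguous stretches
of it — modelled here as the peptide's E-mers (epitope length E, default 7).
Two questions follow, both answered by exact substring matching of E-mers:

* uniqueness (specificity predictor): what fraction of a window's E-mers
  occur in NO other protein of the background proteome? 1.0 means no
  off-target protein shares any epitope-length stretch with the peptide.
* conservation (cross-reactivity predictor): what fraction of the window's
  E-mers occur anywhere in a species' ortholog sequence(s)? 1.0 means an
  antibody seeing any epitope of the peptide could in principle find it in
  that species too.

E-mers containing nonstandard letters (B, Z, X, U, O) are never indexed;
in uniqueness they count as having zero off-target hits but are flagged.
Matching is case-insensitive and exact — no mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sequence_io import STANDARD_AA, ParameterError, Proteome

logger = logging.getLogger("pepdesign")


@dataclass
class EpitopeIndex:
    """Map from E-mer to the set of protein ids containing it."""

    k: int
    postings: dict[str, set[str]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> set[str]:
        return self.postings.get(kmer.upper(), set())


@dataclass
class UniquenessResult:
    start: int
    end: int
    uniqueness_score: float
    off_target_ids: set[str]
    per_epitope: dict[str, int]
    nonstandard_epitopes: list[str] = field(default_factory=list)


@dataclass
class ConservationResult:
    start: int
    end: int
    per_species: dict[str, float]
    overall: float


def _clean_kmers(sequence: str, k: int) -> list[tuple[str, bool]]:
    """All k-mers of a sequence with a standard-letters-only flag."""
    seq = sequence.upper()
    return [
        (kmer, all(c in STANDARD_AA for c in kmer))
        for kmer in (seq[i:i + k] for i in range(len(seq) - k + 1))
    ]


def build_index(proteome: Proteome, epitope_length: int) -> EpitopeIndex:
    """Index every clean E-mer of every record in the proteome."""
    if epitope_length < 1:
        raise ParameterError(f"epitope_length must be >= 1, got {epitope_length}")
    if len(proteome) == 0:
        raise ParameterError("cannot index an empty proteome")
    index = EpitopeIndex(k=epitope_length)
    for record in proteome:
        for kmer, clean in _clean_kmers(record.sequence, epitope_length):
            if clean:
                index.postings.setdefault(kmer, set()).add(record.id)
    return index


def default_target_ids(target_id: str, proteome: Proteome | None) -> set[str]:
    """The target id plus any proteome ids sharing its accession root.

    UniProt isoforms use "P12345-2"-style ids; hits to an isoform of the
    target are self-hits, not off-targets.
    """
    root = target_id.split("-")[0]
    ids = {target_id}
    if proteome is not None:
        ids.update(r.id for r in proteome if r.id.split("-")[0] == root)
    return ids


def uniqueness(window_sequence: str, start: int, index: EpitopeIndex,
               target_ids: set[str]) -> UniquenessResult:
    """Fraction of the window's E-mers with zero off-target proteome hits."""
    k = index.k
    if len(window_sequence) < k:
        raise ParameterError(
            f"window length {len(window_sequence)} is shorter than "
            f"epitope length {k}")
    kmers = _clean_kmers(window_sequence, k)
    per_epitope: dict[str, int] = {}
    off_targets: set[str] = set()
    nonstandard: list[str] = []
    n_unique = 0
    for kmer, clean in kmers:
        if not clean:
            per_epitope[kmer] = 0
            nonstandard.append(kmer)
            n_unique += 1
            continue
        hits = index.lookup(kmer) - target_ids
        per_epitope[kmer] = len(hits)
        off_targets |= hits
        if not hits:
            n_unique += 1
    return UniquenessResult(
        start=start, end=start + len(window_sequence) - 1,
        uniqueness_score=n_unique / len(kmers),
        off_target_ids=off_targets, per_epitope=per_epitope,
        nonstandard_epitopes=nonstandard,
    )


def conservation(window_sequence: str, start: int,
                 ortholog_sets: dict[str, Proteome],
                 epitope_length: int) -> ConservationResult:
    """Per-species fraction of the window's E-mers present in the orthologs.

    Presence is anywhere in the species' ortholog sequences, not
    position-restricted. Species with empty ortholog sets score 0 with a
    logged warning.
    """
    if not ortholog_sets:
        raise ParameterError("at least one species of orthologs is required")
    return conservation_from_indices(
        window_sequence, start,
        build_species_indices(ortholog_sets, epitope_length), epitope_length)


def build_species_indices(ortholog_sets: dict[str, Proteome],
                          epitope_length: int) -> dict[str, "EpitopeIndex | None"]:
    """One E-mer index per species; None for species with no sequences."""
    indices: dict[str, EpitopeIndex | None] = {}
    for species, proteome in ortholog_sets.items():
        if len(proteome) == 0:
            logger.warning("species %r has no ortholog sequences; "
                           "conservation will be 0", species)
            indices[species] = None
        else:
            indices[species] = build_index(proteome, epitope_length)
    return indices


def conservation_from_indices(window_sequence: str, start: int,
                              species_indices: dict[str, "EpitopeIndex | None"],
                              epitope_length: int) -> ConservationResult:
    """Conservation against prebuilt per-species indices (shared across
    windows of one run)."""
    k = epitope_length
    if len(window_sequence) < k:
        raise ParameterError(
            f"window length {len(window_sequence)} is shorter than "
            f"epitope length {k}")
    kmers = _clean_kmers(window_sequence, k)
    per_species: dict[str, float] = {}
    for species, index in species_indices.items():
        if index is None:
            per_species[species] = 0.0
            continue
        n_hit = sum(1 for kmer, clean in kmers if clean and index.lookup(kmer))
        per_species[species] = n_hit / len(kmers)
    overall = sum(per_species.values()) / len(per_species)
    return ConservationResult(
        start=start, end=start + len(window_sequence) - 1,
        per_species=per_species, overall=overall,
    )


def conservation_band(score: float) -> str:
    """Map a fractional score onto prose bands: conserved / partial / none."""
    if score >= 0.999:
        return "conserved"
    if score > 0.0:
        return "partial"
    return "none"


def uniqueness_band(score: float) -> str:
    """Map a fractional score onto prose bands: unique / partial / none."""
    if score >= 0.999:
        return "unique"
    if score > 0.0:
        return "partial"
    return "none"
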