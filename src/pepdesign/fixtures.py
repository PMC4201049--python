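"""Deterministic synthetic data: random proteins, planted epitopes, planted
features, toy proteomes and ortholog sets.

Everything is generated from an integer seed through Python's ``random``
module (the Mersenne Twister, whose integer-seeded output is stable across
platforms and CPython versions), so fixtures are byte-identical wherever
they are regenerated. Per-protein streams derive from
``seed * 1_000_003 + index`` so individual records are reproducible in
isolation.

The generator emulates the situations the design engine must handle —
shared epitopes between unrelated proteins (uniqueness), point-substituted
orthologs (conservation), annotated features at known positions (overlap
flags) — not realistic protein evolution: compositions are i.i.d. and there
are no indels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .sequence_io import (Proteome, ProteinRecord,
                          SequenceFeature, write_fasta)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class FixtureSpecError(ValueError):
    """Inconsistent fixture specification (e.g. planted k-mer out of bounds)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic toy proteome.

    planted_kmers: (kmer, protein_index, 1-based position) triples written
    over the sampled sequence, so specific epitope sharing can be arranged.
    planted_features: (protein_index, SequenceFeature) pairs.
    """

    seed: int
    n_proteins: int = 10
    length_range: tuple[int, int] = (80, 300)
    composition: dict[str, float] = field(default_factory=dict)
    planted_kmers: tuple[tuple[str, int, int], ...] = ()
    planted_features: tuple[tuple[int, SequenceFeature], ...] = ()


def _rng_for(spec_seed: int, index: int) -> random.Random:
    return random.Random(spec_seed * 1_000_003 + index)


def make_protein(spec: FixtureSpec, index: int) -> ProteinRecord:
    """The index-th protein of the spec, deterministic in (seed, index)."""
    if not (0 <= index < spec.n_proteins):
        raise FixtureSpecError(
            f"protein index {index} outside [0, {spec.n_proteins})")
    rng = _rng_for(spec.seed, index)
    lo, hi = spec.length_range
    length = rng.randint(lo, hi)
    if spec.composition:
        letters = sorted(spec.composition)
        weights = [spec.composition[a] for a in letters]
    else:
        letters, weights = list(AA_ALPHABET), None
    seq = rng.choices(letters, weights=weights, k=length)
    for kmer, p_idx, pos in spec.planted_kmers:
        if p_idx != index:
            continue
        if pos < 1 or pos + len(kmer) - 1 > length:
            raise FixtureSpecError(
                f"planted k-mer {kmer!r} at position {pos} exceeds the "
                f"{length}-aa sequence of protein {index}")
        seq[pos - 1:pos - 1 + len(kmer)] = list(kmer.upper())
    features = [f for i, f in spec.planted_features if i == index]
    return ProteinRecord(id=f"SYN{index:06d}", sequence="".join(seq),
                         description=f"synthetic protein seed={spec.seed}",
                         features=list(features))


def make_proteome(spec: FixtureSpec, species_label: str = "synthetic") -> Proteome:
    """All proteins of the spec as one proteome."""
    return Proteome(records=[make_protein(spec, i) for i in range(spec.n_proteins)],
                    species_label=species_label)


def make_ortholog(protein: ProteinRecord, substitution_rate: float,
                  seed: int) -> ProteinRecord:
    """A point-substituted copy of a protein.

    Each position is independently replaced, with the given probability, by
    a seeded-random standard residue different from the original. Rate 0
    returns an identical sequence; rate 1 changes every position.
    """
    if not (0.0 <= substitution_rate <= 1.0):
        raise FixtureSpecError(
            f"substitution_rate must be in [0, 1], got {substitution_rate}")
    rng = random.Random(seed)
    out = []
    for a in protein.sequence:
        if rng.random() < substitution_rate:
            choices = [c for c in AA_ALPHABET if c != a]
            out.append(rng.choice(choices))
        else:
            out.append(a)
    return ProteinRecord(id=f"{protein.id}_ortho_s{seed}",
                         sequence="".join(out),
                         description=f"ortholog of {protein.id} "
                                     f"rate={substitution_rate} seed={seed}")


def write_fixture_fasta(spec: FixtureSpec, path: Path) -> Path:
    """Write the spec's proteome as FASTA (exercises the real writer)."""
    return write_fasta(make_proteome(spec).records, path)


def write_feature_table(features: list[SequenceFeature], path: Path) -> Path:
    """Write features as the tab-separated table the reader consumes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# kind\tstart\tend\tnote\n")
        for f in features:
            fh.write(f"{f.kind}\t{f.start}\t{f.end}\t{f.note}\n")
    return path
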