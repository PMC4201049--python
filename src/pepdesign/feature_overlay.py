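"""Flag candidate windows for overlap with annotated sequence features.

A peptide overlapping a phosphorylation or glycosylation site may raise an
antibody blind to the modified protein; one overlapping a variant or an
alternative-splicing difference may miss some alleles or isoforms; one
inside a transmembrane span is inaccessible in the folded protein. The
flags are advisory — flagged windows stay in the report so trade-offs can
be judged — with optional exclusion switches at the CLI.

Kind-to-flag mapping:
    PTM              MOD_RES, CARBOHYD, LIPID, DISULFID
    variant          VARIANT
    splice/conflict  VAR_SEQ, CONFLICT
    membrane         TRANSMEM
    context          TOPO_DOM, DOMAIN, SIGNAL, OTHER (informational only)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_io import SequenceFeature

PTM_KINDS = frozenset({"MOD_RES", "CARBOHYD", "LIPID", "DISULFID"})
VARIANT_KINDS = frozenset({"VARIANT"})
SPLICE_CONFLICT_KINDS = frozenset({"VAR_SEQ", "CONFLICT"})
TRANSMEM_KINDS = frozenset({"TRANSMEM"})
CONTEXT_KINDS = frozenset({"TOPO_DOM", "DOMAIN", "SIGNAL", "OTHER"})


@dataclass
class WindowFlags:
    """Feature-overlap summary for one window."""

    start: int
    end: int
    ptm_detail: list[SequenceFeature] = field(default_factory=list)
    variant_detail: list[SequenceFeature] = field(default_factory=list)
    splice_conflict_detail: list[SequenceFeature] = field(default_factory=list)
    transmem_detail: list[SequenceFeature] = field(default_factory=list)
    domain_context: list[SequenceFeature] = field(default_factory=list)

    @property
    def ptm_overlap(self) -> bool:
        return bool(self.ptm_detail)

    @property
    def variant_overlap(self) -> bool:
        return bool(self.variant_detail)

    @property
    def splice_conflict_overlap(self) -> bool:
        return bool(self.splice_conflict_detail)

    @property
    def transmem_overlap(self) -> bool:
        return bool(self.transmem_detail)


def overlaps(window_start: int, window_end: int, feature: SequenceFeature) -> bool:
    """Closed-interval overlap: true iff max(starts) <= min(ends)."""
    return max(window_start, feature.start) <= min(window_end, feature.end)


def flag_window(start: int, end: int,
                features: list[SequenceFeature]) -> WindowFlags:
    """Overlap flags for a single window."""
    flags = WindowFlags(start=start, end=end)
    for f in features:
        if not overlaps(start, end, f):
            continue
        if f.kind in PTM_KINDS:
            flags.ptm_detail.append(f)
        elif f.kind in VARIANT_KINDS:
            flags.variant_detail.append(f)
        elif f.kind in SPLICE_CONFLICT_KINDS:
            flags.splice_conflict_detail.append(f)
        elif f.kind in TRANSMEM_KINDS:
            flags.transmem_detail.append(f)
        else:  # CONTEXT_KINDS — every remaining vocabulary kind
            flags.domain_context.append(f)
    return flags


def flag_windows(windows, features: list[SequenceFeature]) -> list[WindowFlags]:
    """Overlap flags for every window (windows carry .start/.end)."""
    return [flag_window(w.start, w.end, features) for w in windows]
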