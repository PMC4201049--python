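"""Assemble the ranked, track-aligned design report and write TSV / JSON.

One row per candidate window, sorted by position, carrying the Ig-score and
rank, the uniqueness and conservation tracks (``NA`` when no proteome /
orthologs were supplied — an absent track is not a zero), the feature
overlap flags, and normalised heat-map columns so an external renderer can
reproduce the brightest-green/yellow/red convention: per track,
(score - min) / (max - min), 0 when the track is constant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .epitope_index import (build_index, build_species_indices,
                            conservation_from_indices, default_target_ids,
                            uniqueness)
from .feature_overlay import WindowFlags, flag_windows
from .immunogenicity import DesignParams, PeptideWindow, score_windows
from .sequence_io import (FormatError, Proteome, ProteinRecord,
                          SequenceFeature)

logger = logging.getLogger("pepdesign")

SCHEMA_VERSION = "1.0"
NA = "NA"
CONJUGATION_NOTE = ("consider adding a terminal Cys for carrier conjugation; "
                    "sequence not modified")


@dataclass
class ReportRow:
    """One candidate window with every track attached."""

    window: PeptideWindow
    uniqueness_score: float | None = None
    off_target_ids: set[str] = field(default_factory=set)
    nonstandard_epitopes: list[str] = field(default_factory=list)
    per_species: dict[str, float] = field(default_factory=dict)
    conservation_overall: float | None = None
    flags: WindowFlags | None = None
    ig_norm: float | None = None
    uniqueness_norm: float | None = None
    conservation_norm: float | None = None


@dataclass
class DesignReport:
    """The tool's primary output: a ranked, track-aligned window table."""

    protein_id: str
    protein_length: int
    params: DesignParams
    species: list[str]
    rows: list[ReportRow]
    normalization: dict[str, dict[str, float]]

    @property
    def has_uniqueness(self) -> bool:
        return self.rows and self.rows[0].uniqueness_score is not None

    @property
    def has_conservation(self) -> bool:
        return bool(self.species)


def _track_norm(values: list[float]) -> tuple[dict[str, float], list[float]]:
    lo, hi = min(values), max(values)
    meta = {"min": lo, "max": hi}
    if hi == lo:
        return meta, [0.0] * len(values)
    return meta, [(v - lo) / (hi - lo) for v in values]


def run_design(target: ProteinRecord,
               proteome: Proteome | None = None,
               orthologs: dict[str, Proteome] | None = None,
               features: list[SequenceFeature] | None = None,
               params: DesignParams | None = None,
               target_ids: set[str] | None = None) -> DesignReport:
    """Run the full design: score, rank, and annotate every window.

    Uniqueness is computed only when a background proteome is given, and
    conservation only when ortholog sets are given; absent tracks appear as
    NA in the output. Extra ``features`` are merged with any carried by the
    target record. Deterministic for fixed inputs.
    """
    params = params or DesignParams()
    orthologs = orthologs or {}

    all_features = list(target.features)
    for f in features or []:
        if f.end > len(target.sequence):
            raise FormatError(
                f"feature {f.kind} [{f.start}, {f.end}] extends beyond the "
                f"{len(target.sequence)}-aa target")
        all_features.append(f)

    windows = score_windows(target, params)
    rows = [ReportRow(window=w) for w in windows]

    if proteome is not None:
        index = build_index(proteome, params.epitope_length)
        tids = target_ids or default_target_ids(target.id, proteome)
        for row in rows:
            u = uniqueness(row.window.sequence, row.window.start, index, tids)
            row.uniqueness_score = u.uniqueness_score
            row.off_target_ids = u.off_target_ids
            row.nonstandard_epitopes = u.nonstandard_epitopes
    else:
        logger.warning("no background proteome supplied; "
                       "uniqueness track will be NA")

    species = sorted(orthologs)
    if orthologs:
        indices = build_species_indices(orthologs, params.epitope_length)
        for row in rows:
            c = conservation_from_indices(row.window.sequence,
                                          row.window.start, indices,
                                          params.epitope_length)
            row.per_species = {sp: c.per_species[sp] for sp in species}
            row.conservation_overall = c.overall
    else:
        logger.warning("no ortholog sets supplied; "
                       "conservation track will be NA")

    for row, flags in zip(rows, flag_windows(windows, all_features)):
        row.flags = flags

    normalization: dict[str, dict[str, float]] = {}
    norm_ig, ig_normed = _track_norm([r.window.ig_score for r in rows])
    normalization["ig_score"] = norm_ig
    for row, v in zip(rows, ig_normed):
        row.ig_norm = v
    if rows[0].uniqueness_score is not None:
        meta, normed = _track_norm([r.uniqueness_score for r in rows])
        normalization["uniqueness_score"] = meta
        for row, v in zip(rows, normed):
            row.uniqueness_norm = v
    if species:
        meta, normed = _track_norm([r.conservation_overall for r in rows])
        normalization["conservation_overall"] = meta
        for row, v in zip(rows, normed):
            row.conservation_norm = v

    return DesignReport(protein_id=target.id,
                        protein_length=len(target.sequence),
                        params=params, species=species, rows=rows,
                        normalization=normalization)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _fmt(value: float | None) -> str:
    return NA if value is None else f"{value:.3f}"


def _join(items) -> str:
    return ";".join(items)


def report_columns(report: DesignReport) -> list[str]:
    """The fixed, documented column order of the TSV output."""
    return (
        ["start", "end", "sequence", "ig_score", "ig_rank",
         "hydrophilicity_component", "turn_component", "tail_bonus",
         "uniqueness_score", "off_target_ids", "nonstandard_epitopes"]
        + [f"cons_{sp}" for sp in report.species]
        + ["conservation_overall",
           "ptm_overlap", "ptm_detail", "variant_overlap",
           "splice_conflict_overlap", "transmem_overlap", "domain_context",
           "ig_norm", "uniqueness_norm", "conservation_norm", "note"]
    )


def _feature_labels(features: list[SequenceFeature]) -> str:
    return _join(f"{f.kind}@{f.start}-{f.end}" + (f"({f.note})" if f.note else "")
                 for f in features)


def report_to_frame(report: DesignReport) -> pd.DataFrame:
    """The report as a string-typed DataFrame in the documented column order."""
    cols = report_columns(report)
    data: list[list[str]] = []
    for row in report.rows:
        w, fl = row.window, row.flags
        rec = [
            str(w.start), str(w.end), w.sequence,
            _fmt(w.ig_score), str(w.rank),
            _fmt(w.hydrophilicity_component), _fmt(w.turn_component),
            _fmt(w.tail_bonus),
            _fmt(row.uniqueness_score),
            _join(sorted(row.off_target_ids)),
            _join(row.nonstandard_epitopes),
        ]
        rec += [_fmt(row.per_species[sp]) for sp in report.species]
        rec += [
            _fmt(row.conservation_overall),
            str(fl.ptm_overlap), _feature_labels(fl.ptm_detail),
            str(fl.variant_overlap), str(fl.splice_conflict_overlap),
            str(fl.transmem_overlap), _feature_labels(fl.domain_context),
            _fmt(row.ig_norm), _fmt(row.uniqueness_norm),
            _fmt(row.conservation_norm),
            CONJUGATION_NOTE,
        ]
        data.append(rec)
    return pd.DataFrame(data, columns=cols)


def write_report_tsv(report: DesignReport, path) -> Path:
    """Write the report as TSV: one header row, rows by position, floats to
    three decimals, list cells ';'-joined, absent tracks as NA, empty sets
    as empty cells."""
    path = Path(path)
    report_to_frame(report).to_csv(path, sep="\t", index=False,
                                   lineterminator="\n")
    return path


def report_to_dict(report: DesignReport) -> dict:
    """Full-fidelity structured dump (schema version 1.0)."""
    p = report.params
    return {
        "schema_version": SCHEMA_VERSION,
        "protein": {"id": report.protein_id, "length": report.protein_length},
        "params": {
            "peptide_length": p.peptide_length,
            "epitope_length": p.epitope_length,
            "tail_length": p.tail_length,
            "tail_bonus_factor": p.tail_bonus_factor,
            "high_ig_threshold": p.high_ig_threshold,
        },
        "species": report.species,
        "normalization": report.normalization,
        "rows": [
            {
                "start": r.window.start,
                "end": r.window.end,
                "sequence": r.window.sequence,
                "ig_score": r.window.ig_score,
                "ig_rank": r.window.rank,
                "hydrophilicity_component": r.window.hydrophilicity_component,
                "turn_component": r.window.turn_component,
                "tail_bonus": r.window.tail_bonus,
                "uniqueness_score": r.uniqueness_score,
                "off_target_ids": sorted(r.off_target_ids),
                "nonstandard_epitopes": r.nonstandard_epitopes,
                "conservation": r.per_species or None,
                "conservation_overall": r.conservation_overall,
                "ptm_overlap": r.flags.ptm_overlap,
                "ptm_detail": [
                    {"kind": f.kind, "start": f.start, "end": f.end, "note": f.note}
                    for f in r.flags.ptm_detail],
                "variant_overlap": r.flags.variant_overlap,
                "splice_conflict_overlap": r.flags.splice_conflict_overlap,
                "transmem_overlap": r.flags.transmem_overlap,
                "domain_context": [
                    {"kind": f.kind, "start": f.start, "end": f.end, "note": f.note}
                    for f in r.flags.domain_context],
                "ig_norm": r.ig_norm,
                "uniqueness_norm": r.uniqueness_norm,
                "conservation_norm": r.conservation_norm,
                "note": CONJUGATION_NOTE,
            }
            for r in report.rows
        ],
    }


def write_report_json(report: DesignReport, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=1)
        fh.write("\n")
    return path
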