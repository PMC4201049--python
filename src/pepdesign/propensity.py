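"""Residue propensity scales and per-residue display tracks.

Two classic scales ship with the package as tab-separated data files:

* the Kyte-Doolittle hydropathy index (positive = hydrophobic), used both
  for the hydropathy display track and for the hydrophilicity term of the
  immunogenicity score;
* the Chou-Fasman conformational parameters Pa (helix), Pb (sheet),
  Pt (beta turn), used for the secondary-structure display track and for
  the turn term of the immunogenicity score.

Nonstandard letters (B, Z, X, U, O, ...) take a neutral default so that a
window containing an X is not biased either way: KD 0.0, Pa = Pb = Pt = 1.0.

The secondary-structure track is a deliberately simplified single-pass
classifier over 5-residue centered propensity means — a display aid for
spotting turn-rich stretches, not a full Chou-Fasman nucleation/extension
prediction. It never feeds the immunogenicity score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .sequence_io import ParameterError

SS_CLASSES = ("HELIX", "SHEET", "TURN_STRONG", "TURN_WEAK", "NONE")


@dataclass(frozen=True)
class PropensityScale:
    """A residue → dimensionless propensity map with a default for absentees."""

    name: str
    values: dict[str, float]
    default_value: float = 0.0

    def __post_init__(self):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.values.get(residue.upper(), self.default_value)


def _read_scale_file(name: str) -> list[list[str]]:
    text = resources.files("pepdesign.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def load_kyte_doolittle() -> PropensityScale:
    """The packaged Kyte-Doolittle hydropathy scale (default 0.0)."""
    rows = _read_scale_file("kyte_doolittle.tsv")
    return PropensityScale("kyte_doolittle",
                           {r[0]: float(r[1]) for r in rows}, default_value=0.0)


def load_chou_fasman() -> tuple[PropensityScale, PropensityScale, PropensityScale]:
    """The packaged Chou-Fasman (Pa, Pb, Pt) scales (default 1.0 each)."""
    rows = _read_scale_file("chou_fasman.tsv")
    pa = PropensityScale("chou_fasman_Pa", {r[0]: float(r[1]) for r in rows}, 1.0)
    pb = PropensityScale("chou_fasman_Pb", {r[0]: float(r[2]) for r in rows}, 1.0)
    pt = PropensityScale("chou_fasman_Pt", {r[0]: float(r[3]) for r in rows}, 1.0)
    return pa, pb, pt


# module-level singletons: the scales are fixed package data
KYTE_DOOLITTLE = load_kyte_doolittle()
CF_HELIX, CF_SHEET, CF_TURN = load_chou_fasman()

#: Kyte-Doolittle range over the 20 standard residues, used for normalisation.
KD_MIN, KD_MAX = -4.5, 4.5
#: Chou-Fasman turn-propensity range over the 20 standard residues.
PT_MIN, PT_MAX = 0.47, 1.56


def windowed_mean(values: list[float], window: int) -> list[float]:
    """Centered moving average, truncating the window at the ends.

    The value at position i is the arithmetic mean over the residues of the
    window centered at i that actually exist; near the termini the window
    simply shrinks.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and positive, got {window}")
    n = len(values)
    half = window // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def hydropathy_track(sequence: str, window: int = 9) -> list[float]:
    """Window-averaged Kyte-Doolittle hydropathy, one value per residue.

    Hydrophilic (surface-exposed, antibody-accessible) stretches are the
    negative troughs of this track. Default window 9, the conventional
    choice for Kyte-Doolittle plots.
    """
    if window > len(sequence):
        raise ParameterError(
            f"window {window} exceeds sequence length {len(sequence)}")
    raw = [KYTE_DOOLITTLE[a] for a in sequence]
    return windowed_mean(raw, window)


def secondary_structure_track(sequence: str) -> list[str]:
    """Per-residue secondary-structure class from smoothed Chou-Fasman means.

    For each residue take the 5-wide centered means mPa, mPb, mPt
    (truncated at the ends) and assign, in priority order:

    * TURN_STRONG  if mPt >= 1.10 and mPt >= max(mPa, mPb)
    * TURN_WEAK    if 1.00 <= mPt < 1.10 and mPt >= max(mPa, mPb)
    * HELIX        if mPa >= 1.06 and mPa > mPb
    * SHEET        if mPb >= 1.05 and mPb >= mPa
    * NONE         otherwise

    The thresholds are the classic former/breaker cutoffs; ties resolve to
    the first matching class.
    """
    if not sequence:
        raise ParameterError("sequence must be non-empty")
    mpa = windowed_mean([CF_HELIX[a] for a in sequence], 5)
    mpb = windowed_mean([CF_SHEET[a] for a in sequence], 5)
    mpt = windowed_mean([CF_TURN[a] for a in sequence], 5)
    labels = []
    for a, b, t in zip(mpa, mpb, mpt):
        if t >= 1.10 and t >= max(a, b):
            labels.append("TURN_STRONG")
        elif 1.00 <= t < 1.10 and t >= max(a, b):
            labels.append("TURN_WEAK")
        elif a >= 1.06 and a > b:
            labels.append("HELIX")
        elif b >= 1.05 and b >= a:
            labels.append("SHEET")
        else:
            labels.append("NONE")
    return labels


@dataclass
class ResidueTracks:
    """Aligned per-residue display tracks for one protein."""

    hydropathy: list[float]
    ss_class: list[str]


def residue_tracks(sequence: str, hydropathy_window: int = 9) -> ResidueTracks:
    """Compute both display tracks for a sequence."""
    return ResidueTracks(
        hydropathy=hydropathy_track(sequence, hydropathy_window),
        ss_class=secondary_structure_track(sequence),
    )
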