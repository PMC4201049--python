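# Methods

## Scope and coordinates

`pepdesign` evaluates *linear* peptide immunogens only: candidate windows
are contiguous substrings of the target, and epitopes within them are
modelled as contiguous k-mers. Conformational/structural epitope methods
are deliberately out of scope. All coordinates are 1-based inclusive, the
UniProt convention, in every module, file format and report column.

## Propensity scales

The Kyte–Doolittle hydropathy index and the Chou–Fasman conformational
parameters (Pa helix, Pb sheet, Pt turn) are transcribed from the original
publications into `src/pepdesign/data/*.tsv` with provenance headers;
loading asserts all 20 standard residues are present, and the tests pin
anchor values (Ile KD = 4.5, Arg KD = −4.5, Asn/Gly Pt = 1.56, Ile
Pt = 0.47). Nonstandard letters (B, Z, X, U, O) are tolerated in input
sequences and score with neutral defaults — KD 0.0, Pa = Pb = Pt = 1.0 —
so a stray X neither inflates nor deflates a window.

## The Ig-score

The immunogenicity score of a window is a normalised three-factor product:

    Ig = 10 · H · T · b

* `H = clamp((4.5 − meanKD)/9, 0, 1)` — the window's mean Kyte–Doolittle
  value mapped onto [0, 1] over the scale's range [−4.5, 4.5], with 1 at
  the hydrophilic extreme.
* `T = clamp((meanPt − 0.47)/1.09, 0, 1)` — the window's mean Chou–Fasman
  turn parameter mapped onto [0, 1] over the attainable per-residue range
  [0.47, 1.56].
* `b` — the tail bonus: `tail_bonus_factor` (default 2.0) when the window
  lies *entirely* within `tail_length` (default 60) residues of either
  terminus, else 1. Full containment rather than mere overlap keeps the
  rule unambiguous and testable.

The factor-of-10 rescaling places scores in a 0–10·B band in which 7 is
the documented "high immunogenicity" threshold; the C-terminal aquaporin-2
reference peptide `EPDTDWEEREVRRRQ` scores 7.457 under the defaults
(H = 0.807, T = 0.462, b = 2), which the acceptance script recomputes.
Where the design was genuinely open — the tail extent, whether the bonus is
additive or multiplicative, and whether the product is rescaled — this
package's choices are: multiplicative bonus, T_tail = 60, B = 2.0, rescale
by 10. These defaults are frozen; an optional networked check
(`scripts/paper_check.py`) additionally verifies that the reference peptide
ranks second among all 15-mers of the full rat aquaporin-2 sequence.

Ranking is competition ranking on descending score: tied windows share the
smallest rank and the next distinct score gets rank = (number of strictly
better windows) + 1. File output stays in position order with rank as a
column; the console summary orders by rank, ties by start.

## Uniqueness and conservation

Both predictors run on an exact-substring k-mer index (`EpitopeIndex`:
E-mer → set of protein ids). E is the user's epitope length, default 7 —
roughly the footprint of an antibody's contact with a linear epitope.
E-mers containing nonstandard letters are never indexed; in uniqueness they
count as zero-hit (and are listed in a flag column) rather than as
off-target evidence.

* Uniqueness of a window = fraction of its L−E+1 E-mers with **zero**
  off-target hits in the background proteome. The self set defaults to the
  target id plus any proteome ids sharing its accession root before a
  hyphen (the "P12345-2" isoform convention), overridable with
  `--target-ids`. Internal repeats of the target are therefore self, never
  off-target.
* Conservation per species = fraction of the window's E-mers present
  *anywhere* in that species' ortholog set (not position-restricted —
  the simplest rule consistent with antibody cross-reactivity). The overall
  value is the unweighted mean across species. Species with empty ortholog
  files score 0 with a logged warning.

Fractions rather than binary flags preserve the graded "partially
aligned / partially conserved" cases; the prose bands are ≥ 0.999 →
unique/conserved, (0, 0.999) → partial, 0 → none.

## Feature overlap

Closed-interval overlap (`max(starts) ≤ min(ends)`) between each window and
each feature, routed by kind: PTM = {MOD_RES, CARBOHYD, LIPID, DISULFID}
(disulfide bridges are treated as PTM-like epitope risks), variant =
{VARIANT}, splice/conflict = {VAR_SEQ, CONFLICT}, membrane = {TRANSMEM},
context = {TOPO_DOM, DOMAIN, SIGNAL, OTHER}. Flags are advisory and never
enter the Ig-score; the CLI's `--exclude-ptm`/`--exclude-transmem` switches
drop rows post hoc.

## Display tracks

The per-residue hydropathy track is a centered moving average (default
window 9, truncated at the ends). The secondary-structure track is a
simplified single-pass classifier over 5-wide centered means of Pa/Pb/Pt
with the classic former cutoffs (turn ≥ 1.10 strong / ≥ 1.00 weak when
turn dominates; helix mPa ≥ 1.06, mPa > mPb; sheet mPb ≥ 1.05, mPb ≥ mPa;
priority in that order). It is a display aid only — not a claim to
reproduce any particular published predictor, and never an input to the
score.

## Report and serialisation

One row per window, position-sorted. TSV: fixed documented column order,
floats to 3 decimals, ';'-joined list cells, `NA` for an absent track
(no proteome / no orthologs supplied) as distinct from a computed 0, empty
string for an empty set. JSON: exact floats, run parameters,
`schema_version` "1.0". Heat-map columns are min–max normalised per track —
(x − min)/(max − min), defined as 0 for a constant track — with the min/max
recorded in the report's normalisation metadata so an external renderer can
reproduce the brightest-colour convention. Identical inputs give
byte-identical TSV output.

## Synthetic data

The fixture generator (`pepdesign.fixtures`) draws i.i.d. sequences from a
configurable residue composition (uniform by default) with Python's
Mersenne Twister (`random.Random`), whose integer-seeded stream is stable
across platforms and CPython versions; per-protein streams are seeded with
`seed · 1000003 + index`. Shared epitopes are arranged by overwriting
planted k-mers at stated positions; orthologs are per-position independent
substitutions at a given rate (a point-substitution model — no indels, no
phylogeny, no compositional realism). Default toy-proteome size is 10–50
proteins of 60–300 aa, which exercises every code path in well under a
second. Consequences: passing tests demonstrate correctness of the
machinery (index ≡ brute-force scan, flags ≡ all-pairs oracle, ranking ≡
strictly-better counting, monotonicities, round-trips), not biological
performance on real proteomes, where k-mer sharing is far more structured
than under an i.i.d. model.

## Problem sizes and determinism

The offline test suite and the acceptance script use in-paper peptides and
synthetic proteomes of ≤ 50 × ≤ 300 aa; a full run on a real proteome
(~20,000 proteins) is linear in total residues for index construction and
in windows × species for annotation. Everything outside the fixture
generator is deterministic; the fixture generator is deterministic given
its seed.

## Known limitations

* Exact matching only — a single conservative substitution in an ortholog
  breaks all E-mers crossing it, so conservation is a lower bound on
  cross-reactivity.
* Only the modern UniProt flat-file FT dialect (key + `a..b` spans +
  `/note`) is parsed; the pre-2019 fixed-column dialect is not.
* Features with uncertain positions (`?`, `<`, `>`) are skipped with a
  warning rather than approximated.
* The Ig-score is a screening heuristic; it ignores surface probability,
  structural context and MHC presentation entirely.
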