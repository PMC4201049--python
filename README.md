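# pepdesign

Offline design of peptide immunogens for antibody production.

Raising an antibody against a protein usually starts with choosing a short
synthetic peptide (typically 12–30 aa) to immunize with. A good immunizing
peptide should be **immunogenic** (hydrophilic, turn-rich, ideally near a
disordered terminus), **unique** in the host proteome (so the antibody is
specific), **conserved** in the other species the antibody should work in,
and free of **post-translational modification sites, variants, splice
differences and membrane-buried stretches** that could ablate the epitope.
`pepdesign` scores every candidate window of a target protein on all of
these axes at once and emits a ranked, track-aligned report so the
trade-offs can be judged together.

## The model

For a protein of length *n* and a chosen peptide length *L*, every one of
the *n − L + 1* windows gets an immunogenicity score

```
Ig = 10 · H · T · b
H = clamp((4.5 − meanKD) / 9, 0, 1)          hydrophilicity (Kyte–Doolittle)
T = clamp((meanPt − 0.47) / 1.09, 0, 1)      turn propensity (Chou–Fasman Pt)
b = B if the window lies wholly within the first or last
    T_tail residues, else 1                  tail bonus (default B = 2, T_tail = 60)
```

where meanKD and meanPt are the arithmetic means of the published
Kyte–Doolittle hydropathy values and Chou–Fasman β-turn parameters over the
window, and the normalisation constants are the ranges of the two scales
over the 20 standard residues (KD ∈ [−4.5, 4.5], Pt ∈ [0.47, 1.56]). A
score of **7 or more** counts as high immunogenicity. Windows are ranked by
competition ranking (ties share the best rank).

Specificity and cross-reactivity are both modelled through epitope-length
k-mers (default *E* = 7): an antibody recognises contiguous stretches of
the peptide, so

* **uniqueness** = fraction of the window's *E*-mers found in *no*
  off-target protein of the background proteome (exact substring matching;
  the target and its isoforms count as self);
* **conservation** per species = fraction of the window's *E*-mers present
  anywhere in that species' ortholog sequence(s).

Feature overlap flags (PTMs, variants, splice/conflict regions,
transmembrane spans, plus topological context) are advisory columns, not
filters, though `--exclude-ptm` / `--exclude-transmem` can drop flagged
windows.

## Worked example

Inputs can be plain FASTA or a UniProt/Swiss-Prot flat-text record (feature
lines are picked up automatically); a tab-separated feature table can stand
in when no curated record exists. The package ships a deterministic
synthetic-data generator, which the example below uses:

```python
from pepdesign.fixtures import (FixtureSpec, make_protein, make_ortholog,
                                write_fixture_fasta)
from pepdesign.sequence_io import write_fasta

spec = FixtureSpec(seed=11, n_proteins=8, length_range=(120, 220))
write_fixture_fasta(spec, "proteome.fa")          # background proteome
target = make_protein(spec, 0)
write_fasta([target], "target.fa")
write_fasta([make_ortholog(target, 0.05, seed=12)], "mouse.fa")
```

```sh
pepdesign --target target.fa --proteome proteome.fa \
          --ortholog mouse=mouse.fa --peptide-length 18 \
          --out design --format both --top 3
```

prints

```
# SYN000000  length=206  L=18  E=7
rank	start	end	sequence	ig_score	uniqueness
1	1	18	SHCQYGLMTPLHNFVRHG	5.623	1.000 (unique)
2	178	195	HNLIKSIYNYYMPRKPML	5.606	1.000 (unique)
3	177	194	VHNLIKSIYNYYMPRKPM	5.530	1.000 (unique)
```

The best windows here sit at the two termini — both windows are inside the
60-residue tail regions, so their Ig-scores carry the ×2 tail bonus — and
every epitope-length 7-mer of each is absent from the other seven proteome
records (uniqueness 1.000). `design.tsv` holds one row per window, sorted
by position, with the score components, per-species conservation fractions,
feature flags, and min–max-normalised heat-map columns; `design.json` is
the same report with exact floats and the run parameters, under
`schema_version` 1.0.

The published anchor the engine is calibrated around: the C-terminal
aquaporin-2 peptide `EPDTDWEEREVRRRQ` scores

```
H = 0.807, T = 0.462, b = 2  →  Ig = 7.457  (high, ≥ 7)
```

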