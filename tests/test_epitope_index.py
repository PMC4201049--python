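"""k-mer index, uniqueness and conservation vs naive substring-scan oracles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdesign.epitope_index import (build_index, conservation,
                                     conservation_band, default_target_ids,
                                     uniqueness, uniqueness_band)
from pepdesign.fixtures import FixtureSpec, make_ortholog, make_proteome
from pepdesign.sequence_io import (STANDARD_AA, ParameterError, Proteome,
                                   ProteinRecord)

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_hits(kmer, proteome):
    """Brute-force substring scan: ids of proteins containing the k-mer."""
    return {r.id for r in proteome if kmer in r.sequence}


class TestBuildIndex:
    def test_single_record_dimers(self):
        p = Proteome(records=[ProteinRecord(id="a", sequence="ACDE")])
        idx = build_index(p, 2)
        assert set(idx.postings) == {"AC", "CD", "DE"}
        assert all(v == {"a"} for v in idx.postings.values())
        assert idx.lookup("QQ") == set()

    def test_shared_kmer_posts_both_ids(self):
        p = Proteome(records=[ProteinRecord(id="a", sequence="AKNPDA"),
                              ProteinRecord(id="b", sequence="CCKNPDCC")])
        assert build_index(p, 4).lookup("KNPD") == {"a", "b"}

    def test_nonstandard_kmers_not_indexed(self):
        p = Proteome(records=[ProteinRecord(id="a", sequence="AXAA")])
        idx = build_index(p, 2)
        assert set(idx.postings) == {"AA"}

    def test_invalid_epitope_length(self):
        p = Proteome(records=[ProteinRecord(id="a", sequence="ACDE")])
        with pytest.raises(ParameterError):
            build_index(p, 0)

    def test_matches_substring_scan_on_random_proteome(self, random_proteome):
        idx = build_index(random_proteome, 7)
        # every posted k-mer agrees with the scan ...
        for kmer in list(idx.postings)[::97]:
            assert idx.postings[kmer] == naive_hits(kmer, random_proteome)
        # ... and every window k-mer of every 5th protein is found
        for rec in random_proteome.records[::5]:
            for i in range(len(rec.sequence) - 6):
                kmer = rec.sequence[i:i + 7]
                assert idx.lookup(kmer) == naive_hits(kmer, random_proteome)


class TestUniqueness:
    def test_toy_example(self, uniq_toy):
        target, proteome = uniq_toy
        idx = build_index(proteome, 4)
        u = uniqueness("KNPDGSQ", 3, idx, {"T1"})
        assert u.uniqueness_score == pytest.approx(0.75)
        assert u.off_target_ids == {"OFF1"}
        assert u.per_epitope == {"KNPD": 0, "NPDG": 0, "PDGS": 0, "DGSQ": 1}

    def test_lone_target_is_fully_unique(self):
        target = ProteinRecord(id="t", sequence="MKNPDGSQRW")
        idx = build_index(Proteome(records=[target]), 4)
        u = uniqueness("KNPDGSQ", 2, idx, {"t"})
        assert u.uniqueness_score == 1.0 and not u.off_target_ids

    def test_unlisted_duplicate_kills_uniqueness(self):
        target = ProteinRecord(id="t", sequence="MKNPDGSQRW")
        dup = ProteinRecord(id="other", sequence="MKNPDGSQRW")
        idx = build_index(Proteome(records=[target, dup]), 4)
        u = uniqueness("KNPDGSQ", 2, idx, {"t"})
        assert u.uniqueness_score == 0.0 and u.off_target_ids == {"other"}

    def test_isoform_ids_default_to_self(self):
        proteome = Proteome(records=[
            ProteinRecord(id="P12345", sequence="MKNPDGSQRW"),
            ProteinRecord(id="P12345-2", sequence="MKNPDGSQRW"),
            ProteinRecord(id="P99999", sequence="AAAA")])
        assert default_target_ids("P12345", proteome) == {"P12345", "P12345-2"}

    def test_window_shorter_than_epitope_rejected(self):
        idx = build_index(
            Proteome(records=[ProteinRecord(id="a", sequence="ACDEFG")]), 4)
        with pytest.raises(ParameterError):
            uniqueness("AC", 1, idx, set())

    def test_nonstandard_epitopes_flagged_not_counted_as_hits(self):
        target = ProteinRecord(id="t", sequence="MKXNPDGSQ")
        idx = build_index(Proteome(records=[target]), 4)
        u = uniqueness("MKXNPDG", 1, idx, {"t"})
        assert "MKXN" in u.nonstandard_epitopes
        assert u.uniqueness_score == 1.0

    def test_adding_protein_never_increases_uniqueness(self, random_proteome):
        target = random_proteome.records[0]
        windows = [(target.sequence[i:i + 18], i + 1)
                   for i in range(0, len(target.sequence) - 17, 7)]
        tids = {target.id}
        scores = {}
        for n in (10, 30, 50):
            sub = Proteome(records=random_proteome.records[:n])
            idx = build_index(sub, 7)
            scores[n] = [uniqueness(s, p, idx, tids).uniqueness_score
                         for s, p in windows]
        assert all(a >= b for a, b in zip(scores[10], scores[30]))
        assert all(a >= b for a, b in zip(scores[30], scores[50]))


class TestConservation:
    def test_identical_ortholog_is_fully_conserved(self, small_protein):
        orth = Proteome(records=[make_ortholog(small_protein, 0.0, seed=1)])
        seq = small_protein.sequence
        for start in (1, 40, len(seq) - 17):
            c = conservation(seq[start - 1:start + 17], start,
                             {"mouse": orth}, 7)
            assert c.per_species["mouse"] == 1.0 and c.overall == 1.0

    def test_unrelated_ortholog_scores_zero(self):
        window = "KNPDGSQ"
        orth = Proteome(records=[ProteinRecord(id="o", sequence="WWWWYYYYWWWW")])
        assert "KNPD" not in orth.records[0].sequence
        c = conservation(window, 1, {"rat": orth}, 4)
        assert c.per_species["rat"] == 0.0

    def test_partial_overlap_toy(self):
        orth = Proteome(records=[ProteinRecord(id="m", sequence="AAKNPDGAA")])
        c = conservation("KNPDGSQ", 1, {"mouse": orth}, 4)
        # KNPD and NPDG present, PDGS and DGSQ absent
        assert c.per_species["mouse"] == pytest.approx(0.5)

    def test_overall_is_mean_over_species(self):
        same = Proteome(records=[ProteinRecord(id="s", sequence="KNPDGSQ")])
        none = Proteome(records=[ProteinRecord(id="n", sequence="WWWWWWWW")])
        c = conservation("KNPDGSQ", 1, {"a": same, "b": none}, 4)
        assert c.overall == pytest.approx(0.5)

    def test_no_species_rejected(self):
        with pytest.raises(ParameterError):
            conservation("KNPDGSQ", 1, {}, 4)

    def test_empty_species_scores_zero_with_warning(self, caplog):
        empty = Proteome(records=[])
        c = conservation("KNPDGSQ", 1, {"ghost": empty}, 4)
        assert c.per_species["ghost"] == 0.0

    def test_adding_ortholog_never_decreases_conservation(self, small_protein):
        seq = small_protein.sequence
        window, start = seq[20:38], 21
        far = make_ortholog(small_protein, 0.8, seed=2)
        close = make_ortholog(small_protein, 0.05, seed=3)
        c1 = conservation(window, start,
                          {"sp": Proteome(records=[far])}, 7)
        c2 = conservation(window, start,
                          {"sp": Proteome(records=[far, close])}, 7)
        assert c2.per_species["sp"] >= c1.per_species["sp"]

    def test_self_conservation_is_one_for_every_window(self, small_protein):
        orth = {"self": Proteome(records=[
            ProteinRecord(id="copy", sequence=small_protein.sequence)])}
        seq = small_protein.sequence
        for start in range(1, len(seq) - 17, 11):
            c = conservation(seq[start - 1:start + 17], start, orth, 7)
            assert c.overall == 1.0


class TestBands:
    @pytest.mark.parametrize("score,band", [
        (1.0, "unique"), (0.9995, "unique"), (0.6, "partial"), (0.0, "none")])
    def test_uniqueness_bands(self, score, band):
        assert uniqueness_band(score) == band

    @pytest.mark.parametrize("score,band", [
        (1.0, "conserved"), (0.5, "partial"), (0.0, "none")])
    def test_conservation_bands(self, score, band):
        assert conservation_band(score) == band


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.lists(st.text(AA, min_size=10, max_size=60), min_size=1,
                max_size=8), st.integers(2, 5))
def test_index_equals_scan_property(seqs, k):
    proteome = Proteome(records=[ProteinRecord(id=f"r{i}", sequence=s)
                                 for i, s in enumerate(seqs)])
    idx = build_index(proteome, k)
    for rec in proteome:
        for i in range(len(rec.sequence) - k + 1):
            kmer = rec.sequence[i:i + k]
            assert idx.lookup(kmer) == naive_hits(kmer, proteome)
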