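"""SSR detection against a brute-force maximal-repeat oracle, motif
canonicalization, and cross-genotype polymorphism calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergene.ssrmine import (
    SSRLocus,
    canonical_motif,
    classify_ssrs,
    detect_ssrs,
    export_primer_regions,
    match_polymorphic,
)

THRESH = {1: 8, 2: 6, 3: 4, 4: 4, 5: 4, 6: 4}


# ---------------------------------------------------------------- oracle
def _primitive(m):
    return all(not (len(m) % d == 0 and m == m[: d] * (len(m) // d))
               for d in range(1, len(m)))


def oracle_detect(seq, thresholds, min_seq_len=0):
    """Independent enumeration of maximal perfect repeats by substring
    comparison, with the same longest-first overlap resolution."""
    if len(seq) < min_seq_len:
        return []
    cands = []
    for u, mr in thresholds.items():
        for s in range(len(seq) - u):
            if seq[s] != seq[s + u]:
                continue
            if s > 0 and seq[s - 1] == seq[s - 1 + u]:
                continue  # not the leftmost phase of its periodic region
            motif = seq[s : s + u]
            if "N" in motif or not _primitive(motif):
                continue
            k = 1
            while seq[s + k * u : s + (k + 1) * u] == motif:
                k += 1
            if k >= mr:
                cands.append((s, u, k, motif))
    cands.sort(key=lambda t: (-t[1] * t[2], t[0], t[1]))
    taken, kept = [], []
    for s, u, k, motif in cands:
        lo, hi = s, s + u * k - 1
        if any(not (hi < a or lo > b) for a, b in taken):
            continue
        taken.append((lo, hi))
        kept.append((s + 1, u, k, motif))
    return sorted(kept)


def _as_tuples(loci):
    return sorted((l.start, l.unit, l.repeats, l.motif) for l in loci)


# ---------------------------------------------------------------- detection
class TestDetect:
    def test_poly_n_has_no_ssrs(self):
        assert detect_ssrs({"s": "N" * 1200}, THRESH) == []

    def test_planted_tgt_repeat(self):
        rng = np.random.default_rng(0)
        seq = oracle_free_background(rng, 1200)
        seq = seq[:600] + "TGTTGTTGTTGT" + seq[612:]
        # guard bases so the planted tract is exact
        seq = seq[:599] + "A" + seq[600:612] + "A" + seq[613:]
        loci = detect_ssrs({"s": seq}, THRESH)
        planted = [l for l in loci if l.motif == "TGT"]
        assert len(planted) == 1
        l = planted[0]
        assert (l.start, l.end, l.repeats, l.unit) == (601, 612, 4, 3)
        assert l.end - l.start + 1 == l.unit * l.repeats == 12

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.3, 0.2, 0.2, 0.3]))
            got = _as_tuples(detect_ssrs({"s": seq}, THRESH, min_seq_len=0))
            assert got == oracle_detect(seq, THRESH)

    def test_length_filter(self):
        seq = "A" * 20 + "C" * 500
        assert detect_ssrs({"s": seq}, THRESH, min_seq_len=1000) == []
        assert len(detect_ssrs({"s": seq}, THRESH, min_seq_len=100)) > 0

    def test_flanks_truncated_at_sequence_ends(self):
        seq = "T" * 12 + "GACGGATCGC" * 120
        locus = detect_ssrs({"s": seq}, THRESH, min_seq_len=0)[0]
        assert locus.upstream_flank == ""
        assert len(locus.downstream_flank) == 300

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError, match="bad_seq"):
            detect_ssrs({"bad_seq": "ACGU" * 300}, THRESH, min_seq_len=0)

    def test_strand_consistency(self):
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(2)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=1500, p=[0.35, 0.15, 0.15, 0.35]))
            fwd = detect_ssrs({"s": seq}, THRESH, min_seq_len=0)
            rc = seq.translate(comp)[::-1]
            rev = detect_ssrs({"s": rc}, THRESH, min_seq_len=0)
            assert len(fwd) == len(rev)
            L = len(seq)
            fwd_keys = sorted((l.canonical, l.unit, l.repeats) for l in fwd)
            rev_keys = sorted((l.canonical, l.unit, l.repeats) for l in rev)
            assert fwd_keys == rev_keys
            # mirrored coordinates up to the phase of a partial repeat unit
            fwd_pos = sorted(L - l.end + 1 for l in fwd)
            rev_pos = sorted(l.start for l in rev)
            assert all(abs(a - b) < 6 for a, b in zip(fwd_pos, rev_pos))


def oracle_free_background(rng, n):
    """Random sequence without tandem repeats near the thresholds."""
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if not oracle_detect(seq, {u: max(3, t - 1) for u, t in THRESH.items()}):
            return seq


# ---------------------------------------------------------------- classes
class TestClassify:
    def test_percentage_arithmetic(self):
        units = [1] * 793 + [2] * 273 + [3] * 564 + [4] * 9 + [5] * 10 + [6] * 8
        table = classify_ssrs(units).set_index("ssr_class")
        assert table.loc["mono", "percentage"] == 47.86
        assert table.loc["tri", "percentage"] == 34.04
        assert abs(table["percentage"].sum() - 100.0) <= 0.02

    def test_empty_input_all_zero(self):
        table = classify_ssrs([])
        assert (table["count"] == 0).all() and (table["percentage"] == 0).all()


class TestCanonicalMotif:
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(deadline=None, derandomize=True)
    def test_invariant_under_rotation_and_reverse_complement(self, motif):
        comp = str.maketrans("ACGT", "TGCA")
        expect = canonical_motif(motif)
        for i in range(len(motif)):
            rot = motif[i:] + motif[:i]
            assert canonical_motif(rot) == expect
            assert canonical_motif(rot.translate(comp)[::-1]) == expect
        assert len(expect) == len(motif)

    @pytest.mark.parametrize("a,b", [("TGT", "ACA"), ("CT", "AG"), ("GAA", "TTC"),
                                     ("T", "A"), ("TCTT", "AAGA")])
    def test_reverse_complement_pairs_share_canonical(self, a, b):
        assert canonical_motif(a) == canonical_motif(b)

    def test_rotations_share_canonical(self):
        assert canonical_motif("TGT") == canonical_motif("GTT") == canonical_motif("TTG")


# ---------------------------------------------------------------- matching
def _locus(sid, motif, reps, start=500, up="G" * 300, down="C" * 300):
    u = len(motif)
    return SSRLocus(unigene_id=sid, motif=motif, canonical=canonical_motif(motif),
                    unit=u, repeats=reps, start=start, end=start + u * reps - 1,
                    upstream_flank=up, downstream_flank=down)


class TestMatchPolymorphic:
    def test_divergence_four_passes_rule(self):
        poly = match_polymorphic([_locus("P1", "CT", 8)], [_locus("G1", "CT", 6)],
                                 [("P1", "G1")])
        assert len(poly) == 1
        assert poly[0].divergence_nt == 4 and poly[0].passes_primer_rule

    def test_divergence_one_fails_rule(self):
        poly = match_polymorphic([_locus("P1", "T", 11)], [_locus("G1", "T", 12)],
                                 [("P1", "G1")])
        assert len(poly) == 1
        assert poly[0].divergence_nt == 1 and not poly[0].passes_primer_rule

    def test_identical_repeats_not_polymorphic(self):
        assert match_polymorphic([_locus("P1", "TGT", 5)], [_locus("G1", "TGT", 5)],
                                 [("P1", "G1")]) == []

    def test_flank_anchor_rejects_unrelated_loci(self):
        a = _locus("P1", "CT", 8, up="A" * 300, down="A" * 300)
        b = _locus("G1", "CT", 6, up="G" * 300, down="G" * 300)
        assert match_polymorphic([a], [b], [("P1", "G1")]) == []

    def test_orientation_robust_matching(self):
        # TGT in P vs ACA in G: same canonical motif, matched
        poly = match_polymorphic([_locus("P1", "TGT", 6)], [_locus("G1", "ACA", 4)],
                                 [("P1", "G1")])
        assert len(poly) == 1 and poly[0].divergence_nt == 6


class TestExportPrimerRegions:
    def test_full_flanks_emitted(self):
        records, flagged = export_primer_regions(
            match_polymorphic([_locus("P1", "CT", 8)], [_locus("G1", "CT", 6)],
                              [("P1", "G1")])
        )
        assert len(records) == 1 and len(flagged) == 0
        row = records.iloc[0]
        assert row["target_start"] == 301 and row["target_end"] == 316
        assert len(row["template"]) == 616

    def test_short_flank_flagged_not_emitted(self):
        short = _locus("P1", "CT", 8, up="G" * 10)
        poly = match_polymorphic([short], [_locus("G1", "CT", 6)], [("P1", "G1")])
        records, flagged = export_primer_regions(poly)
        assert len(records) == 0 and len(flagged) == 1

    def test_counting_mixed(self):
        pairs = [("P1", "G1"), ("P2", "G2"), ("P3", "G3")]
        ssrs_p = [_locus("P1", "CT", 8), _locus("P2", "GA", 9),
                  _locus("P3", "T", 12, up="G" * 20)]
        ssrs_g = [_locus("G1", "CT", 6), _locus("G2", "GA", 7), _locus("G3", "T", 9)]
        records, flagged = export_primer_regions(match_polymorphic(ssrs_p, ssrs_g, pairs))
        assert len(records) == 2 and len(flagged) == 1
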