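"""Six-frame translation, motif scanners, in-silico PCR and peptide mass."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from evlpkit import fixtures
from evlpkit.sequence_tools import (
    DEFAULT_PROPERTY_CLASSES,
    FRAMES,
    MotifHit,
    PeptideQuery,
    PrimerPair,
    insilico_pcr,
    peptide_average_mass,
    rank_candidates,
    scan_exact,
    scan_hamming,
    scan_property,
    translate_six_frames,
)
from evlpkit.simulate import gen_plasmid_with_motif

QUERY = fixtures.HIBIT_PEPTIDE

# ---------------------------------------------------------------------------
# independent oracles

_ORACLE_CODONS = {
    # built independently from the standard genetic code, first-listed codon
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def oracle_scan(frames, query, mode, threshold, alphabet=None):
    """Naive all-windows scan used as the reference for every scanner."""
    alphabet = DEFAULT_PROPERTY_CLASSES if alphabet is None else alphabet
    k = len(query)
    hits = []
    for fr in frames:
        for off in range(len(fr.peptide) - k + 1):
            win = fr.peptide[off : off + k]
            if "*" in win:
                continue
            if mode == "exact":
                if "X" in win or win != query:
                    continue
                d = 0
            elif mode == "hamming":
                d = sum(1 for a, b in zip(win, query) if a != b)
            else:
                d = sum(
                    1
                    for a, b in zip(win, query)
                    if alphabet.get(a) != alphabet.get(b) or a == "X"
                )
            if d <= threshold:
                hits.append((d, fr.source_id, FRAMES.index(fr.frame), off, win))
    return sorted(hits)


def as_tuples(hits):
    return [(h.distance, h.source_id, FRAMES.index(h.frame), h.offset, h.window)
            for h in hits]


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


# ---------------------------------------------------------------------------
# translation


@pytest.mark.parametrize(
    "seq,frame,expected",
    [
        ("ATGGCC", 1, "MA"),
        ("ATGGCC", -1, "GH"),  # revcomp GGCCAT -> G, H
        ("ATGGCCA", 2, "WP"),
        ("TAATAG", 1, "**"),  # stops kept, translation continues
        ("ATGNCCATG", 1, "MXM"),  # ambiguous codon -> X
    ],
)
def test_translation_examples(seq, frame, expected):
    frames = {f.frame: f for f in translate_six_frames(seq, "s")}
    assert frames[frame].peptide == expected


def test_translation_roundtrip_from_codon_table():
    # 33-nt coding sequence built residue-by-residue from an independent table
    seq = "".join(_ORACLE_CODONS[aa] for aa in QUERY)
    assert len(seq) == 33
    frames = {f.frame: f for f in translate_six_frames(seq, "s")}
    assert frames[1].peptide == QUERY


def test_translation_properties():
    frames = translate_six_frames("ATGGCCGTAAACCT", "s")
    assert len(frames) == 6
    n = 14
    for fr in frames:
        assert len(fr.peptide) == (n - (abs(fr.frame) - 1)) // 3
        for i in range(len(fr.peptide)):
            assert 0 <= fr.nt_start(i) <= n - 3


def test_translation_errors():
    with pytest.raises(ValueError):
        translate_six_frames("AT", "s")
    with pytest.raises(ValueError, match="position 2"):
        translate_six_frames("ATZGCC", "s")


def test_reverse_frame_mapping_roundtrips_through_revcomp(rng):
    seq = "".join(rng.choice(list("ACGT"), size=120))
    frames = {f.frame: f for f in translate_six_frames(seq, "s")}
    rc_frames = {f.frame: f for f in translate_six_frames(revcomp(seq), "s")}
    n = len(seq)
    for k in (1, 2, 3):
        assert frames[-k].peptide == rc_frames[k].peptide
        # the -k codon's forward coordinate mirrors its +k position on rc(seq)
        for i in range(len(frames[-k].peptide)):
            assert frames[-k].nt_start(i) == n - rc_frames[k].nt_start(i) - 3


# ---------------------------------------------------------------------------
# scanners


def test_exact_scan_finds_planted_motif():
    rec, ann = gen_plasmid_with_motif(300, QUERY, frame=2, offset=7, seed=5)
    frames = translate_six_frames(str(rec.seq), rec.id)
    hits = scan_exact(frames, QUERY)
    assert [(h.frame, h.offset, h.distance) for h in hits] == [(2, 7, 0)]
    assert hits[0].nt_start == ann["nt_start"]


def test_exact_scan_absent_query_and_double_plant():
    rec, _ = gen_plasmid_with_motif(300, QUERY, frame=1, offset=0, seed=6)
    frames = translate_six_frames(str(rec.seq), rec.id)
    assert scan_exact(frames, "WWWWWWWWWWW") == []
    # plant a second copy in a different record -> two hits total
    rec2, _ = gen_plasmid_with_motif(300, QUERY, frame=-2, offset=3, seed=7)
    frames2 = translate_six_frames(str(rec2.seq), rec2.id)
    hits = scan_exact(frames + frames2, QUERY)
    assert len(hits) == 2
    assert {h.frame for h in hits} == {1, -2}


def test_hamming_distances():
    frames = translate_six_frames(
        "".join(_ORACLE_CODONS[aa] for aa in QUERY), "s"
    )
    assert scan_hamming(frames, QUERY, 0)[0].distance == 0
    mutated = QUERY[:-1] + "A"
    frames_mut = translate_six_frames(
        "".join(_ORACLE_CODONS[aa] for aa in mutated), "s"
    )
    hits = scan_hamming(frames_mut, QUERY, 11)
    assert hits[0].distance == 1
    with pytest.raises(ValueError):
        scan_hamming(frames, QUERY, -1)


def test_mutated_plant_found_by_hamming_not_exact():
    rec, ann = gen_plasmid_with_motif(400, QUERY, frame=-2, offset=4,
                                      n_mutations=2, seed=11)
    frames = translate_six_frames(str(rec.seq), rec.id)
    assert scan_exact(frames, QUERY) == []
    hits = scan_hamming(frames, QUERY, 2)
    assert [(h.frame, h.offset, h.distance) for h in hits] == [(-2, 4, 2)]


def test_property_scan_same_class_substitution():
    # V->I stays hydrophobic: property distance 0, Hamming distance 1
    window = "I" + QUERY[1:]
    frames = translate_six_frames(
        "".join(_ORACLE_CODONS[aa] for aa in window), "s"
    )
    prop = scan_property(frames, QUERY, max_class_mismatches=0)
    ham = scan_hamming(frames, QUERY, 11)
    assert prop[0].distance == 0
    assert ham[0].distance == 1
    # K->D crosses charge classes: property distance 1
    window2 = QUERY.replace("K", "D", 1)
    frames2 = translate_six_frames(
        "".join(_ORACLE_CODONS[aa] for aa in window2), "s"
    )
    assert scan_property(frames2, QUERY, max_class_mismatches=1)[0].distance == 1


def test_property_alphabet_must_be_total():
    frames = translate_six_frames("ATGGCCGTAAAC", "s")
    with pytest.raises(ValueError, match="missing"):
        scan_property(frames, "MAV", alphabet={"M": "a"})


@pytest.mark.parametrize("mode", ["exact", "hamming", "property"])
def test_scanners_match_bruteforce_oracle(mode, rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        frames = translate_six_frames(seq, "s")
        threshold = 0 if mode == "exact" else 7
        if mode == "exact":
            hits = scan_exact(frames, QUERY)
        elif mode == "hamming":
            hits = scan_hamming(frames, QUERY, threshold)
        else:
            hits = scan_property(frames, QUERY, max_class_mismatches=threshold)
        assert as_tuples(hits) == oracle_scan(frames, QUERY, mode, threshold)


def test_hit_containment(rng):
    seq = "".join(rng.choice(list("ACGT"), size=900))
    frames = translate_six_frames(seq, "s")
    for t in (0, 3, 6):
        exact = {(h.frame, h.offset) for h in scan_exact(frames, QUERY)}
        ham = {(h.frame, h.offset) for h in scan_hamming(frames, QUERY, t)}
        prop = {(h.frame, h.offset)
                for h in scan_property(frames, QUERY, max_class_mismatches=t)}
        assert exact <= ham <= prop


def test_frame_symmetry_under_revcomp(rng):
    seq = "".join(rng.choice(list("ACGT"), size=600))
    fwd = scan_hamming(translate_six_frames(seq, "s"), QUERY, 6)
    rev = scan_hamming(translate_six_frames(revcomp(seq), "s"), QUERY, 6)
    assert sorted((-h.frame, h.offset, h.distance) for h in fwd) == sorted(
        (h.frame, h.offset, h.distance) for h in rev
    )


@given(hst.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=11, max_size=11))
def test_hamming_distance_is_a_metric_to_query(window):
    frames = translate_six_frames(
        "".join(_ORACLE_CODONS[aa] for aa in window), "s"
    )
    hits = scan_hamming(frames, QUERY, 11)
    d = hits[0].distance
    assert 0 <= d <= 11
    assert (d == 0) == (window == QUERY)


def test_rank_candidates_order_and_tiebreak():
    def hit(src, frame, off, d):
        return MotifHit(src, frame, off, "x" * 11, 0, "hamming", d)

    hits = [hit("p1", 1, 0, 3), hit("p1", 2, 5, 5), hit("p1", -1, 2, 2)]
    top = rank_candidates(hits, per_source=2)
    assert [(h.distance, h.frame) for h in top] == [(2, -1), (3, 1)]
    assert rank_candidates([], per_source=3) == []
    ties = [hit("p1", -1, 0, 4), hit("p1", 2, 9, 4), hit("p1", 2, 1, 4)]
    assert [(h.frame, h.offset) for h in rank_candidates(ties, 3)] == [
        (2, 1), (2, 9), (-1, 0),
    ]


# ---------------------------------------------------------------------------
# in-silico PCR


def test_scaffold_primers_give_69bp_on_all_standard_oligos():
    primers = fixtures.scaffold_primers()
    lengths = {
        name: insilico_pcr(seq, primers, name).length
        for name, seq in fixtures.standard_oligos().items()
    }
    assert len(lengths) == 3
    assert set(lengths.values()) == {69}  # spacer-agnostic design


def test_insilico_pcr_minimal_template():
    primers = PrimerPair("ATGCATGCAT", "GGTTCCAAGG")
    template = primers.forward + revcomp(primers.reverse)
    pred = insilico_pcr(template, primers, "mini")
    assert pred.found and pred.length == len(template)
    assert insilico_pcr("ACGT" * 30, primers).found is False
    with pytest.raises(ValueError):
        PrimerPair("ATGU", "ACGT")


def test_insilico_pcr_multiple_products_returns_shortest():
    primers = PrimerPair("ATGCATGCAT", "GGTTCCAAGG")
    unit = primers.forward + "AA" + revcomp(primers.reverse)
    template = primers.forward + "CCCC" + unit + "CCCC"
    pred = insilico_pcr(template, primers)
    assert pred.multiple and pred.length == len(unit)


def test_insilico_pcr_circular_template():
    primers = PrimerPair("ATGCATGCAT", "GGTTCCAAGG")
    unit = primers.forward + "AA" + revcomp(primers.reverse)
    # split the product across the origin
    rotated = unit[15:] + "CCCCCC" + unit[:15]
    assert insilico_pcr(rotated, primers).found is False
    assert insilico_pcr(rotated, primers, circular=True).length == len(unit)


# ---------------------------------------------------------------------------
# peptide mass

_RESIDUE_AVG = {  # independent average residue masses (Da)
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


def test_peptide_mass_glycine_and_hibit():
    assert peptide_average_mass("G") == pytest.approx(75.07, abs=0.01)
    assert round(peptide_average_mass(QUERY) / 1000, 1) == 1.3
    # against an independent residue-mass table
    expected = sum(_RESIDUE_AVG[aa] for aa in QUERY) + 18.02
    assert peptide_average_mass(QUERY) == pytest.approx(expected, abs=0.05)


def test_peptide_mass_additivity_and_errors():
    m = peptide_average_mass
    assert m("VS") == pytest.approx(m("V") + m("S") - 18.02, abs=0.01)
    with pytest.raises(ValueError):
        m("")
    with pytest.raises(ValueError):
        m("VSB")


def test_query_fixture_geometry():
    q = PeptideQuery(QUERY)
    assert len(q) == 11
    assert all(len(s) == 20 for s in fixtures.spacers().values())
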