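"""Six-frame translation, HiBiT-like motif scanning and in-silico PCR.

A split-luciferase lytic assay can pick up cross-reactive luminescence from
plasmid-encoded peptides that resemble the HiBiT tag.  This module provides
the sequence side of that investigation: translate a plasmid in all six
reading frames, slide an 11-residue query window over every frame, and score
windows by exact identity, Hamming distance, or agreement of biochemical
property classes.  It also predicts PCR products from exact primer matches,
which is how the 69-bp scaffold amplicon of the sgRNA qPCR assay is checked
against the printed standard oligonucleotides.

Coordinates are 0-based, half-open, on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

__all__ = [
    "FRAMES",
    "DEFAULT_PROPERTY_CLASSES",
    "PeptideQuery",
    "FrameTranslation",
    "MotifHit",
    "PrimerPair",
    "AmpliconPrediction",
    "translate_six_frames",
    "scan_exact",
    "scan_hamming",
    "scan_property",
    "rank_candidates",
    "insilico_pcr",
    "peptide_average_mass",
]

#: Frame labels in canonical reporting order.
FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default reduced alphabet: five biochemical classes covering all 20
#: standard residues.  Overridable wherever a class map is accepted.
DEFAULT_PROPERTY_CLASSES: dict[str, str] = {}
for _cls, _res in {
    "hydrophobic": "AVLIMFWY",
    "special": "GPC",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
}.items():
    for _aa in _res:
        DEFAULT_PROPERTY_CLASSES[_aa] = _cls


def _revcomp(seq: str) -> str:
    return seq[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class PeptideQuery:
    """An uppercase amino-acid query for the window scanners."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("query peptide must be non-empty")
        bad = set(self.sequence) - set(_AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"query contains non-standard residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """Whole-frame conceptual translation of one strand offset.

    ``peptide`` may contain ``*`` (stop, translation continues through it)
    and ``X`` (codon with a non-ACGT base).  ``nt_starts[i]`` is the
    forward-strand position of the leftmost base of residue ``i``'s codon,
    so reverse-frame coordinates stay on the forward strand.
    """

    source_id: str
    frame: int
    peptide: str
    nt_starts: tuple[int, ...] = field(repr=False)

    def nt_start(self, pep_index: int) -> int:
        return self.nt_starts[pep_index]


@dataclass(frozen=True)
class MotifHit:
    source_id: str
    frame: int
    offset: int  # 0-based peptide window start within the frame
    window: str
    nt_start: int  # leftmost forward-strand base covered by the window
    mode: str  # exact | hamming | property
    distance: int


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(
                    f"{name} primer contains non-ACGT characters: {sorted(bad)}"
                )


@dataclass(frozen=True)
class AmpliconPrediction:
    """Outcome of an in-silico PCR on one template.

    ``found`` is False for an explicit no-product result; ``multiple`` is
    True when more than one product was possible (the shortest is reported).
    """

    template_id: str
    found: bool
    start: int | None = None
    end: int | None = None
    length: int | None = None
    orientation: str | None = None
    multiple: bool = False


def translate_six_frames(seq: str, source_id: str = "seq") -> list[FrameTranslation]:
    """Translate ``seq`` in all six reading frames through stop codons.

    Codons containing any non-ACGT (IUPAC-ambiguous) base translate to
    ``X``; stops are ``*`` and translation continues (this is whole-frame
    translation for motif scanning, not ORF finding).
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt")
    for pos, base in enumerate(seq):
        if base not in _IUPAC_DNA:
            raise ValueError(f"non-IUPAC DNA character {base!r} at position {pos}")

    n = len(seq)
    rc = _revcomp(seq)
    out: list[FrameTranslation] = []
    for frame in FRAMES:
        strand_seq = seq if frame > 0 else rc
        shift = abs(frame) - 1
        residues = []
        starts = []
        for i in range(shift, n - 2, 3):
            codon = strand_seq[i : i + 3]
            residues.append(_CODON_TO_AA.get(codon, "X") if set(codon) <= set("ACGT") else "X")
            # leftmost forward-strand base of this codon
            starts.append(i if frame > 0 else n - i - 3)
        out.append(
            FrameTranslation(
                source_id=source_id,
                frame=frame,
                peptide="".join(residues),
                nt_starts=tuple(starts),
            )
        )
    return out


def _window_nt_start(frame: FrameTranslation, offset: int, k: int) -> int:
    # leftmost forward-strand base covered by residues offset..offset+k-1
    return min(frame.nt_starts[offset], frame.nt_starts[offset + k - 1])


def _scan(
    frames: Iterable[FrameTranslation],
    query: PeptideQuery,
    mode: str,
    distance_fn: Callable[[str], int | None],
    max_distance: int,
) -> list[MotifHit]:
    k = len(query)
    hits = []
    for frame in frames:
        pep = frame.peptide
        for offset in range(len(pep) - k + 1):
            window = pep[offset : offset + k]
            dist = distance_fn(window)
            if dist is None or dist > max_distance:
                continue
            hits.append(
                MotifHit(
                    source_id=frame.source_id,
                    frame=frame.frame,
                    offset=offset,
                    window=window,
                    nt_start=_window_nt_start(frame, offset, k),
                    mode=mode,
                    distance=dist,
                )
            )
    return sorted(hits, key=_hit_key)


def _hit_key(hit: MotifHit):
    return (hit.distance, hit.source_id, FRAMES.index(hit.frame), hit.offset)


def scan_exact(
    frames: Iterable[FrameTranslation], query: PeptideQuery | str
) -> list[MotifHit]:
    """Every window identical to the query (distance 0).

    Windows containing ``*`` or ``X`` never match.
    """
    query = PeptideQuery(query) if isinstance(query, str) else query

    def dist(window: str) -> int | None:
        return 0 if window == query.sequence else None

    return _scan(frames, query, "exact", dist, 0)


def scan_hamming(
    frames: Iterable[FrameTranslation],
    query: PeptideQuery | str,
    max_distance: int = 3,
) -> list[MotifHit]:
    """Windows within ``max_distance`` mismatches of the query.

    Windows containing a stop are excluded; ``X`` counts as a mismatch.
    Hits are sorted by ascending distance, then (source, frame, offset).
    """
    query = PeptideQuery(query) if isinstance(query, str) else query
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")

    def dist(window: str) -> int | None:
        if "*" in window:
            return None
        return sum(a != b for a, b in zip(window, query.sequence))

    return _scan(frames, query, "hamming", dist, max_distance)


def scan_property(
    frames: Iterable[FrameTranslation],
    query: PeptideQuery | str,
    alphabet: dict[str, str] | None = None,
    max_class_mismatches: int = 0,
) -> list[MotifHit]:
    """Windows matching the query under a reduced biochemical alphabet.

    Both window and query are mapped residue-wise through ``alphabet``
    (default: the shipped five-class map); distance is the number of
    positions whose class labels differ.  Windows with ``*`` are excluded;
    ``X`` has no class and counts as a class mismatch, so every Hamming hit
    at a threshold is also a property hit at that threshold.
    """
    query = PeptideQuery(query) if isinstance(query, str) else query
    if max_class_mismatches < 0:
        raise ValueError("max_class_mismatches must be non-negative")
    alphabet = DEFAULT_PROPERTY_CLASSES if alphabet is None else alphabet
    missing = set(_AMINO_ACIDS) - set(alphabet)
    if missing:
        raise ValueError(f"property alphabet missing residues: {sorted(missing)}")
    qclasses = [alphabet[aa] for aa in query.sequence]

    def dist(window: str) -> int | None:
        if "*" in window:
            return None
        return sum(alphabet.get(aa) != qc for aa, qc in zip(window, qclasses))

    return _scan(frames, query, "property", dist, max_class_mismatches)


def rank_candidates(hits: Sequence[MotifHit], per_source: int = 5) -> list[MotifHit]:
    """Keep the ``per_source`` best hits per source id.

    Ordering and tie-break: ascending distance, then frame in the order
    +1,+2,+3,-1,-2,-3, then offset.
    """
    if per_source < 1:
        raise ValueError("per_source must be >= 1")
    by_source: dict[str, list[MotifHit]] = {}
    for hit in sorted(hits, key=_hit_key):
        kept = by_source.setdefault(hit.source_id, [])
        if len(kept) < per_source:
            kept.append(hit)
    return [h for kept in by_source.values() for h in kept]


def insilico_pcr(
    template: str,
    primers: PrimerPair,
    template_id: str = "template",
    circular: bool = False,
) -> AmpliconPrediction:
    """Predict the PCR product of an exact-match primer pair on a template.

    One primer must match the forward strand and the reverse complement of
    the other must occur downstream; the product runs from the 5' end of
    the upstream match through the 3' end of the downstream match.  If more
    than one product is possible the shortest is returned with
    ``multiple=True``; if none, ``found=False``.  ``circular=True`` scans
    the template concatenated with its first (primer length - 1) bases so
    origin-spanning products are seen.
    """
    template = template.upper()
    bad = set(template) - set("ACGT")
    if bad:
        raise ValueError(f"template contains non-ACGT characters: {sorted(bad)}")

    n = len(template)
    search = template
    if circular:
        wrap = max(len(primers.forward), len(primers.reverse)) - 1
        search = template + template[:wrap]

    def occurrences(sub: str) -> list[int]:
        out, i = [], search.find(sub)
        while i != -1:
            if i < n:  # anchor the upstream primer inside the template proper
                out.append(i)
            i = search.find(sub, i + 1)
        return out

    products: list[tuple[int, int, str]] = []  # (start, end, orientation)
    for up, down, orientation in (
        (primers.forward, _revcomp(primers.reverse), "forward-top/reverse-bottom"),
        (primers.reverse, _revcomp(primers.forward), "reverse-top/forward-bottom"),
    ):
        for i in occurrences(up):
            j = search.find(down, i + len(up))
            if j != -1:
                products.append((i, j + len(down), orientation))

    if not products:
        return AmpliconPrediction(template_id=template_id, found=False)
    products.sort(key=lambda p: (p[1] - p[0], p[0]))
    start, end, orientation = products[0]
    return AmpliconPrediction(
        template_id=template_id,
        found=True,
        start=start,
        end=end,
        length=end - start,
        orientation=orientation,
        multiple=len(products) > 1,
    )


def peptide_average_mass(peptide: str) -> float:
    """Average (isotope-weighted) mass of a peptide in daltons.

    Sum of average residue masses plus one water; e.g. the 11-residue HiBiT
    tag comes to ~1.3 kDa.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - set(_AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return float(molecular_weight(Seq(peptide), seq_type="protein", monoisotopic=False))
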