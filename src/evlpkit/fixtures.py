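"""Bundled assay sequences.

The package ships the published components of the spacer-agnostic sgRNA
scaffold qPCR assay: the scaffold-specific primer pair, the three
cDNA-sense standard oligonucleotides (one per sgRNA target: HEK2, HEK3 and
CFTR exon 11), the four 20-nt spacers, and the 11-residue HiBiT peptide
used as the default motif-scan query.
"""

from __future__ import annotations

from importlib import resources

from Bio import SeqIO

from .sequence_tools import PrimerPair

#: HiBiT peptide, the small fragment of the split NanoBiT luciferase.
HIBIT_PEPTIDE = "VSGWRLFKKIS"

_FASTA = "scaffold_assay.fasta"


def _records() -> dict[str, SeqIO.SeqRecord]:
    path = resources.files("evlpkit.data").joinpath(_FASTA)
    with path.open() as handle:
        return {rec.id: rec for rec in SeqIO.parse(handle, "fasta")}


def fixture_fasta_path() -> str:
    """Filesystem path of the bundled FASTA (for CLI use)."""
    return str(resources.files("evlpkit.data").joinpath(_FASTA))


def scaffold_primers() -> PrimerPair:
    """The scaffold-specific qPCR primer pair (binds every sgRNA cDNA)."""
    recs = _records()
    return PrimerPair(
        forward=str(recs["qPCR_sgRNA_fw"].seq),
        reverse=str(recs["qPCR_sgRNA_rv"].seq),
    )


def standard_oligos() -> dict[str, str]:
    """The three cDNA-sense standard oligonucleotides, keyed by name."""
    recs = _records()
    return {
        name: str(rec.seq)
        for name, rec in recs.items()
        if "type=standard_oligo" in rec.description
    }


def spacers() -> dict[str, str]:
    """The 20-nt spacer sequences, keyed by target name."""
    recs = _records()
    return {
        name.removeprefix("spacer_"): str(rec.seq)
        for name, rec in recs.items()
        if "type=spacer" in rec.description
    }
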