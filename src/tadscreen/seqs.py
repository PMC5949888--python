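"""Shared nucleotide/peptide utilities.

Small primitives used across the simulator, read processing and feature
stages: alphabet validation, translation of library inserts, edit distance
and end-to-end alignment identity.
"""

from __future__ import annotations

import edlib
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGT")
STOP_CODONS = {"TAA", "TAG", "TGA"}
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Back-translation table: one fixed, frequent codon per amino acid.
#: Codon identity is irrelevant downstream except for stop codons, so a
#: deterministic single-codon table keeps simulated libraries reproducible.
BACKTRANSLATION_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


def check_dna(seq: str) -> str:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise InvalidAlphabetError(f"non-ACGT characters in sequence: {bad}")
    return seq


def check_peptide(peptide: str) -> str:
    if not set(peptide) <= STANDARD_AA:
        bad = sorted(set(peptide) - STANDARD_AA)
        raise InvalidAlphabetError(f"non-standard amino acids: {bad}")
    return peptide


def reverse_complement(seq: str) -> str:
    return str(Seq(check_dna(seq)).reverse_complement())


def translate_insert(dna: str) -> tuple[str, bool]:
    """Translate a library insert to its peptide.

    Standard genetic code, truncated at the first stop codon. Inserts whose
    length is not a multiple of 3 have their trailing 1-2 nt dropped (flagged
    upstream in QC). Returns ``(peptide, starts_with_stop)`` where the flag
    is true iff the first codon is TAA/TAG/TGA.
    """
    check_dna(dna)
    trimmed = dna[: len(dna) - len(dna) % 3]
    starts_with_stop = trimmed[:3] in STOP_CODONS
    peptide = str(Seq(trimmed).translate(to_stop=True))
    return peptide, starts_with_stop


def back_translate(peptide: str) -> str:
    """Deterministic back-translation using the fixed codon table."""
    check_peptide(peptide)
    return "".join(BACKTRANSLATION_TABLE[aa] for aa in peptide)


def levenshtein(a: str, b: str) -> int:
    """Edit distance: substitutions, insertions and deletions all cost 1."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _make_aligner() -> PairwiseAligner:
    # Global end-to-end; match +1, mismatch -1, gap -2 (terminal gaps
    # penalised like internal ones so identity counts all columns).
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner

_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global end-to-end alignment.

    Identity = matching columns / total alignment columns, terminal gaps
    included. Among co-optimal alignments the aligner's first path is used.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length
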