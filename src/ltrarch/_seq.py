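"""Low-level sequence primitives shared across the package.

Coordinates are 0-based half-open on the forward strand unless a function
says otherwise.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# codon -> amino acid (stop = '*'); anything ambiguous -> 'X'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

# amino acid -> sorted list of synonymous codons
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a forward-frame DNA string; partial 3' codons are dropped.

    Codons containing characters outside ACGT become 'X'; stops become '*'.
    """
    out = []
    for i in range(0, len(dna) - 2, 3):
        out.append(CODON_TABLE.get(dna[i : i + 3].upper(), "X"))
    return "".join(out)


def frame_to_genomic(frame: int, aa_offset: int, aa_len: int, seq_len: int) -> tuple[int, int]:
    """Map an amino-acid window in a six-frame translation to forward-strand
    coordinates.

    ``frame`` follows the +1..+3 / -1..-3 convention; minus frames index into
    the reverse complement.
    """
    if frame > 0:
        start = (frame - 1) + 3 * aa_offset
        return start, start + 3 * aa_len
    rc_start = (-frame - 1) + 3 * aa_offset
    rc_end = rc_start + 3 * aa_len
    return seq_len - rc_end, seq_len - rc_start
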