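"""Sequence alphabet utilities shared across the pipeline.

Reads and genomes are handled internally as uppercase DNA (``ACGTN``);
RNA-facing output (mature miRNAs, hairpin sequences, duplexes) converts
T→U on the way out. Both conversions are idempotent, so normalising an
already-normalised sequence is a no-op.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_TO_DNA = str.maketrans("Uu", "Tt")
_TO_RNA = str.maketrans("Tt", "Uu")

VALID_DNA = frozenset("ACGTN")
VALID_RNA = frozenset("ACGUN")


def normalize_dna(seq: str) -> str:
    """Uppercase and convert U→T. Idempotent."""
    return seq.translate(_TO_DNA).upper()


def to_rna(seq: str) -> str:
    """Uppercase and convert T→U. Idempotent."""
    return seq.translate(_TO_RNA).upper()


def revcomp(seq: str) -> str:
    """Reverse complement, as DNA (input may be DNA or RNA; N maps to N)."""
    return normalize_dna(seq).translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string, returned as RNA."""
    return to_rna(revcomp(normalize_dna(seq)))


def validate_alphabet(seq: str, *, rna: bool = False, allow_n: bool = True) -> None:
    alphabet = VALID_RNA if rna else VALID_DNA
    if not allow_n:
        alphabet = alphabet - {"N"}
    bad = set(seq.upper()) - alphabet
    if bad:
        kind = "RNA" if rna else "DNA"
        raise ValueError(f"invalid {kind} characters: {sorted(bad)!r}")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
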