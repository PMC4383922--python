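"""Nucleotide-sequence normalization helpers.

Every sequence entering the toolkit — miRBase-style FASTA, RefSeq-derived
3'-UTRs, raw user submissions — is normalized once at ingest to the uppercase
RNA alphabet {A,C,G,U}; DNA input (T) is accepted and transcribed.
Normalization is idempotent.
"""

from __future__ import annotations

from .errors import AlphabetError

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(raw: str, *, name: str = "sequence") -> str:
    """Strip whitespace, fold case, transcribe T->U and verify the alphabet.

    Raises AlphabetError naming the 1-based position of the first offending
    character.
    """
    seq = "".join(raw.split()).upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(
                f"{name}: invalid character {ch!r} at position {pos}; "
                "expected A/C/G/U (T accepted as U)"
            )
    return seq


def revcomp_rna(seq: str) -> str:
    """Reverse complement of a normalized RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
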