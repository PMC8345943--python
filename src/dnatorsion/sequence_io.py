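"""Reading, generating and editing the nucleotide sequence of chain 1.

The mechanical duplex is parameterized entirely by the base sequence of its
first strand; the second strand is always the Watson–Crick complement.  This
module owns that sequence: FASTA input/output, complementation, homopolymer
block substitution (the 40A/40T/40G/40C/100A experiments) and seeded random
sequence generation with controllable GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
# lowercase and RNA spellings are normalized on input
_NORMALIZE = str.maketrans("acgtuU", "ACGTTT")


class SequenceError(ValueError):
    """Raised for malformed or unsupported nucleotide input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase DNA sequence over {A, C, G, T} with an optional id.

    ``symbols`` is stored as a plain string; ``len()`` gives the number of
    base pairs n of the duplex the sequence parameterizes.
    """

    symbols: str
    id: str = field(default="seq")

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise SequenceError("sequence must contain at least one base")
        for pos, sym in enumerate(self.symbols, start=1):
            if sym not in _COMPLEMENT:
                raise SequenceError(
                    f"invalid symbol {sym!r} at position {pos} "
                    "(alphabet is A, C, G, T after normalization)"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]

    @property
    def gc_fraction(self) -> float:
        s = self.symbols
        return (s.count("G") + s.count("C")) / len(s)

    def complement(self) -> "NucleotideSequence":
        """Base-wise Watson–Crick complement (not reversed: pair i faces pair i)."""
        return NucleotideSequence(
            "".join(_COMPLEMENT[b] for b in self.symbols), id=f"{self.id}_complement"
        )


def normalize(raw: str) -> str:
    """Uppercase a raw sequence string and map U to T; reject anything else.

    The error message names the 1-based position of the first offending
    symbol, since the parameter table has no entry for ambiguity codes.
    """
    out = raw.translate(_NORMALIZE)
    for pos, sym in enumerate(out, start=1):
        if sym not in _COMPLEMENT:
            raise SequenceError(f"invalid symbol {raw[pos - 1]!r} at position {pos}")
    return out


def complement(base: str) -> str:
    """Watson–Crick complement of a single base symbol (A<->T, G<->C)."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise SequenceError(f"invalid base symbol {base!r}") from None


def read_fasta(path) -> NucleotideSequence:
    """Read the first record of a FASTA file as a :class:`NucleotideSequence`.

    Lowercase letters are uppercased and U is mapped to T.  Multi-record
    files are not concatenated: the model is defined on a single duplex, so
    only the first record is used.
    """
    records = SeqIO.parse(str(path), "fasta")
    try:
        rec = next(records)
    except StopIteration:
        raise SequenceError(f"no FASTA record found in {path}") from None
    if len(rec.seq) == 0:
        raise SequenceError(f"first FASTA record in {path} is empty")
    return NucleotideSequence(normalize(str(rec.seq)), id=rec.id)


def write_fasta(seq: NucleotideSequence, path) -> None:
    SeqIO.write([SeqRecord(Seq(seq.symbols), id=seq.id, description="")], str(path), "fasta")


def substitute_region(
    seq: NucleotideSequence, start: int, length: int, base: str
) -> NucleotideSequence:
    """Replace a block of the sequence by a homopolymer run of ``base``.

    ``start`` is 1-based and the block covers positions
    ``start .. start+length-1`` inclusive; a new sequence is returned and the
    record id is extended with an edit descriptor such as ``40A@471``.
    A zero-length edit returns the sequence unchanged (same symbols, same id).
    """
    if base not in _COMPLEMENT:
        raise SequenceError(f"invalid base symbol {base!r}")
    if length < 0:
        raise SequenceError("substitution length must be non-negative")
    if length == 0:
        return seq
    n = len(seq)
    if start < 1 or start + length - 1 > n:
        raise SequenceError(
            f"substitution [{start}, {start + length - 1}] out of bounds for n={n}"
        )
    s = seq.symbols
    edited = s[: start - 1] + base * length + s[start - 1 + length :]
    return NucleotideSequence(edited, id=f"{seq.id}_{length}{base}@{start}")


def centered_block(n: int, length: int) -> int:
    """1-based start of a length-``length`` block centered in an n-mer.

    For n=980 this places the 40-base block at positions 471–510 and the
    100-base block at 441–540, i.e. "the middle of the molecule".
    """
    if length > n:
        raise SequenceError(f"block of {length} does not fit in n={n}")
    return (n - length) // 2 + 1


def random_sequence(
    n: int, gc_fraction: float = 0.5, seed: int | None = None, id: str | None = None
) -> NucleotideSequence:
    """Draw an i.i.d. sequence with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2.

    Identical (n, gc_fraction, seed) always yield the identical sequence.
    This is the synthetic stand-in used when no real gene sequence is
    supplied.
    """
    if n < 1:
        raise SequenceError("n must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise SequenceError(f"gc_fraction must lie in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(np.array(list("ATGC")), size=n, p=[at, at, gc, gc])
    label = id if id is not None else f"synthetic_n{n}_gc{gc_fraction:g}_seed{seed}"
    return NucleotideSequence("".join(draws), id=label)
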