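"""CDS validation, codon decomposition and observed dinucleotide proportions.

A :class:`CodingSequence` is an in-frame coding sequence: length divisible by
three, no internal stop codons, at most one trailing stop codon (trimmed).
Codons containing ambiguity codes (N, R, Y, ...) are kept in place to preserve
the reading frame but are masked out of all counts, along with both bridge
pairs touching them.

:func:`observed_proportions` bins the sequence's dinucleotides by synonymous
unit — amino acid for the two within-codon positions, ordered amino-acid pair
for the bridge — producing the observed counterpart of the codon table's
expected proportions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .genetic_code import (
    NUCLEOTIDES,
    FramePosition,
    GeneticCode,
    normalize_nucleotides,
    standard_code,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "ObservedProportionTable",
    "ValidationError",
    "parse_fasta",
    "observed_proportions",
]

# IUPAC nucleotide ambiguity codes (beyond ACGU) tolerated in input.
_AMBIGUITY = set("RYSWKMBDHVN")


class ValidationError(ValueError):
    """A record failed CDS validation; the message states the reason."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated, RNA-normalized coding sequence.

    Attributes
    ----------
    id : record identifier (FASTA header token)
    nts : nucleotide string, RNA alphabet, trailing stop trimmed
    codons : ordered codon list (may include ambiguity-containing codons)
    aa_seq : translation; ambiguous codons translate to 'X'
    clean : per-codon flag, False where the codon contains ambiguity codes
    """

    id: str
    nts: str
    codons: tuple
    aa_seq: str
    clean: tuple
    code: GeneticCode = field(default_factory=standard_code, compare=False)

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def pairs(self) -> tuple:
        """Ordered adjacent amino-acid pairs (one per codon bridge)."""
        return tuple(zip(self.aa_seq[:-1], self.aa_seq[1:]))

    @classmethod
    def from_string(
        cls,
        record_id: str,
        sequence: str,
        code: GeneticCode | None = None,
        strict: bool = True,
    ) -> "CodingSequence":
        """Validate and decompose a raw nucleotide string.

        Raises :class:`ValidationError` for: length not divisible by 3,
        non-IUPAC characters, empty sequence, or (strict mode) an internal
        stop codon.  With ``strict=False`` the sequence is truncated at the
        first internal stop instead.  A single trailing stop is trimmed.
        """
        code = code or standard_code()
        nts = normalize_nucleotides(sequence.strip())
        if not nts:
            raise ValidationError(f"{record_id}: empty sequence")
        bad = set(nts) - set(NUCLEOTIDES) - _AMBIGUITY
        if bad:
            raise ValidationError(
                f"{record_id}: non-IUPAC characters {sorted(bad)}"
            )
        if len(nts) % 3:
            raise ValidationError(
                f"{record_id}: length {len(nts)} not divisible by 3"
            )
        codons = [nts[i : i + 3] for i in range(0, len(nts), 3)]
        if codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        if not codons:
            raise ValidationError(f"{record_id}: no sense codons")
        aa_chars = []
        clean = []
        for idx, codon in enumerate(codons):
            if set(codon) <= set(NUCLEOTIDES):
                if codon in code.stop_codons:
                    if strict:
                        # 1-based codon index for the user-facing message
                        raise ValidationError(
                            f"{record_id}: internal stop codon at codon {idx + 1}"
                        )
                    logger.warning(
                        "%s: truncating at internal stop codon %d", record_id, idx + 1
                    )
                    codons = codons[:idx]
                    break
                aa_chars.append(code.translate_codon(codon))
                clean.append(True)
            else:
                logger.warning(
                    "%s: codon %d (%s) contains ambiguity codes; "
                    "excluded from counts",
                    record_id,
                    idx + 1,
                    codon,
                )
                aa_chars.append("X")
                clean.append(False)
        if not aa_chars:
            raise ValidationError(f"{record_id}: no sense codons")
        codons = codons[: len(aa_chars)]
        return cls(
            id=record_id,
            nts="".join(codons),
            codons=tuple(codons),
            aa_seq="".join(aa_chars),
            clean=tuple(clean),
            code=code,
        )

    def with_codons(self, codons: Iterable[str]) -> "CodingSequence":
        """Same protein, different (synonymous) codon realization."""
        codons = tuple(codons)
        return CodingSequence(
            id=self.id,
            nts="".join(codons),
            codons=codons,
            aa_seq=self.aa_seq,
            clean=self.clean,
            code=self.code,
        )


def parse_fasta(
    path: str | Path,
    code: GeneticCode | None = None,
    strict: bool = True,
    on_error: str = "raise",
) -> list:
    """Read a (multi-record) FASTA of coding sequences.

    ``on_error='raise'`` aborts on the first invalid record; ``'skip'``
    logs the reason and drops the record. ``strict`` controls internal-stop
    handling per record (abort vs truncate).
    """
    if on_error not in {"raise", "skip"}:
        raise ValueError("on_error must be 'raise' or 'skip'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        try:
            out.append(
                CodingSequence.from_string(rec.id, str(rec.seq), code, strict=strict)
            )
        except ValidationError as exc:
            if on_error == "raise":
                raise
            logger.warning("skipping record: %s", exc)
    if not out:
        raise ValidationError(f"{path}: no valid coding sequences")
    return out


@dataclass
class ObservedProportionTable:
    """Observed dinucleotide proportions at one frame position.

    ``counts[i]`` is the number of countable occurrences of unit *i* (codons
    for pos1/pos2, adjacent pairs for the bridge); ``dinuc_counts[i][j]``
    the occurrences realising dinucleotide *j*. ``proportion(i, j)`` is the
    empirical o, and ``total`` the grand count over units.
    """

    position: FramePosition
    counts: dict
    dinuc_counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, unit, dinuc: str) -> float:
        n = self.counts.get(unit, 0)
        if n == 0:
            raise KeyError(f"unit {unit!r} not present at {self.position}")
        return self.dinuc_counts[unit].get(dinuc, 0) / n

    def merge(self, other: "ObservedProportionTable") -> "ObservedProportionTable":
        """Pool counts across records (for pooled-mode metrics)."""
        if other.position is not self.position:
            raise ValueError("cannot merge tables for different frame positions")
        counts = Counter(self.counts)
        counts.update(other.counts)
        dinucs = {u: Counter(c) for u, c in self.dinuc_counts.items()}
        for u, c in other.dinuc_counts.items():
            dinucs.setdefault(u, Counter()).update(c)
        return ObservedProportionTable(
            position=self.position,
            counts=dict(counts),
            dinuc_counts={u: dict(c) for u, c in dinucs.items()},
        )


def observed_proportions(
    seq: CodingSequence, pos: FramePosition | str
) -> ObservedProportionTable:
    """Count the dinucleotides of `seq` at `pos`, binned by synonymous unit.

    Ambiguity-containing codons and the bridge pairs touching them are
    excluded from the counts.
    """
    pos = FramePosition.coerce(pos)
    counts: Counter = Counter()
    dinuc_counts: dict = {}
    if pos is FramePosition.BRIDGE:
        for t in range(len(seq.codons) - 1):
            if not (seq.clean[t] and seq.clean[t + 1]):
                continue
            unit = (seq.aa_seq[t], seq.aa_seq[t + 1])
            dinuc = seq.codons[t][2] + seq.codons[t + 1][0]
            counts[unit] += 1
            dinuc_counts.setdefault(unit, Counter())[dinuc] += 1
    else:
        start = 0 if pos is FramePosition.POS1 else 1
        for t, codon in enumerate(seq.codons):
            if not seq.clean[t]:
                continue
            unit = seq.aa_seq[t]
            counts[unit] += 1
            dinuc_counts.setdefault(unit, Counter())[codon[start : start + 2]] += 1
    return ObservedProportionTable(
        position=pos,
        counts=dict(counts),
        dinuc_counts={u: dict(c) for u, c in dinuc_counts.items()},
    )
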