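"""Codon-table combinatorics for synonymous dinucleotide usage.

A coding sequence exposes dinucleotides at three frame positions: within a
codon at nucleotides (1,2) ("pos1") and (2,3) ("pos2"), and bridging two
adjacent codons at (3, next-1) ("bridge").  For a fixed amino acid (pos1/pos2)
or ordered amino-acid pair (bridge), the set of dinucleotides reachable by
synonymous codon changes defines the *synonymous dinucleotides*, and under the
null hypothesis of equal synonymous codon usage each one has a fixed expected
proportion ``e``.  This module derives those expectations, the per-unit
maximum over/under-representation ratios ``1/e``, and the enumeration of
*informative* (dinucleotide, position) combinations — the cells where some
unit has ``0 < e < 1`` so the usage statistic can deviate from 1.

Everything is computed from an injected codon table (standard NCBI table 1 by
default, via Biopython), never hard-wired, so alternative translation tables
drop in without touching the math.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Union

from Bio.Data import CodonTable

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "AMINO_ACIDS",
    "FramePosition",
    "GeneticCode",
    "ExpectedProportionTable",
    "normalize_dinucleotide",
    "normalize_nucleotides",
    "standard_code",
]

NUCLEOTIDES = "ACGU"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

# Unit of synonymous variation: a single amino acid (pos1/pos2) or an ordered
# amino-acid pair (bridge).
Unit = Union[str, tuple]


class FramePosition(str, Enum):
    """Frame position of a dinucleotide relative to the codon structure."""

    POS1 = "pos1"  # codon nucleotides (1, 2)
    POS2 = "pos2"  # codon nucleotides (2, 3)
    BRIDGE = "bridge"  # codon nucleotide 3 + first nucleotide of next codon

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "FramePosition | str") -> "FramePosition":
        if isinstance(value, cls):
            return value
        token = str(value).strip().lower()
        aliases = {"1": "pos1", "2": "pos2", "p1": "pos1", "p2": "pos2", "br": "bridge"}
        token = aliases.get(token, token)
        try:
            return cls(token)
        except ValueError:
            raise ValueError(
                f"unknown frame position {value!r}; expected pos1, pos2 or bridge"
            ) from None


def normalize_nucleotides(seq: str) -> str:
    """Uppercase and convert DNA (T) to the RNA alphabet used throughout."""
    return seq.upper().replace("T", "U")


def normalize_dinucleotide(token: str) -> str:
    """Accept 'CG', 'CpG', 'cg', DNA 'TG' etc.; return the RNA form, e.g. 'CG'."""
    cleaned = normalize_nucleotides(token.replace("p", "").replace("P", ""))
    if len(cleaned) != 2 or any(c not in NUCLEOTIDES for c in cleaned):
        raise ValueError(f"not a dinucleotide: {token!r}")
    return cleaned


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus the synonymous-set combinatorics derived from it.

    Parameters
    ----------
    codon_to_aa
        Map of the sense codons (RNA alphabet) to one-letter amino acids.
    stop_codons
        The stop codons of the table (excluded from all synonymous sets).
    name
        Human-readable table name, reported by the CLI version string.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset
    name: str = "Standard"
    aa_to_codons: Mapping[str, tuple] = field(init=False)

    def __post_init__(self) -> None:
        inverse: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
                raise ValueError(f"invalid codon {codon!r}")
            if aa == STOP:
                raise ValueError("stop codons belong in stop_codons, not codon_to_aa")
            inverse.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "aa_to_codons", {aa: tuple(cs) for aa, cs in inverse.items()}
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_ncbi_table(cls, table_id: int = 1) -> "GeneticCode":
        """Build from an NCBI translation table (Biopython's registry)."""
        table = CodonTable.unambiguous_rna_by_id[table_id]
        return cls(
            codon_to_aa=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
            name=table.names[0] if table.names else f"table {table_id}",
        )

    # -- basic accessors --------------------------------------------------

    @property
    def amino_acids(self) -> tuple:
        return tuple(sorted(self.aa_to_codons))

    def codons_for(self, aa: str) -> tuple:
        try:
            return self.aa_to_codons[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid {aa!r}") from None

    def translate_codon(self, codon: str) -> str:
        """Translate one sense codon; stop codons return '*'."""
        codon = normalize_nucleotides(codon)
        if codon in self.stop_codons:
            return STOP
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise ValueError(f"untranslatable codon {codon!r}") from None

    # -- marginal nucleotide profiles under equal synonymous usage --------

    def nt_profile(self, aa: str, slot: int) -> dict:
        """P(nucleotide at codon slot 0/1/2) with synonyms equally weighted."""
        codons = self.codons_for(aa)
        prof = {nt: 0.0 for nt in NUCLEOTIDES}
        for codon in codons:
            prof[codon[slot]] += 1.0 / len(codons)
        return prof

    # -- expected proportions ---------------------------------------------

    def expected_proportion(
        self, unit: Unit, dinuc: str, pos: "FramePosition | str"
    ) -> float:
        """Expected proportion ``e`` of `dinuc` at `pos` for `unit`.

        For pos1/pos2 the unit is one amino acid and ``e`` is the fraction of
        its equally-weighted synonymous codons realising the dinucleotide at
        that position.  For the bridge the unit is an ordered amino-acid pair
        (a, b) and ``e`` factorises as P(third nt of a) x P(first nt of b)
        under uniform codon usage — equivalently the fraction of all
        synonymous codon pairs realising the dinucleotide.
        """
        pos = FramePosition.coerce(pos)
        dinuc = normalize_dinucleotide(dinuc)
        if pos is FramePosition.BRIDGE:
            if not (isinstance(unit, tuple) and len(unit) == 2):
                raise ValueError("bridge units are ordered amino-acid pairs (a, b)")
            a, b = unit
            return self.nt_profile(a, 2)[dinuc[0]] * self.nt_profile(b, 0)[dinuc[1]]
        if not isinstance(unit, str) or len(unit) != 1:
            raise ValueError(f"pos1/pos2 units are single amino acids, got {unit!r}")
        codons = self.codons_for(unit)
        start = 0 if pos is FramePosition.POS1 else 1
        hits = sum(1 for c in codons if c[start : start + 2] == dinuc)
        return hits / len(codons)

    def max_ratio_weight(self, unit: Unit, dinuc: str, pos: "FramePosition | str") -> float:
        """``1/e``: the maximal observed/expected ratio a unit can attain,
        reached when every synonymous slot of the unit uses the dinucleotide.
        """
        e = self.expected_proportion(unit, dinuc, pos)
        if e == 0.0:
            raise ValueError(
                f"{unit!r} cannot realise {dinuc} at {FramePosition.coerce(pos)}; "
                "the maximum ratio is undefined"
            )
        return 1.0 / e

    # -- informative-combination enumeration ------------------------------

    def units_for(self, pos: "FramePosition | str") -> tuple:
        """All units at a frame position: amino acids, or ordered pairs."""
        pos = FramePosition.coerce(pos)
        if pos is FramePosition.BRIDGE:
            return tuple(itertools.product(self.amino_acids, repeat=2))
        return self.amino_acids

    def is_informative(self, dinuc: str, pos: "FramePosition | str") -> bool:
        """True iff some unit has 0 < e < 1, so usage can deviate from 1."""
        pos = FramePosition.coerce(pos)
        dinuc = normalize_dinucleotide(dinuc)
        return any(
            0.0 < self.expected_proportion(u, dinuc, pos) < 1.0
            for u in self.units_for(pos)
        )

    def informative_combinations(self) -> frozenset:
        """The set of (dinucleotide, FramePosition) cells carrying signal."""
        return frozenset(
            (d, p)
            for p in FramePosition
            for d in DINUCLEOTIDES
            if self.is_informative(d, p)
        )

    def to_json(self) -> str:
        """Serialize the codon table for debugging."""
        return json.dumps(
            {
                "name": self.name,
                "codon_to_aa": dict(self.codon_to_aa),
                "stop_codons": sorted(self.stop_codons),
            },
            indent=2,
        )


class ExpectedProportionTable:
    """Dense cache of e(unit, dinucleotide, position) for one genetic code.

    Thin convenience over :meth:`GeneticCode.expected_proportion`; entries are
    ratios of small integers derived by enumerating synonymous codons.
    """

    def __init__(self, code: GeneticCode):
        self.code = code
        self.entries: dict = {}
        for pos in FramePosition:
            for unit in code.units_for(pos):
                for dinuc in DINUCLEOTIDES:
                    self.entries[(unit, dinuc, pos)] = code.expected_proportion(
                        unit, dinuc, pos
                    )

    def get(self, unit: Unit, dinuc: str, pos: "FramePosition | str") -> float:
        return self.entries[
            (unit, normalize_dinucleotide(dinuc), FramePosition.coerce(pos))
        ]

    def row(self, unit: Unit, pos: "FramePosition | str") -> dict:
        pos = FramePosition.coerce(pos)
        return {d: self.entries[(unit, d, pos)] for d in DINUCLEOTIDES}


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (shared instance)."""
    return GeneticCode.from_ncbi_table(1)
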