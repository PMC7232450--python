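"""Dinucleotide representation metrics for coding sequences.

Four metrics are implemented:

* **SDU** — synonymous dinucleotide usage: the weighted arithmetic mean over
  synonymous units (amino acids, or ordered amino-acid pairs at the bridge)
  of the ratio between the observed proportion o of a dinucleotide and its
  expectation e under equal synonymous codon usage, weighted by unit
  abundance n_i::

      SDU(j, h) = sum_i n_i * o_i / e_i  /  N,   N = sum_i n_i

  SDU = 1 means agreement with the null of equal synonymous codon usage,
  0 means the dinucleotide is synonymously absent, >1 over-representation.

* **sdu_max** — the supremum of SDU over synonymous recodings,
  ``sum_i n_i / e_i / N``, attained when every synonymous slot carries the
  dinucleotide.

* **RSDU** — SDU normalised by sdu_max, in [0, 1]; comparable across
  dinucleotides and positions.

* **RDA** — relative dinucleotide abundance, the classical odds ratio
  f(XY) / (f(X) f(Y)); whole-sequence, or per frame position with
  slot-specific mononucleotide marginals.

* **RSCU** — relative synonymous codon usage, count(c) * m / sum over the
  amino acid's codons, the standard codon-bias companion statistic.

Units with e = 0 cannot exhibit the dinucleotide synonymously and are
excluded from both the sum and N (otherwise SDU < 1 under the null).  Units
with e = 1 contribute a ratio of exactly 1; they are included by default and
can be dropped via ``include_e1_units=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genetic_code import (
    DINUCLEOTIDES,
    NUCLEOTIDES,
    FramePosition,
    GeneticCode,
    normalize_dinucleotide,
    standard_code,
)
from .sequences import CodingSequence, ObservedProportionTable, observed_proportions

__all__ = [
    "UndefinedMetricError",
    "MetricResult",
    "RscuTable",
    "sdu",
    "sdu_max",
    "rsdu",
    "rda",
    "rscu",
    "sdu_from_observed",
    "sdu_max_from_observed",
    "metric_table",
]


class UndefinedMetricError(ValueError):
    """No synonymous unit in the sequence can carry the requested dinucleotide."""


# ---------------------------------------------------------------------------
# SDU family
# ---------------------------------------------------------------------------


def _included_units(
    obs: ObservedProportionTable,
    code: GeneticCode,
    dinuc: str,
    include_e1_units: bool,
):
    """Yield (n_i, o_i, e_i) for units passing the inclusion rule (e > 0)."""
    for unit, n in obs.counts.items():
        e = code.expected_proportion(unit, dinuc, obs.position)
        if e == 0.0:
            continue
        if e == 1.0 and not include_e1_units:
            continue
        yield n, obs.proportion(unit, dinuc), e


def sdu_from_observed(
    obs: ObservedProportionTable,
    dinuc: str,
    code: GeneticCode | None = None,
    include_e1_units: bool = True,
) -> float:
    """SDU from a pre-counted (possibly pooled) observed-proportion table."""
    code = code or standard_code()
    dinuc = normalize_dinucleotide(dinuc)
    total = 0.0
    weight = 0
    for n, o, e in _included_units(obs, code, dinuc, include_e1_units):
        total += n * o / e
        weight += n
    if weight == 0:
        raise UndefinedMetricError(
            f"no unit present can realise {dinuc} at {obs.position}"
        )
    return total / weight


def sdu_max_from_observed(
    obs: ObservedProportionTable,
    dinuc: str,
    code: GeneticCode | None = None,
    include_e1_units: bool = True,
) -> float:
    """Maximum attainable SDU, over the same included units as the SDU."""
    code = code or standard_code()
    dinuc = normalize_dinucleotide(dinuc)
    total = 0.0
    weight = 0
    for n, _o, e in _included_units(obs, code, dinuc, include_e1_units):
        total += n / e
        weight += n
    if weight == 0:
        raise UndefinedMetricError(
            f"no unit present can realise {dinuc} at {obs.position}"
        )
    return total / weight


def sdu(
    seq: CodingSequence,
    dinuc: str,
    pos: FramePosition | str,
    include_e1_units: bool = True,
) -> float:
    """Synonymous dinucleotide usage of `dinuc` at frame position `pos`."""
    obs = observed_proportions(seq, pos)
    return sdu_from_observed(obs, dinuc, seq.code, include_e1_units)


def sdu_max(
    seq: CodingSequence,
    dinuc: str,
    pos: FramePosition | str,
    include_e1_units: bool = True,
) -> float:
    """Supremum of the SDU over all synonymous recodings of `seq`."""
    obs = observed_proportions(seq, pos)
    return sdu_max_from_observed(obs, dinuc, seq.code, include_e1_units)


def rsdu(
    seq: CodingSequence,
    dinuc: str,
    pos: FramePosition | str,
    include_e1_units: bool = True,
) -> float:
    """Relative SDU: sdu / sdu_max, in [0, 1], shared unit inclusion."""
    obs = observed_proportions(seq, pos)
    num = sdu_from_observed(obs, dinuc, seq.code, include_e1_units)
    den = sdu_max_from_observed(obs, dinuc, seq.code, include_e1_units)
    return num / den


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------


def _freqs(chars: Sequence[str]) -> dict:
    total = len(chars)
    counts = {nt: 0 for nt in NUCLEOTIDES}
    for c in chars:
        counts[c] += 1
    return {nt: n / total for nt, n in counts.items()}


def rda(
    seq: CodingSequence,
    dinuc: str,
    pos: FramePosition | str | None = None,
) -> float:
    """Relative dinucleotide abundance f(XY) / (f(X) f(Y)).

    With ``pos=None`` the classical whole-sequence odds ratio: f(XY) over all
    overlapping dinucleotides, f(X) and f(Y) the global mononucleotide
    frequencies.  With a frame position, f(XY) is the dinucleotide frequency
    at that position and the marginals are slot-specific (codon slots 1 and 2
    for pos1, 2 and 3 for pos2, slot 3 and the next codon's slot 1 for the
    bridge), so slot-independent composition gives RDA = 1 exactly.
    """
    x, y = normalize_dinucleotide(dinuc)
    nts = set(NUCLEOTIDES)
    if pos is None:
        chars = [c for c in seq.nts if c in nts]
        windows = [
            seq.nts[i : i + 2]
            for i in range(len(seq.nts) - 1)
            if set(seq.nts[i : i + 2]) <= nts
        ]
        if not windows:
            raise UndefinedMetricError("no countable dinucleotides in sequence")
        f_xy = sum(1 for w in windows if w == x + y) / len(windows)
        mono = _freqs(chars)
        left, right = mono, mono
    else:
        pos = FramePosition.coerce(pos)
        if pos is FramePosition.BRIDGE:
            idx = [
                t
                for t in range(len(seq.codons) - 1)
                if seq.clean[t] and seq.clean[t + 1]
            ]
            if not idx:
                raise UndefinedMetricError("no countable bridge pairs")
            pairs = [seq.codons[t][2] + seq.codons[t + 1][0] for t in idx]
            f_xy = sum(1 for p in pairs if p == x + y) / len(pairs)
            left = _freqs([seq.codons[t][2] for t in idx])
            right = _freqs([seq.codons[t + 1][0] for t in idx])
        else:
            start = 0 if pos is FramePosition.POS1 else 1
            idx = [t for t in range(len(seq.codons)) if seq.clean[t]]
            if not idx:
                raise UndefinedMetricError("no countable codons")
            dis = [seq.codons[t][start : start + 2] for t in idx]
            f_xy = sum(1 for d in dis if d == x + y) / len(dis)
            left = _freqs([seq.codons[t][start] for t in idx])
            right = _freqs([seq.codons[t][start + 1] for t in idx])
    denom = left[x] * right[y]
    if denom == 0.0:
        raise UndefinedMetricError(
            f"mononucleotide frequency of {x} or {y} is zero; RDA undefined"
        )
    return f_xy / denom


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass
class RscuTable:
    """RSCU values per sense codon; codons of absent amino acids are missing.

    For an amino acid with m synonymous codons, RSCU(c) = count(c) * m /
    total count of the amino acid; the mean over its codons is 1 whenever the
    amino acid occurs.  Stop codons are never assigned a value.
    """

    record_id: str
    values: dict  # codon -> RSCU
    codon_counts: dict

    def get(self, codon: str) -> float:
        from .genetic_code import normalize_nucleotides

        return self.values[normalize_nucleotides(codon)]

    def to_rows(self) -> list:
        code = standard_code()
        rows = []
        for codon, value in sorted(self.values.items()):
            rows.append(
                {
                    "record": self.record_id,
                    "codon": codon,
                    "aa": code.codon_to_aa[codon],
                    "count": self.codon_counts.get(codon, 0),
                    "rscu": value,
                }
            )
        return rows


def rscu(seq: CodingSequence) -> RscuTable:
    """Relative synonymous codon usage for every codon of a present amino acid."""
    code = seq.code
    counts: dict = {}
    for t, codon in enumerate(seq.codons):
        if seq.clean[t]:
            counts[codon] = counts.get(codon, 0) + 1
    values: dict = {}
    for aa, codons in code.aa_to_codons.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        m = len(codons)
        for c in codons:
            values[c] = counts.get(c, 0) * m / total
    return RscuTable(record_id=seq.id, values=values, codon_counts=counts)


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------


@dataclass
class MetricResult:
    """One metric evaluated over a grid of (dinucleotide, position) cells.

    ``values`` maps cells to floats, or to None where no present unit can
    carry the dinucleotide (reported as missing, never as 0).
    ``informative`` flags cells where the codon table allows deviation from
    1; non-informative cells are emitted flagged, not dropped.
    """

    record_id: str
    metric: str
    values: dict
    informative: dict
    n_units: dict
    weights: dict  # cell -> N (total included unit count)

    def to_rows(self) -> list:
        rows = []
        for (dinuc, pos), value in sorted(
            self.values.items(), key=lambda kv: (kv[0][1].value, kv[0][0])
        ):
            rows.append(
                {
                    "record": self.record_id,
                    "metric": self.metric,
                    "dinuc": dinuc,
                    "position": pos.value,
                    "value": value,
                    "informative": self.informative[(dinuc, pos)],
                    "n_units": self.n_units[(dinuc, pos)],
                    "N": self.weights[(dinuc, pos)],
                }
            )
        return rows


_SDU_FAMILY = {
    "sdu": sdu_from_observed,
    "sdu_max": sdu_max_from_observed,
}


def metric_table(
    seq: CodingSequence,
    metric: str = "sdu",
    dinucs: Iterable[str] | None = None,
    positions: Iterable[FramePosition | str] | None = None,
    include_e1_units: bool = True,
    informative_only: bool = False,
) -> MetricResult:
    """Evaluate `metric` ('sdu', 'sdu_max', 'rsdu' or 'rda') over a cell grid.

    Defaults to all 16 dinucleotides at all three frame positions; with
    ``informative_only`` the grid is restricted to the informative cells.
    """
    code = seq.code
    dinucs = (
        [normalize_dinucleotide(d) for d in dinucs] if dinucs else list(DINUCLEOTIDES)
    )
    positions = (
        [FramePosition.coerce(p) for p in positions]
        if positions
        else list(FramePosition)
    )
    values: dict = {}
    informative: dict = {}
    n_units: dict = {}
    weights: dict = {}
    obs_cache = {p: observed_proportions(seq, p) for p in positions}
    for p in positions:
        obs = obs_cache[p]
        for d in dinucs:
            cell = (d, p)
            info = code.is_informative(d, p)
            if informative_only and not info:
                continue
            informative[cell] = info
            included = list(_included_units(obs, code, d, include_e1_units))
            n_units[cell] = len(included)
            weights[cell] = sum(n for n, _o, _e in included)
            try:
                if metric in _SDU_FAMILY:
                    values[cell] = _SDU_FAMILY[metric](
                        obs, d, code, include_e1_units
                    )
                elif metric == "rsdu":
                    values[cell] = sdu_from_observed(
                        obs, d, code, include_e1_units
                    ) / sdu_max_from_observed(obs, d, code, include_e1_units)
                elif metric == "rda":
                    values[cell] = rda(seq, d, p)
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            except UndefinedMetricError:
                values[cell] = None
    return MetricResult(
        record_id=seq.id,
        metric=metric,
        values=values,
        informative=informative,
        n_units=n_units,
        weights=weights,
    )
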