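"""Monte-Carlo null distributions for synonymous dinucleotide usage.

The null hypothesis behind the SDU is equal usage of synonymous codons.  Its
sampling error for a concrete protein is measured empirically: the amino-acid
sequence is kept fixed and every codon is redrawn independently and uniformly
from its synonymous set, the metric is recomputed on each model sequence, and
the resulting vector of values is the *error distribution* of the metric for
that sequence under the null.  An observed value falling outside the
distribution's range is called a significant skew.

Resampling is i.i.d. uniform per codon — deliberately not preserving GC
content or codon counts, since those are exactly the quantities the null
randomises over.

The heavy lifting is vectorised: codon choices for all iterations are drawn
as one uniform matrix and mapped through small integer lookup tables, which
keeps a thousand resamples of a multi-kilobase CDS well under a second.  The
scalar path (:func:`resample_synonymous` + :func:`syndinuc.metrics.sdu`)
consumes the generator stream in the same order, so the two routes are
bit-identical for a given seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genetic_code import (
    DINUCLEOTIDES,
    NUCLEOTIDES,
    FramePosition,
    GeneticCode,
    normalize_dinucleotide,
)
from .metrics import UndefinedMetricError
from .sequences import CodingSequence

__all__ = [
    "NullDistribution",
    "resample_synonymous",
    "null_distribution",
    "null_distributions",
    "significance_call",
    "record_rng",
]

_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


def record_rng(seed: int | None, record_id: str) -> np.random.Generator:
    """Deterministic per-record substream: runs are reproducible regardless
    of record order.  The record id is folded in via CRC32."""
    if seed is None:
        return np.random.default_rng()
    key = zlib.crc32(record_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


class _CodeTables:
    """Integer lookup tables for one genetic code (cached per code)."""

    _cache: dict = {}

    def __new__(cls, code: GeneticCode):
        if id(code) in cls._cache:
            return cls._cache[id(code)]
        self = super().__new__(cls)
        self.code = code
        self.amino_acids = code.amino_acids
        self.aa_index = {aa: i for i, aa in enumerate(self.amino_acids)}
        n_aa = len(self.amino_acids)
        max_syn = max(len(c) for c in code.aa_to_codons.values())
        self.nsyn = np.zeros(n_aa, dtype=np.int64)
        # per (aa, synonym): dinucleotide codes at pos1/pos2, boundary nts
        self.d1 = np.full((n_aa, max_syn), -1, dtype=np.int8)
        self.d2 = np.full((n_aa, max_syn), -1, dtype=np.int8)
        self.nt3 = np.full((n_aa, max_syn), -1, dtype=np.int8)
        self.nt1 = np.full((n_aa, max_syn), -1, dtype=np.int8)
        self.codon_strings: list = []
        # uniform-usage marginals of the first / third codon nucleotide
        self.p1 = np.zeros((n_aa, 4))
        self.p3 = np.zeros((n_aa, 4))
        # expected dinucleotide proportions, per (aa, dinuc) at pos1/pos2
        self.e1 = np.zeros((n_aa, 16))
        self.e2 = np.zeros((n_aa, 16))
        for i, aa in enumerate(self.amino_acids):
            codons = code.aa_to_codons[aa]
            self.nsyn[i] = len(codons)
            self.codon_strings.append(list(codons))
            for s, codon in enumerate(codons):
                a, b, c = (_NT_INDEX[nt] for nt in codon)
                self.d1[i, s] = 4 * a + b
                self.d2[i, s] = 4 * b + c
                self.nt3[i, s] = c
                self.nt1[i, s] = a
                self.p1[i, a] += 1.0 / len(codons)
                self.p3[i, c] += 1.0 / len(codons)
                self.e1[i, 4 * a + b] += 1.0 / len(codons)
                self.e2[i, 4 * b + c] += 1.0 / len(codons)
        cls._cache[id(code)] = self
        return self


class _SiteModel:
    """Per-sequence arrays: amino-acid index and validity mask per codon site."""

    def __init__(self, seq: CodingSequence):
        self.seq = seq
        self.tables = _CodeTables(seq.code)
        L = len(seq.codons)
        self.aa_idx = np.zeros(L, dtype=np.int64)
        self.valid = np.zeros(L, dtype=bool)
        for t, (aa, clean) in enumerate(zip(seq.aa_seq, seq.clean)):
            if clean and aa in self.tables.aa_index:
                self.aa_idx[t] = self.tables.aa_index[aa]
                self.valid[t] = True
        # ambiguous sites resample trivially (1 pseudo-choice), never counted
        self.site_nsyn = np.where(self.valid, self.tables.nsyn[self.aa_idx], 1)

    def draw_choices(self, rng: np.random.Generator, n_iter: int) -> np.ndarray:
        """(n_iter, L) synonymous-codon choice indices, one uniform per site."""
        u = rng.random((n_iter, len(self.site_nsyn)))
        return np.minimum(
            (u * self.site_nsyn).astype(np.int64), self.site_nsyn - 1
        )

    # -- per-cell site weights -------------------------------------------

    def cell_weights(
        self, dinuc: str, pos: FramePosition, include_e1_units: bool
    ):
        """Included site indices and their 1/e weights for one cell.

        Returns (sites, weights, N).  For the bridge, `sites` indexes the
        left codon of each included pair.
        """
        t = self.tables
        x, y = (_NT_INDEX[c] for c in normalize_dinucleotide(dinuc))
        dcode = 4 * x + y
        if pos is FramePosition.BRIDGE:
            pair_ok = self.valid[:-1] & self.valid[1:]
            e = t.p3[self.aa_idx[:-1], x] * t.p1[self.aa_idx[1:], y]
            mask = pair_ok & (e > 0.0)
            if not include_e1_units:
                mask &= e < 1.0
            sites = np.nonzero(mask)[0]
            return sites, 1.0 / e[sites], len(sites)
        etab = t.e1 if pos is FramePosition.POS1 else t.e2
        e = etab[self.aa_idx, dcode]
        mask = self.valid & (e > 0.0)
        if not include_e1_units:
            mask &= e < 1.0
        sites = np.nonzero(mask)[0]
        return sites, 1.0 / e[sites], len(sites)

    def evaluate(
        self,
        choices: np.ndarray,
        dinuc: str,
        pos: FramePosition,
        include_e1_units: bool,
        metric: str,
    ) -> np.ndarray:
        """Metric value per resample row of `choices` for one cell."""
        t = self.tables
        x, y = (_NT_INDEX[c] for c in normalize_dinucleotide(dinuc))
        dcode = 4 * x + y
        sites, w, n = self.cell_weights(dinuc, pos, include_e1_units)
        if n == 0:
            raise UndefinedMetricError(
                f"no unit present can realise {normalize_dinucleotide(dinuc)} at {pos}"
            )
        if pos is FramePosition.BRIDGE:
            left = t.nt3[self.aa_idx[sites], choices[:, sites]] == x
            right = t.nt1[self.aa_idx[sites + 1], choices[:, sites + 1]] == y
            hits = left & right
        else:
            dtab = t.d1 if pos is FramePosition.POS1 else t.d2
            hits = dtab[self.aa_idx[sites], choices[:, sites]] == dcode
        samples = hits @ w / n
        if metric == "sdu":
            return samples
        if metric == "rsdu":
            return samples / (w.sum() / n)
        raise ValueError(f"unknown null-model metric {metric!r}")


def resample_synonymous(
    seq: CodingSequence, rng: np.random.Generator
) -> CodingSequence:
    """One random synonymous recoding: same protein, codons drawn uniformly
    from each amino acid's synonymous set.  Ambiguous codons are left as-is.
    """
    model = _SiteModel(seq)
    choices = model.draw_choices(rng, 1)[0]
    t = model.tables
    codons = [
        t.codon_strings[model.aa_idx[i]][choices[i]] if model.valid[i] else seq.codons[i]
        for i in range(len(seq.codons))
    ]
    return seq.with_codons(codons)


@dataclass
class NullDistribution:
    """Resampled metric values for one (dinucleotide, position) cell.

    ``samples`` holds one metric value per model sequence; the summary
    statistics are always recomputed from it.  Identical (sequence, cell,
    n_iter, seed) inputs reproduce the samples bit-for-bit.
    """

    record_id: str
    dinuc: str
    position: FramePosition
    metric: str
    samples: np.ndarray
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.samples)

    @property
    def min(self) -> float:
        return float(self.samples.min())

    @property
    def max(self) -> float:
        return float(self.samples.max())

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1) of the error distribution."""
        return float(self.samples.std(ddof=1)) if self.n_iter > 1 else 0.0

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.samples, q)

    def summary(self, quantiles: Sequence[float] = (0.025, 0.975)) -> dict:
        out = {
            "record": self.record_id,
            "metric": self.metric,
            "dinuc": self.dinuc,
            "position": self.position.value,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "error_min": self.min,
            "error_max": self.max,
            "mean": self.mean,
            "sd": self.sd,
        }
        for q in quantiles:
            out[f"q{q:g}"] = float(self.quantile(q))
        return out


def null_distributions(
    seq: CodingSequence,
    cells: Iterable[tuple],
    n_iter: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    metric: str = "sdu",
    include_e1_units: bool = True,
) -> dict:
    """Null distributions for several cells from one shared set of resamples.

    All requested (dinucleotide, position) cells are evaluated on the same
    ``n_iter`` model sequences, exactly as if each model sequence had been
    built once and every metric read off it.  Cells with no contributing
    unit are returned as None.
    """
    cells = [
        (normalize_dinucleotide(d), FramePosition.coerce(p)) for d, p in cells
    ]
    if rng is None:
        rng = record_rng(seed, seq.id)
    model = _SiteModel(seq)
    choices = model.draw_choices(rng, n_iter)
    out: dict = {}
    for dinuc, pos in cells:
        try:
            samples = model.evaluate(choices, dinuc, pos, include_e1_units, metric)
        except UndefinedMetricError:
            out[(dinuc, pos)] = None
            continue
        out[(dinuc, pos)] = NullDistribution(
            record_id=seq.id,
            dinuc=dinuc,
            position=pos,
            metric=metric,
            samples=samples,
            seed=seed,
        )
    return out


def null_distribution(
    seq: CodingSequence,
    dinuc: str,
    pos: FramePosition | str,
    n_iter: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    metric: str = "sdu",
    include_e1_units: bool = True,
) -> NullDistribution:
    """Null (error) distribution of the metric for a single cell.

    Draws ``n_iter`` independent uniform synonymous recodings of `seq` and
    evaluates the metric on each.  Under this null the expected SDU is
    exactly 1 for every informative cell.
    """
    result = null_distributions(
        seq,
        [(dinuc, pos)],
        n_iter=n_iter,
        seed=seed,
        rng=rng,
        metric=metric,
        include_e1_units=include_e1_units,
    )
    dist = result[(normalize_dinucleotide(dinuc), FramePosition.coerce(pos))]
    if dist is None:
        raise UndefinedMetricError(
            f"no unit present can realise {dinuc} at {FramePosition.coerce(pos)}"
        )
    return dist


def significance_call(
    observed: float,
    null: NullDistribution,
    rule: str = "range",
    lower: float = 0.025,
    upper: float = 0.975,
) -> str:
    """Classify an observed value against its null distribution.

    ``rule='range'`` (default): 'within' iff min <= observed <= max of the
    resampled values, else 'under'/'over'.  ``rule='quantile'`` uses the
    [lower, upper] sample quantiles instead.
    """
    if null.n_iter == 0:
        raise ValueError("empty null distribution")
    if rule == "range":
        lo, hi = null.min, null.max
    elif rule == "quantile":
        lo, hi = (float(null.quantile(q)) for q in (lower, upper))
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    if observed < lo:
        return "under"
    if observed > hi:
        return "over"
    return "within"
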