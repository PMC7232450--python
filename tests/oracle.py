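"""Independent brute-force oracles for the metric definitions.

Everything here recomputes the statistics directly from their definitions:
synonymous sets are enumerated from Biopython's codon table, dinucleotides
are binned by sliding over the raw nucleotide string, and the weighted means
are assembled from those raw counts.  Nothing is shared with the package's
counting or table machinery, so agreement is a genuine cross-check.
"""

from collections import Counter
from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_rna_by_id[1]
SENSE_CODONS = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)


def syn_codons(aa):
    return sorted(c for c, a in SENSE_CODONS.items() if a == aa)


def oracle_expected(unit, dinuc, pos):
    """e by exhaustive enumeration of synonymous codons / codon pairs."""
    if pos == "bridge":
        a, b = unit
        pairs = list(product(syn_codons(a), syn_codons(b)))
        return sum(1 for c1, c2 in pairs if c1[2] + c2[0] == dinuc) / len(pairs)
    start = {"pos1": 0, "pos2": 1}[pos]
    codons = syn_codons(unit)
    return sum(1 for c in codons if c[start : start + 2] == dinuc) / len(codons)


def scan_bins(nts):
    """Slide over the raw string, binning every dinucleotide by frame.

    Returns {pos: {unit: Counter(dinuc)}} computed purely from character
    offsets: offset mod 3 == 0 -> pos1 of codon i//3, == 1 -> pos2,
    == 2 -> bridge between codons i//3 and i//3+1.
    """
    codons = [nts[i : i + 3] for i in range(0, len(nts), 3)]
    aas = [SENSE_CODONS.get(c) for c in codons]  # None for ambiguous codons
    bins = {"pos1": {}, "pos2": {}, "bridge": {}}
    for i in range(len(nts) - 1):
        di = nts[i : i + 2]
        frame = i % 3
        t = i // 3
        if frame in (0, 1):
            if aas[t] is None:
                continue
            pos = "pos1" if frame == 0 else "pos2"
            bins[pos].setdefault(aas[t], Counter())[di] += 1
        else:
            if t + 1 >= len(codons) or aas[t] is None or aas[t + 1] is None:
                continue
            bins["bridge"].setdefault((aas[t], aas[t + 1]), Counter())[di] += 1
    return bins


def oracle_sdu(nts, dinuc, pos, include_e1_units=True, maximum=False):
    """SDU (or its maximum) straight from the definitional weighted mean."""
    units = scan_bins(nts)[pos]
    num = 0.0
    N = 0
    for unit, counter in units.items():
        e = oracle_expected(unit, dinuc, pos)
        if e == 0.0 or (e == 1.0 and not include_e1_units):
            continue
        n = sum(counter.values())
        o = counter.get(dinuc, 0) / n
        num += n * ((1.0 if maximum else o) / e)
        N += n
    if N == 0:
        return None
    return num / N


def oracle_rda_whole(nts, dinuc):
    mono = Counter(nts)
    di = Counter(nts[i : i + 2] for i in range(len(nts) - 1))
    L = len(nts)
    f_xy = di.get(dinuc, 0) / (L - 1)
    return f_xy / ((mono[dinuc[0]] / L) * (mono[dinuc[1]] / L))


def oracle_rscu(nts):
    codons = [nts[i : i + 3] for i in range(0, len(nts), 3)]
    counts = Counter(c for c in codons if c in SENSE_CODONS)
    out = {}
    for aa in set(SENSE_CODONS.values()):
        syn = syn_codons(aa)
        total = sum(counts.get(c, 0) for c in syn)
        if total == 0:
            continue
        for c in syn:
            out[c] = counts.get(c, 0) * len(syn) / total
    return out
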