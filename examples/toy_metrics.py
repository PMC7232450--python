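"""Compute all four metrics on two tiny hand-checkable coding sequences.

A run of ten ACG (threonine) codons puts a CpG in every synonymous
position-2 slot, so its SDU equals the maximum attainable ratio 1/e = 4 and
its RSDU is 1.  One codon of each threonine synonym is exactly the
equal-usage null, so every value sits at 1.
"""

from syndinuc import CodingSequence, rda, rscu, rsdu, sdu

acg_run = CodingSequence.from_string("acg_run", "ACG" * 10)
equal_thr = CodingSequence.from_string("equal_thr", "ACUACCACAACG")

for seq in (acg_run, equal_thr):
    print(f"-- {seq.id}: {seq.nts}")
    print(f"   SDU (CpG, pos2)  = {sdu(seq, 'CG', 'pos2'):.3f}")
    print(f"   RSDU(CpG, pos2)  = {rsdu(seq, 'CG', 'pos2'):.3f}")
    print(f"   RDA (CpG, whole) = {rda(seq, 'CG'):.3f}")
    acg_rscu = rscu(seq).get("ACG")
    print(f"   RSCU(ACG)        = {acg_rscu:.3f}")

print(
    "\nSDU=1 means the dinucleotide occurs exactly as often as equal "
    "synonymous codon\nusage predicts; 4 is the largest value a "
    "threonine-only sequence can reach at\nposition 2 (expected proportion "
    "e=1/4), and RSDU rescales that maximum to 1."
)
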