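import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from syndinuc import CodingSequence, random_cds, random_protein, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def acg10():
    """Ten ACG (Thr) codons: CG fills every synonymous pos2 slot."""
    return CodingSequence.from_string("acg10", "ACG" * 10)


@pytest.fixture
def equal_thr():
    """One of each Thr codon: exactly the equal-synonymous-usage null."""
    return CodingSequence.from_string("equal_thr", "ACUACCACAACG")


@pytest.fixture
def make_random_cds():
    """Factory for seeded random coding sequences of a given codon length."""

    def _make(n_codons, seed, record_id=None):
        rng = np.random.default_rng(seed)
        protein = random_protein(n_codons, rng)
        return random_cds(
            protein, rng, record_id=record_id or f"rand{n_codons}_{seed}"
        )

    return _make


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="input.fasta", wrap=None):
        lines = []
        for rid, seq in records:
            lines.append(f">{rid}")
            if wrap:
                lines.extend(seq[i : i + wrap] for i in range(0, len(seq), wrap))
            else:
                lines.append(seq)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
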