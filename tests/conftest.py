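import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cypsrs.srs_mapping import AlignmentParams, ProteinRecord, SrsAnnotation
from cypsrs.synthetic import FamilySimConfig, ScreenSimConfig, simulate_family, simulate_screen


@pytest.fixture(scope="session")
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def default_params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def family():
    """A moderately diverged synthetic family without indels."""
    return simulate_family(FamilySimConfig(seed=7, n_sequences=3))


@pytest.fixture(scope="session")
def indel_family():
    """Substitution-free family whose descendants carry a 1-residue SRS6 deletion."""
    return simulate_family(
        FamilySimConfig(
            seed=11, n_sequences=2, srs_sub_prob=0.0, non_srs_sub_prob=0.0,
            srs6_indel_prob=1.0, srs6_indel_length=1,
        )
    )


@pytest.fixture(scope="session")
def noiseless_screen():
    return simulate_screen(ScreenSimConfig(seed=3, cv=0.0))


def brute_force_align_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by exhaustive enumeration of all alignments.

    Affine convention: a gap run of length L costs gap_open + (L-1)*gap_extend.
    Independent of the dynamic-programming path under test.
    """
    best = -np.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "diag")
        if i < len(a):
            cost = gap_extend if last == "gap_b" else gap_open
            rec(i + 1, j, score - cost, "gap_b")
        if j < len(b):
            cost = gap_extend if last == "gap_a" else gap_open
            rec(i, j + 1, score - cost, "gap_a")

    rec(0, 0, 0.0, "start")
    return float(best)


def tiny_annotation(seq_id: str, intervals) -> SrsAnnotation:
    return SrsAnnotation(seq_id, tuple(intervals))
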