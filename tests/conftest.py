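import numpy as np
import pytest

from circplasmid import synth
from circplasmid.seqio import DetectionParams, Scaffold


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def params():
    return DetectionParams()


def longest_terminal_exact_repeat(seq: str) -> int:
    """Brute-force oracle: longest p with seq[:p] == seq[-p:], p <= L//2."""
    best = 0
    for p in range(1, len(seq) // 2 + 1):
        if seq[:p] == seq[-p:]:
            best = p
    return best


def smith_waterman(a: str, b: str, match=1, mismatch=-2, gap=-2):
    """Independent affine-free local-alignment oracle (numpy DP).

    Linear gap penalty of ``gap`` per gapped base, matching the detector's
    open == extend configuration.  Returns the best score.
    """
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    for i in range(1, la + 1):
        sub = np.where(bb == aa[i - 1], match, mismatch)
        row = H[i]
        prev = H[i - 1]
        for j in range(1, lb + 1):
            row[j] = max(0, prev[j - 1] + sub[j - 1], prev[j] + gap,
                         row[j - 1] + gap)
    return int(H.max())


def planted_scaffold(length: int, overlap: int, rng, mismatches: int = 0) -> Scaffold:
    """Scaffold from a random circle of ``length`` bp with a planted
    terminal direct repeat of ``overlap`` bp."""
    circle = synth.random_dna(length, rng)
    seq = synth.plant_terminal_repeat(circle, overlap, mismatches, rng)
    return Scaffold(id=f"planted_{length}_{overlap}", seq=seq)
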