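import pytest

from csrseq import SimJunctionConfig, make_reference
from csrseq.caller import SegmentMatch


@pytest.fixture(scope="session")
def sim_cfg():
    return SimJunctionConfig(seed=11)


@pytest.fixture(scope="session")
def refs(sim_cfg):
    """Synthetic donor/acceptor switch-region references shared by tests."""
    return make_reference(sim_cfg)


def segment_from_truth(frag) -> SegmentMatch:
    """Build a gap-free SegmentMatch from a simulator truth fragment."""
    length = frag.query_end - frag.query_start
    return SegmentMatch(
        query_start=frag.query_start,
        query_end=frag.query_end,
        region_name=frag.region_name,
        ref_start=frag.ref_start,
        ref_end=frag.ref_end,
        strand=frag.strand,
        mismatches=0,
        score=length,
    )


def bruteforce_boundary(read, left_target, left_diag, right_target, right_diag):
    """Independent brute-force seam oracle for clean two-fragment reads.

    Enumerates breakpoint placements directly: the donor part must match its
    continuation perfectly from the read start, the acceptor part perfectly
    to the read end; the overlap is the span covered by both.
    """
    n = len(read)
    i_max = 0
    while i_max < n:
        t = i_max + left_diag
        if not (0 <= t < len(left_target)) or read[i_max] != left_target[t] or read[i_max] == "N":
            break
        i_max += 1
    j_min = n
    while j_min > 0:
        q = j_min - 1
        t = q + right_diag
        if not (0 <= t < len(right_target)) or read[q] != right_target[t] or read[q] == "N":
            break
        j_min -= 1
    if i_max > j_min:
        return ("microhomology", i_max - j_min, "")
    if i_max == j_min:
        return ("blunt", 0, "")
    return ("insertion", 0, read[i_max:j_min])
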