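"""Junction taxonomy and complexity scoring.

A *simple* junction carries exactly the expected inter-switch recombination
event: two fragments, donor then acceptor, both forward.  A *compound*
junction bears additional intra-switch recombination events (Smu-Smu-Sx or
Smu-Sx-Sx architectures, and anything else that is not simple).  Compound
junctions can be *atypical*: microdeletions (a short same-region reference
gap between adjacent fragments), long microhomologies (any boundary with
OL >= 15 by default), and inversions (any reverse-strand fragment).  The
complexity of a junction counts its events: intra-switch recombination
events + insertions + inversions + microdeletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import JunctionCall, SegmentMatch
from .refdata import ValidationError

LONG_MH_THRESHOLD = 15  # ">= 15 bp of microhomology"


@dataclass
class JunctionClass:
    """Taxonomy of one junction call."""

    read_id: str
    category: str  # "simple" | "compound" | "uncallable"
    atypical_flags: frozenset[str]
    architecture: str
    complexity: int
    intra_events: int
    n_insertions: int = 0
    n_inversions: int = 0
    n_microdeletions: int = 0
    max_overlap: int = 0

    @property
    def is_atypical(self) -> bool:
        return bool(self.atypical_flags)


def _ref_gap(left: SegmentMatch, right: SegmentMatch) -> int | None:
    """Reference gap between same-region, same-strand adjacent fragments.

    Positive = skipped reference bases (deletion), negative/zero = overlap or
    duplication.  None when the pair is not same-region/same-strand.
    """
    if left.region_name != right.region_name or left.strand != right.strand:
        return None
    if left.strand == "+":
        return right.ref_start - left.ref_end
    # reverse-strand pairs descend along the forward reference
    return left.ref_start - right.ref_end


def classify(
    call: JunctionCall,
    donor_name: str,
    acceptor_name: str,
    long_mh_threshold: int = LONG_MH_THRESHOLD,
    microdel_min: int = 1,
    microdel_max: int = 50,
) -> JunctionClass:
    """Assign category, atypical flags and complexity to a junction call.

    Same-region adjacency with a reference gap in [microdel_min, microdel_max]
    is a microdeletion; larger same-region gaps (and duplications) are plain
    intra-switch recombination events.  Any reverse-strand fragment flags an
    inversion.  complexity = intra_events + #insertions + #inversions +
    #microdeletions.
    """
    if not call.callable:
        return JunctionClass(
            read_id=call.read_id,
            category="uncallable",
            atypical_flags=frozenset(),
            architecture=call.architecture,
            complexity=0,
            intra_events=0,
        )
    frags = call.fragments
    if len(frags) < 2:
        raise ValidationError(f"call {call.read_id!r}: callable call with < 2 fragments")

    intra_events = 0
    n_microdel = 0
    for left, right in zip(frags[:-1], frags[1:]):
        if left.region_name == right.region_name:
            intra_events += 1
            gap = _ref_gap(left, right)
            if gap is not None and microdel_min <= gap <= microdel_max:
                n_microdel += 1
    n_inversions = sum(1 for f in frags if f.strand == "-")
    n_insertions = sum(1 for b in call.boundaries if b.kind == "insertion")
    max_ol = max((b.overlap_len for b in call.boundaries), default=0)

    simple = (
        len(frags) == 2
        and frags[0].region_name == donor_name
        and frags[1].region_name == acceptor_name
        and frags[0].strand == "+"
        and frags[1].strand == "+"
    )
    flags = set()
    if n_inversions:
        flags.add("inversion")
    if n_microdel:
        flags.add("microdeletion")
    if max_ol >= long_mh_threshold:
        flags.add("long_microhomology")

    return JunctionClass(
        read_id=call.read_id,
        category="simple" if simple else "compound",
        atypical_flags=frozenset(flags),
        architecture=call.architecture,
        complexity=intra_events + n_insertions + n_inversions + n_microdel,
        intra_events=intra_events,
        n_insertions=n_insertions,
        n_inversions=n_inversions,
        n_microdeletions=n_microdel,
        max_overlap=max_ol,
    )


def summarize_classes(classes: list[JunctionClass]) -> dict:
    """Counts and fractions over a set of classified junctions.

    Reports the compound fraction of callable junctions, the atypical
    fraction among compound junctions, mean complexity among compound
    junctions, and per-flag counts.
    """
    if not classes:
        raise ValidationError("summarize_classes: empty class list")
    callable_classes = [c for c in classes if c.category != "uncallable"]
    compound = [c for c in callable_classes if c.category == "compound"]
    atypical = [c for c in compound if c.is_atypical]
    flag_counts = {"microdeletion": 0, "long_microhomology": 0, "inversion": 0}
    for c in compound:
        for flag in c.atypical_flags:
            flag_counts[flag] += 1
    n = len(callable_classes)
    return {
        "n": n,
        "n_uncallable": len(classes) - n,
        "n_simple": n - len(compound),
        "n_compound": len(compound),
        "compound_fraction": len(compound) / n if n else None,
        "n_atypical_compound": len(atypical),
        "atypical_among_compound": len(atypical) / len(compound) if compound else None,
        "mean_complexity_compound": (
            sum(c.complexity for c in compound) / len(compound) if compound else None
        ),
        "flag_counts": flag_counts,
    }
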