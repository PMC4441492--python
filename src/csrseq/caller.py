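"""Switch-junction reconstruction: segmentation and boundary resolution.

A junction amplicon is a chimera of fragments of the donor (Smu) and acceptor
(Sgamma-x) germline switch regions, possibly with additional intra-switch
recombination events.  This module

* finds gap-free mismatch-tolerant local matches of the read against each
  reference on both strands (exact k-mer seeds, X-drop extension),
* chains them into the highest-scoring left-to-right fragment architecture,
* resolves every fragment boundary as blunt, microhomology or insertion.

The overlap (OL) of a boundary is the length of the longest read window
spanning the breakpoint that matches BOTH germline continuations perfectly
and without interruption; a junction with any novel base at the seam is an
insertion (OL is not reported for it), and OL = 0 with no novel base is a
blunt join.  Within a microhomology window no single breakpoint exists: the
reported coordinates delimit the ambiguity window itself (left break = last
donor-side base of the maximal donor extension, right break = first
acceptor-side base of the maximal acceptor extension).

Alignment is deliberately gap-free: Sanger-scale switch junction reads are
substitution-dominated, and gap-free segments keep every decision auditable
against brute-force enumeration.  A read fragment containing a true indel
simply splits into two collinear segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .refdata import (
    ReferenceSet,
    SwitchRegion,
    ValidationError,
    revcomp,
)

# scoring used for extension and chaining; mismatches are strongly penalised
# so that segment ends sit on matches and spurious chaining is unprofitable
MATCH_SCORE = 1
MISMATCH_SCORE = -3
XDROP = 12


@dataclass
class CallerParams:
    """Tunable parameters of the junction caller."""

    min_seg_len: int = 20
    max_mismatch_rate: float = 0.1
    seed_k: int = 12
    max_boundary_overlap: int = 60  # max query overlap of adjacent fragments
    junction_penalty: int = 12  # chain-score cost of each extra fragment

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatch_rate < 0.5):
            raise ValidationError("max_mismatch_rate must be in [0, 0.5)")
        if self.min_seg_len < self.seed_k:
            raise ValidationError("min_seg_len must be >= seed_k")


@dataclass(frozen=True)
class SegmentMatch:
    """A gap-free local alignment of a read substring to a reference region.

    ``ref_interval`` is always on the region's forward strand (0-based
    half-open); for ``strand == "-"`` the read substring equals the reverse
    complement of that reference slice.
    """

    query_start: int
    query_end: int
    region_name: str
    ref_start: int
    ref_end: int
    strand: str  # "+" | "-"
    mismatches: int
    score: int

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.ref_end <= self.ref_start:
            raise ValidationError("SegmentMatch intervals must be non-empty")
        if self.mismatches < 0:
            raise ValidationError("mismatches must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start

    def oriented_diag(self, region: SwitchRegion) -> int:
        """Offset d with read[q] aligned to oriented(region)[q + d]."""
        if self.strand == "+":
            return self.ref_start - self.query_start
        # on "-": oriented coords o = len(region) - ref_end .. len(region) - ref_start
        return (len(region) - self.ref_end) - self.query_start


@dataclass(frozen=True)
class BoundaryCall:
    """Resolution of the seam between two adjacent fragments."""

    kind: str  # "blunt" | "microhomology" | "insertion"
    overlap_len: int
    insertion_seq: str
    left_break_ref: int  # 1-based genomic coordinate of last donor-side base
    right_break_ref: int  # 1-based genomic coordinate of first acceptor-side base
    query_left_end: int = 0  # read coord one past the maximal left extension
    query_right_start: int = 0  # read coord of the start of the right extension

    def __post_init__(self) -> None:
        if self.kind == "blunt" and (self.overlap_len != 0 or self.insertion_seq):
            raise ValidationError("blunt boundary must have OL=0 and no insertion")
        if self.kind == "microhomology" and self.overlap_len < 1:
            raise ValidationError("microhomology boundary must have OL >= 1")
        if self.kind == "insertion" and (not self.insertion_seq or self.overlap_len != 0):
            raise ValidationError("insertion boundary must carry bases and OL=0")


@dataclass
class JunctionCall:
    """Reconstructed architecture of one read."""

    read_id: str
    read_seq: str
    fragments: list[SegmentMatch]
    boundaries: list[BoundaryCall]
    unassigned_prefix: int = 0
    unassigned_suffix: int = 0
    callable: bool = True
    was_reverse_complemented: bool = False
    note: str = ""

    @property
    def architecture(self) -> str:
        return ",".join(f"{f.region_name}{f.strand}" for f in self.fragments)


def uncallable_call(read_id: str, read_seq: str, partial: list[SegmentMatch], note: str) -> JunctionCall:
    return JunctionCall(
        read_id=read_id,
        read_seq=read_seq,
        fragments=partial,
        boundaries=[],
        callable=False,
        note=note,
    )


# ---------------------------------------------------------------------------
# seed-and-extend scan
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _match(a: str, b: str) -> bool:
    # N never counts as a match
    return a == b and a != "N"


def _extend_on_diag(read: str, target: str, diag: int, seed_q: int, seed_len: int) -> tuple[int, int, int]:
    """X-drop extension of an exact seed along one diagonal.

    Returns (query_start, query_end, mismatches) of the maximal-score gap-free
    segment; endpoints are trimmed to the best-score positions so segments
    start and end on matches.
    """
    n = len(read)
    m = len(target)
    # rightward
    best = 0
    score = 0
    q = seed_q + seed_len
    end = q
    while q < n and q + diag < m and score > best - XDROP:
        score += MATCH_SCORE if _match(read[q], target[q + diag]) else MISMATCH_SCORE
        q += 1
        if score > best:
            best = score
            end = q
    # leftward
    best = 0
    score = 0
    q = seed_q - 1
    start = seed_q
    while q >= 0 and q + diag >= 0 and score > best - XDROP:
        score += MATCH_SCORE if _match(read[q], target[q + diag]) else MISMATCH_SCORE
        if score > best:
            best = score
            start = q
        q -= 1
    mism = sum(1 for i in range(start, end) if not _match(read[i], target[i + diag]))
    return start, end, mism


def scan_reference(
    read: str,
    region: SwitchRegion,
    strand: str,
    params: CallerParams | None = None,
) -> list[SegmentMatch]:
    """All locally optimal gap-free matches of read substrings to a region.

    Matches on the reverse strand are reported in forward-region coordinates
    with ``strand="-"``.  Results are filtered to length >= ``min_seg_len``
    and mismatch fraction <= ``max_mismatch_rate``, and sorted by query start
    then descending score.
    """
    params = params or CallerParams()
    if not read:
        raise ValidationError("scan_reference: empty read")
    read = read.upper()
    target = region.oriented(strand)
    k = params.seed_k
    index = _kmer_index(target, k)
    seen: dict[tuple[int, int, int], None] = {}
    covered: dict[int, list[tuple[int, int]]] = {}  # diag -> query intervals found
    out: list[SegmentMatch] = []
    for qpos in range(len(read) - k + 1):
        kmer = read[qpos : qpos + k]
        if "N" in kmer:
            continue
        for tpos in index.get(kmer, ()):  # noqa: B909 - index is static
            diag = tpos - qpos
            skip = False
            for s, e in covered.get(diag, ()):  # seed already inside a found segment
                if s <= qpos and qpos + k <= e:
                    skip = True
                    break
            if skip:
                continue
            qs, qe, mism = _extend_on_diag(read, target, diag, qpos, k)
            covered.setdefault(diag, []).append((qs, qe))
            key = (diag, qs, qe)
            if key in seen:
                continue
            seen[key] = None
            length = qe - qs
            if length < params.min_seg_len or mism / length > params.max_mismatch_rate:
                continue
            score = (length - mism) * MATCH_SCORE + mism * MISMATCH_SCORE
            ts, te = qs + diag, qe + diag
            if strand == "+":
                rs, re = ts, te
            else:
                rs, re = len(region) - te, len(region) - ts
            out.append(
                SegmentMatch(
                    query_start=qs,
                    query_end=qe,
                    region_name=region.name,
                    ref_start=rs,
                    ref_end=re,
                    strand=strand,
                    mismatches=mism,
                    score=score,
                )
            )
    out.sort(key=lambda s: (s.query_start, -s.score, s.region_name, s.strand, s.ref_start))
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _chain_segments(
    segments: list[SegmentMatch], params: CallerParams
) -> tuple[list[SegmentMatch], int, int] | None:
    """Best-scoring chain tiling the read left-to-right.

    Chain score = sum of segment scores minus query-overlap double counting,
    minus a per-boundary junction penalty (an extra fragment must improve the
    explanation of the read by more than the penalty to be kept).
    Ties are broken by fewer fragments, then fewer total mismatches, then
    segment order (deterministic).  Returns (chain, score, mismatches).
    """
    if not segments:
        return None
    segs = sorted(
        segments,
        key=lambda s: (s.query_start, s.query_end, s.region_name, s.strand, s.ref_start),
    )
    n = len(segs)
    # dp[i] = (score, -nfrags, -mismatches) best chain ending at segs[i]
    best_score = [s.score for s in segs]
    best_frags = [1] * n
    best_mism = [s.mismatches for s in segs]
    parent = [-1] * n
    for i in range(n):
        si = segs[i]
        for j in range(i):
            sj = segs[j]
            if sj.query_end >= si.query_end or sj.query_start >= si.query_start:
                continue
            overlap = sj.query_end - si.query_start
            if overlap > params.max_boundary_overlap:
                continue
            cand = best_score[j] + si.score - max(0, overlap) - params.junction_penalty
            cand_frags = best_frags[j] + 1
            cand_mism = best_mism[j] + si.mismatches
            key = (cand, -cand_frags, -cand_mism)
            if key > (best_score[i], -best_frags[i], -best_mism[i]):
                best_score[i] = cand
                best_frags[i] = cand_frags
                best_mism[i] = cand_mism
                parent[i] = j
    end = max(
        range(n),
        key=lambda i: (best_score[i], -best_frags[i], -best_mism[i], -segs[i].query_start),
    )
    chain: list[SegmentMatch] = []
    i = end
    while i != -1:
        chain.append(segs[i])
        i = parent[i]
    chain.reverse()
    return chain, best_score[end], best_mism[end]


def _scan_all(read: str, refs: ReferenceSet, params: CallerParams) -> list[SegmentMatch]:
    segments: list[SegmentMatch] = []
    for region in (refs.donor, refs.acceptor):
        for strand in ("+", "-"):
            segments.extend(scan_reference(read, region, strand, params))
    return segments


def segment_junction(
    read: str,
    refs: ReferenceSet,
    params: CallerParams | None = None,
    read_id: str = "read",
) -> JunctionCall:
    """Reconstruct a read's fragment architecture and resolve its boundaries.

    The read is tried in the given orientation and as its reverse complement;
    the orientation whose best chain places a forward-strand donor fragment
    first wins (higher chain score on ties).  A read with no donor fragment or
    no acceptor fragment is reported uncallable, carrying partial matches.
    """
    params = params or CallerParams()
    read = read.upper()
    if len(read) < 2 * params.min_seg_len:
        raise ValidationError(
            f"read {read_id!r}: length {len(read)} < 2 x min_seg_len ({2 * params.min_seg_len})"
        )

    candidates = []
    for was_rc, oriented_read in ((False, read), (True, revcomp(read))):
        segments = _scan_all(oriented_read, refs, params)
        chained = _chain_segments(segments, params)
        if chained is None:
            continue
        chain, score, mism = chained
        donor_first_fwd = (
            chain[0].region_name == refs.donor_name and chain[0].strand == "+"
        )
        has_donor = any(s.region_name == refs.donor_name for s in chain)
        has_acceptor = any(s.region_name == refs.acceptor_name for s in chain)
        first_donor_break = min(
            (s.ref_end for s in chain if s.region_name == refs.donor_name),
            default=0,
        )
        candidates.append(
            {
                "was_rc": was_rc,
                "read": oriented_read,
                "segments": segments,
                "chain": chain,
                "score": score,
                "mism": mism,
                "donor_first_fwd": donor_first_fwd,
                "valid": has_donor and has_acceptor,
                "first_donor_break": first_donor_break,
            }
        )

    if not candidates:
        return uncallable_call(read_id, read, [], "no reference match on either strand")

    # prefer: valid call, donor-forward-first, score, fewer fragments, fewer
    # mismatches, leftmost donor breakpoint, given orientation
    candidates.sort(
        key=lambda c: (
            c["valid"],
            c["donor_first_fwd"],
            c["score"],
            -len(c["chain"]),
            -c["mism"],
            -c["first_donor_break"],
            not c["was_rc"],
        ),
        reverse=True,
    )
    best = candidates[0]
    chain = best["chain"]
    oriented_read = best["read"]

    if not best["valid"] or len(chain) < 2:
        missing = []
        if not any(s.region_name == refs.donor_name for s in chain):
            missing.append("donor")
        if not any(s.region_name == refs.acceptor_name for s in chain):
            missing.append("acceptor")
        note = f"no {'/'.join(missing)} fragment" if missing else "single-fragment read"
        return uncallable_call(read_id, read, chain, note)

    boundaries = [
        resolve_boundary(oriented_read, chain[i], chain[i + 1], refs)
        for i in range(len(chain) - 1)
    ]
    return JunctionCall(
        read_id=read_id,
        read_seq=oriented_read,
        fragments=chain,
        boundaries=boundaries,
        unassigned_prefix=chain[0].query_start,
        unassigned_suffix=len(oriented_read) - chain[-1].query_end,
        callable=True,
        was_reverse_complemented=best["was_rc"],
    )


# ---------------------------------------------------------------------------
# boundary resolution
# ---------------------------------------------------------------------------


def _match_profile(read: str, target: str, diag: int) -> list[bool]:
    """A(q): does read[q] match target[q + diag]? (N never matches)."""
    n = len(read)
    out = [False] * n
    for q in range(n):
        t = q + diag
        if 0 <= t < len(target):
            out[q] = _match(read[q], target[t])
    return out


def _oriented_to_genomic(region: SwitchRegion, strand: str, opos: int) -> int:
    """Oriented-strand local position -> 1-based genomic coordinate."""
    local = opos if strand == "+" else len(region) - 1 - opos
    return region.genomic_position(local)


def resolve_boundary(
    read: str,
    left: SegmentMatch,
    right: SegmentMatch,
    refs: ReferenceSet,
) -> BoundaryCall:
    """Resolve the seam between two adjacent fragments.

    The two frontiers are located independently by running-score search
    along each fragment's diagonal: the donor frontier eL is the position
    maximising the cumulative gap-free score of the read prefix (from the
    left fragment's start; smallest position on ties), the acceptor frontier
    sR the position maximising the cumulative score of the read suffix
    (largest on ties).  With match +1 / mismatch -3 this is exactly the end
    of the maximal perfect donor extension (resp. start of the acceptor
    extension) whenever the seam is unambiguous, while still crossing
    isolated point mutations away from the seam.  eL > sR: microhomology
    window [sR, eL), OL = its length; eL == sR: blunt; eL < sR: the bases
    between match neither reference and are an insertion (OL forced 0).
    """
    if (
        left.region_name == right.region_name
        and left.strand == right.strand
        and left.ref_start == right.ref_start
        and left.query_start == right.query_start
    ):
        raise ValidationError("resolve_boundary: degenerate identical fragments")
    if left.query_end > right.query_end:
        raise ValidationError("resolve_boundary: fragments out of order on the read")
    read = read.upper()
    n = len(read)

    lregion = refs[left.region_name]
    rregion = refs[right.region_name]
    ltarget = lregion.oriented(left.strand)
    rtarget = rregion.oriented(right.strand)
    dL = left.oriented_diag(lregion)
    dR = right.oriented_diag(rregion)

    A = _match_profile(read, ltarget, dL)
    B = _match_profile(read, rtarget, dR)

    lo = left.query_start + 1
    hi = right.query_end
    # cumulative prefix score along the donor diagonal and suffix score along
    # the acceptor diagonal (no flooring: plain sums over the search window)
    PS = [0] * (n + 1)
    for q in range(1, n + 1):
        PS[q] = PS[q - 1] + (MATCH_SCORE if A[q - 1] else MISMATCH_SCORE)
    SS = [0] * (n + 1)
    for q in range(n - 1, -1, -1):
        SS[q] = SS[q + 1] + (MATCH_SCORE if B[q] else MISMATCH_SCORE)

    eL = min(range(lo, hi + 1), key=lambda b: (-PS[b], b))
    sR = max(range(lo, hi), key=lambda b: (SS[b], b))

    left_break = _oriented_to_genomic(
        lregion, left.strand, min(max(eL - 1 + dL, 0), len(ltarget) - 1)
    )
    right_break = _oriented_to_genomic(
        rregion, right.strand, min(max(sR + dR, 0), len(rtarget) - 1)
    )

    if eL > sR:
        return BoundaryCall(
            kind="microhomology",
            overlap_len=eL - sR,
            insertion_seq="",
            left_break_ref=left_break,
            right_break_ref=right_break,
            query_left_end=eL,
            query_right_start=sR,
        )
    if eL == sR:
        return BoundaryCall(
            kind="blunt",
            overlap_len=0,
            insertion_seq="",
            left_break_ref=left_break,
            right_break_ref=right_break,
            query_left_end=eL,
            query_right_start=sR,
        )
    return BoundaryCall(
        kind="insertion",
        overlap_len=0,
        insertion_seq=read[eL:sR],
        left_break_ref=left_break,
        right_break_ref=right_break,
        query_left_end=eL,
        query_right_start=sR,
    )


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def dedup_reads(reads: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop exact full-sequence duplicates, keeping the first occurrence.

    Reads identical only around the junction but differing elsewhere are
    distinct sequences and are retained.
    """
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for read_id, seq in reads:
        key = seq.upper()
        if key in seen:
            continue
        seen.add(key)
        out.append((read_id, seq))
    return out


# ---------------------------------------------------------------------------
# three-wise rendering
# ---------------------------------------------------------------------------


def render_threewise(call: JunctionCall, refs: ReferenceSet, flank: int = 40) -> str:
    """Paper-style three-wise alignment text for every boundary of a call.

    Per boundary, five lines: the left germline continuation, a pipe line
    marking identities to it, the read, a pipe line marking identities to the
    right germline, and the right germline continuation; plus an annotation
    line delimiting the microhomology window with ``[``/``]`` (``*`` under
    inserted bases).  Read bases mismatching the locally assigned germline are
    lower-case.  Line prefixes carry the 1-based genomic coordinate of the
    first shown base.  Output is deterministic byte-for-byte.
    """
    if not call.callable:
        return f"# {call.read_id}: uncallable ({call.note})\n"
    read = call.read_seq
    blocks: list[str] = []
    for bi, (left, right, boundary) in enumerate(
        zip(call.fragments[:-1], call.fragments[1:], call.boundaries)
    ):
        lregion = refs[left.region_name]
        rregion = refs[right.region_name]
        ltarget = lregion.oriented(left.strand)
        rtarget = rregion.oriented(right.strand)
        dL = left.oriented_diag(lregion)
        dR = right.oriented_diag(rregion)
        eL = boundary.query_left_end
        sR = boundary.query_right_start
        win_lo = max(0, min(sR, eL) - flank)
        win_hi = min(len(read), max(sR, eL) + flank)

        top = []
        pipe_top = []
        mid = []
        pipe_bot = []
        bot = []
        anno = []
        for q in range(win_lo, win_hi):
            lt = ltarget[q + dL] if 0 <= q + dL < len(ltarget) else " "
            rt = rtarget[q + dR] if 0 <= q + dR < len(rtarget) else " "
            base = read[q]
            in_mh = sR <= q < eL and boundary.kind == "microhomology"
            in_ins = eL <= q < sR and boundary.kind == "insertion"
            match_l = lt != " " and _match(base, lt)
            match_r = rt != " " and _match(base, rt)
            # side assignment for case: left of the window -> donor, right -> acceptor
            if in_ins:
                shown = base.lower()
            elif q < eL:
                shown = base if match_l else base.lower()
            else:
                shown = base if match_r else base.lower()
            top.append(lt)
            pipe_top.append("|" if match_l and (q < eL or in_mh) else " ")
            mid.append(shown)
            pipe_bot.append("|" if match_r and (q >= sR or in_mh) else " ")
            bot.append(rt)
            anno.append("*" if in_ins else " ")
        if boundary.kind in ("microhomology", "blunt"):
            # brackets delimit the homology window: "[" in the column before
            # its first base, "]" in the column after its last, so OL equals
            # the number of columns strictly between them (zero for blunt)
            if sR - 1 >= win_lo:
                anno[sR - 1 - win_lo] = "["
            if eL < win_hi:
                anno[eL - win_lo] = "]"
        # coordinates of the first shown base on each germline line
        lcoord = (
            _oriented_to_genomic(lregion, left.strand, win_lo + dL)
            if 0 <= win_lo + dL < len(ltarget)
            else "-"
        )
        rcoord = (
            _oriented_to_genomic(rregion, right.strand, win_lo + dR)
            if 0 <= win_lo + dR < len(rtarget)
            else "-"
        )
        label = (
            f"# {call.read_id} boundary {bi + 1}: {left.region_name}{left.strand} -> "
            f"{right.region_name}{right.strand} {boundary.kind}"
        )
        if boundary.kind == "microhomology":
            label += f" OL={boundary.overlap_len}"
        elif boundary.kind == "insertion":
            label += f" ins={boundary.insertion_seq}"
        width = 24
        lines = [
            label,
            f"{left.region_name}{left.strand} {lcoord}".ljust(width) + "".join(top),
            " " * width + "".join(pipe_top),
            f"{call.read_id}".ljust(width)[:width] + "".join(mid),
            " " * width + "".join(pipe_bot),
            f"{right.region_name}{right.strand} {rcoord}".ljust(width) + "".join(bot),
            " " * width + "".join(anno),
        ]
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"
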