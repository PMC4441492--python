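"""Synthetic switch-region references, junction reads and SHM clone sets.

Every read is emitted together with its ground truth (fragment coordinates,
boundary kinds and overlap lengths, planted events and mutations), so the
junction caller and the SHM profiler can be scored exactly.

The critical correctness trap of junction simulation in repeat-rich sequence
is that naive concatenation of two reference fragments can create *longer*
accidental homology at the seam than the overlap that was requested.  Two
safeguards handle this:

* the reference generator plants, besides switch-like repeat pentamer
  arrays, one controlled shared-homology tract per length 1..`max_shared_homology`
  (flanked by forced mismatches), and verifies that no cross-region maximal
  exact match exceeds that bound, breaking accidental longer matches;
* every assembled read is checked by a seam scanner and rejection-sampled
  (bounded attempts) until the realized maximal perfect homology at each
  seam equals the planted value exactly.

Point mutations are applied only outside a protected window around each seam
(width max(5, OL + 2) on each side by default) so the planted boundary types
remain the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .refdata import (
    ConfigurationError,
    ReferenceSet,
    SwitchRegion,
    ValidationError,
    build_reference_set,
    revcomp,
)
from .shm import classify_motif

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {b: i for i, b in enumerate("ACGT")}

DEFAULT_MOTIFS = ("GAGCT", "GGGGT")  # switch-region repeat pentamers

MAX_REJECT = 1000


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class SimJunctionConfig:
    """Study conditions for junction simulation."""

    seed: int = 0
    n_reads: int = 100
    ref_length: int = 1600
    repeat_motifs: tuple[str, ...] = DEFAULT_MOTIFS
    repeat_density: float = 0.2  # fraction of each reference inside motif arrays
    max_shared_homology: int = 30  # longest cross-region exact tract planted
    shared_motifs: bool = True  # both regions draw from the same motif set
    boundary_mix: dict = field(
        default_factory=lambda: {"blunt": 0.40, "microhomology": 0.45, "insertion": 0.15}
    )
    mh_length_geom_p: float = 0.45  # geometric length law for planted OL
    mh_length_max: int = 30
    insertion_len_max: int = 20
    mh_length_fixed: int | None = None  # force every planted OL to this value
    compound_fraction: float = 0.15
    event_mix: dict = field(
        default_factory=lambda: {
            "intra_donor": 0.35,
            "intra_acceptor": 0.20,
            "inversion": 0.25,
            "microdeletion": 0.20,
        }
    )
    microdel_gap: tuple[int, int] = (1, 50)
    intra_gap: tuple[int, int] = (100, 400)
    mutation_rate: float = 0.0
    seam_protect_min: int = 5
    read_length_range: tuple[int, int] = (300, 700)
    donor_name: str = "Smu"
    acceptor_name: str = "Sg1"
    donor_offset: int = 136_001
    acceptor_offset: int = 241_001

    def __post_init__(self) -> None:
        for mix in (self.boundary_mix, self.event_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"probability mix must sum to 1, got {total}")
        if self.ref_length < 200:
            raise ConfigurationError("ref_length must be >= 200")


@dataclass
class SimSHMConfig:
    """Study conditions for SHM clone simulation."""

    seed: int = 0
    n_clones: int = 50
    ref_length: int = 500
    target_frequency: float = 5e-3  # F0, per-bp substitution probability
    hotspot_bias: float = 6.0  # rate multiplier at RGYW/WRCY focal positions
    transition_bias: float = 2.0  # Tr:Tv odds (each transversion weighted 1)
    indel_rate: float = 0.0  # per-bp probability of starting an indel

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_frequency <= 0.05):
            raise ConfigurationError("target_frequency must be in [0, 0.05]")
        if self.hotspot_bias < 0 or self.transition_bias < 0:
            raise ConfigurationError("bias multipliers must be >= 0")


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class TrueFragment:
    region_name: str
    strand: str
    ref_start: int  # forward-strand, 0-based half-open
    ref_end: int
    query_start: int
    query_end: int


@dataclass
class TrueBoundary:
    kind: str
    overlap_len: int
    insertion_seq: str = ""


@dataclass
class TrueRead:
    read_id: str
    seq: str
    fragments: list[TrueFragment]
    boundaries: list[TrueBoundary]
    events: list[str]
    mutations: list[tuple[int, str, str]]  # (0-based read pos, old, new)
    compound: bool


@dataclass
class SimTruth:
    reads: list[TrueRead]

    def by_id(self) -> dict[str, TrueRead]:
        return {r.read_id: r for r in self.reads}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _random_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _different_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def maximal_exact_matches(a: str, b: str, min_len: int = 1) -> list[tuple[int, int, int]]:
    """All maximal exact matches between two sequences.

    Returns (length, pos_a, pos_b) triples; a match is maximal when it cannot
    be extended on either side (mismatch or sequence edge).  N matches
    nothing.  Vectorised per diagonal.
    """
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(aa), len(bb)
    n_code = ord("N")
    out: list[tuple[int, int, int]] = []
    for d in range(-(lb - 1), la):
        a0 = max(0, d)
        b0 = a0 - d
        m = min(la - a0, lb - b0)
        if m < min_len:
            continue
        av = aa[a0 : a0 + m]
        bv = bb[b0 : b0 + m]
        eq = (av == bv) & (av != n_code)
        padded = np.concatenate(([False], eq, [False]))
        diff = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(diff[::2], diff[1::2]):
            if e - s >= min_len:
                out.append((int(e - s), int(a0 + s), int(b0 + s)))
    return out


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _plant_motif_arrays(
    arr: np.ndarray, rng: np.random.Generator, motifs: tuple[str, ...], density: float
) -> None:
    if density <= 0 or not motifs:
        return
    n = len(arr)
    target = int(density * n)
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        motif = motifs[int(rng.integers(0, len(motifs)))]
        copies = int(rng.integers(2, 7))
        run = (motif * copies).encode()
        pos = int(rng.integers(0, n - len(run)))
        arr[pos : pos + len(run)] = np.frombuffer(run, dtype=np.uint8)
        covered += len(run)


def make_reference(cfg: SimJunctionConfig) -> ReferenceSet:
    """Generate donor/acceptor switch-region references.

    Random background interleaved with tandem repeat-motif arrays, plus one
    controlled shared-homology tract per length 1..max_shared_homology with
    mismatch-forced flanks; verified so that no cross-region maximal exact
    match exceeds max_shared_homology and every tract length is realizable.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.ref_length
    donor = _random_seq_arr(rng, n)
    acceptor = _random_seq_arr(rng, n)
    if cfg.shared_motifs:
        donor_motifs = acceptor_motifs = cfg.repeat_motifs
    else:
        half = max(1, len(cfg.repeat_motifs) // 2)
        donor_motifs = cfg.repeat_motifs[:half]
        acceptor_motifs = cfg.repeat_motifs[half:] or cfg.repeat_motifs[:half]
    _plant_motif_arrays(donor, rng, donor_motifs, cfg.repeat_density)
    _plant_motif_arrays(acceptor, rng, acceptor_motifs, cfg.repeat_density)

    # plant shared-homology tracts of every length 1..max_shared_homology,
    # break accidental longer cross-region matches, and iterate until every
    # tract length is realizable and no match exceeds the bound; tracts stay
    # well clear of the reference edges so full-length fragments fit around
    # any planted seam
    margin = 110
    used_d: list[tuple[int, int]] = []
    used_a: list[tuple[int, int]] = []

    def _free(slots: list[tuple[int, int]], pos: int, length: int) -> bool:
        return all(pos + length + 2 <= s or pos >= e + 2 for s, e in slots)

    def _in_tract(pos: int) -> bool:
        return any(s <= pos < e for s, e in used_a)

    def _plant_tract(length: int) -> None:
        tract = _random_seq_arr(rng, length)
        for _ in range(MAX_REJECT):
            pd = int(rng.integers(margin, n - margin - length))
            pa = int(rng.integers(margin, n - margin - length))
            if _free(used_d, pd, length) and _free(used_a, pa, length):
                break
        else:  # pragma: no cover - ref_length >= 200 leaves ample room
            raise ConfigurationError("could not place shared-homology tracts")
        donor[pd : pd + length] = tract
        acceptor[pa : pa + length] = tract
        # force mismatching flanks so the tract is exactly this long
        acceptor[pa - 1] = ord(_different_base(rng, chr(donor[pd - 1])))
        acceptor[pa + length] = ord(_different_base(rng, chr(donor[pd + length])))
        used_d.append((pd, pd + length))
        used_a.append((pa, pa + length))

    wanted = set(range(1, cfg.max_shared_homology + 1))
    for length in sorted(wanted):
        _plant_tract(length)
    for _ in range(50):
        dstr, astr = _arr_to_str(donor), _arr_to_str(acceptor)
        mems = maximal_exact_matches(dstr, astr, 1)
        too_long = [m for m in mems if m[0] > cfg.max_shared_homology]
        if too_long:
            # mutate a non-tract acceptor base inside each offending match
            for length, _, pa in too_long:
                for pos in range(pa + length // 2, pa + length):
                    if not _in_tract(pos):
                        acceptor[pos] = ord(_different_base(rng, chr(acceptor[pos])))
                        break
                else:
                    for pos in range(pa, pa + length // 2):
                        if not _in_tract(pos):
                            acceptor[pos] = ord(_different_base(rng, chr(acceptor[pos])))
                            break
            continue
        missing = wanted - {m[0] for m in mems}
        if not missing:
            break
        for length in sorted(missing):
            _plant_tract(length)
    else:  # pragma: no cover
        raise ConfigurationError("could not realize the shared-homology tract set")

    donor_region = SwitchRegion(
        name=cfg.donor_name,
        sequence=_arr_to_str(donor),
        accession="synthetic",
        genomic_offset=cfg.donor_offset,
        role="donor",
    )
    acceptor_region = SwitchRegion(
        name=cfg.acceptor_name,
        sequence=_arr_to_str(acceptor),
        accession="synthetic",
        genomic_offset=cfg.acceptor_offset,
        role="acceptor",
    )
    return build_reference_set(
        [donor_region, acceptor_region], cfg.donor_name, cfg.acceptor_name
    )


# ---------------------------------------------------------------------------
# seam scanner (generator-side verification)
# ---------------------------------------------------------------------------


def _perfect_right_run(read: str, target: str, diag: int, start: int) -> int:
    """Number of consecutive matches read[start..] vs target[start+diag..]."""
    run = 0
    q = start
    while q < len(read) and 0 <= q + diag < len(target):
        if read[q] != target[q + diag] or read[q] == "N":
            break
        run += 1
        q += 1
    return run


def _perfect_left_run(read: str, target: str, diag: int, end: int) -> int:
    """Number of consecutive matches read[..end-1] vs target going left."""
    run = 0
    q = end - 1
    while q >= 0 and 0 <= q + diag < len(target):
        if read[q] != target[q + diag] or read[q] == "N":
            break
        run += 1
        q -= 1
    return run


def realized_boundary(
    read: str,
    left_target: str,
    left_diag: int,
    right_target: str,
    right_diag: int,
    left_cut: int,
    right_cut: int,
) -> tuple[str, int, str]:
    """Realized boundary at a seam, from the construction's own frame.

    ``left_cut`` is the read position one past the last planted left-fragment
    base, ``right_cut`` the first planted right-fragment base (they differ
    only for insertions).  Returns (kind, overlap_len, insertion_seq).
    """
    e_l = left_cut + _perfect_right_run(read, left_target, left_diag, left_cut)
    s_r = right_cut - _perfect_left_run(read, right_target, right_diag, right_cut)
    if e_l > s_r:
        return ("microhomology", e_l - s_r, "")
    if e_l == s_r:
        return ("blunt", 0, "")
    return ("insertion", 0, read[e_l:s_r])


def seam_unambiguous(
    read: str,
    left_target: str,
    left_diag: int,
    right_target: str,
    right_diag: int,
    e_l: int,
    s_r: int,
) -> bool:
    """True when no accidental homology competes with the planted frontiers.

    Beyond the donor frontier the cumulative gap-free score (+1 match,
    -3 mismatch) along the donor diagonal must stay strictly negative, and
    symmetrically before the acceptor frontier; otherwise mismatch-tolerant
    extension could plausibly cross the seam and the planted overlap would
    not be the unambiguous maximal homology.
    """
    c = 0
    for q in range(e_l, len(read)):
        t = q + left_diag
        ok = 0 <= t < len(left_target) and read[q] == left_target[t] and read[q] != "N"
        c += 1 if ok else -3
        if c >= 0:
            return False
        if c < -80:
            break
    c = 0
    for q in range(s_r - 1, -1, -1):
        t = q + right_diag
        ok = 0 <= t < len(right_target) and read[q] == right_target[t] and read[q] != "N"
        c += 1 if ok else -3
        if c >= 0:
            return False
        if c < -80:
            break
    return True


# ---------------------------------------------------------------------------
# junction read simulation
# ---------------------------------------------------------------------------


@dataclass
class _Piece:
    region: SwitchRegion
    strand: str
    o_start: int  # oriented-strand coordinates
    o_end: int

    @property
    def target(self) -> str:
        return self.region.oriented(self.strand)

    @property
    def seq(self) -> str:
        return self.target[self.o_start : self.o_end]

    def forward_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.o_start, self.o_end)
        n = len(self.region)
        return (n - self.o_end, n - self.o_start)


class _MemCache:
    def __init__(self) -> None:
        self._cache: dict[tuple, dict[int, list[tuple[int, int]]]] = {}

    def by_length(self, lt_key: tuple, lt: str, rt_key: tuple, rt: str):
        key = (lt_key, rt_key)
        if key not in self._cache:
            table: dict[int, list[tuple[int, int]]] = {}
            for length, pa, pb in maximal_exact_matches(lt, rt, 1):
                table.setdefault(length, []).append((pa, pb))
            self._cache[key] = table
        return self._cache[key]


class _Retry(Exception):
    pass


def _sample_mh_len(rng: np.random.Generator, cfg: SimJunctionConfig) -> int:
    if cfg.mh_length_fixed is not None:
        return cfg.mh_length_fixed
    length = int(rng.geometric(cfg.mh_length_geom_p))
    return min(max(1, length), cfg.mh_length_max)


def _plant_boundary(
    rng: np.random.Generator,
    cfg: SimJunctionConfig,
    mems: _MemCache,
    left_piece_key: tuple,
    left_target: str,
    right_piece_key: tuple,
    right_target: str,
    kind: str,
    mh_len: int | None = None,
    min_margin: int = 85,
) -> tuple[int, int, str, int]:
    """Choose cut positions realizing the requested boundary kind.

    Returns (left_cut_in_left_target, right_cut_in_right_target,
    insertion_seq, planted_overlap).
    """
    lt, rt = left_target, right_target
    if kind == "microhomology":
        length = mh_len if mh_len is not None else _sample_mh_len(rng, cfg)
        table = mems.by_length(left_piece_key, lt, right_piece_key, rt)
        candidates = [
            (x, y)
            for x, y in table.get(length, [])
            if x >= min_margin and y + length <= len(rt) - min_margin
        ]
        if not candidates:
            raise ConfigurationError(
                f"cannot realize requested overlap {length}: no shared tract of that length"
            )
        x, y = candidates[int(rng.integers(0, len(candidates)))]
        t = int(rng.integers(0, length + 1))
        return (x + t, y + t, "", length)
    for _ in range(MAX_REJECT):
        e = int(rng.integers(min_margin, len(lt) - 1))
        s = int(rng.integers(1, len(rt) - min_margin))
        if lt[e] != rt[s] and lt[e - 1] != rt[s - 1] and "N" not in (lt[e], rt[s]):
            break
    else:
        raise ConfigurationError("cannot realize a blunt seam (rejection cap hit)")
    if kind == "blunt":
        return (e, s, "", 0)
    if kind == "insertion":
        for _ in range(MAX_REJECT):
            length = 1 + int(rng.geometric(0.25)) - 1
            length = min(max(1, length), cfg.insertion_len_max)
            ins = _arr_to_str(_random_seq_arr(rng, length))
            if ins[0] != lt[e] and ins[-1] != rt[s - 1]:
                return (e, s, ins, 0)
        raise ConfigurationError("cannot realize an insertion seam")
    raise ConfigurationError(f"unknown boundary kind {kind!r}")


def _assemble(pieces: list[_Piece], insertions: list[str]) -> tuple[str, list[int], list[int]]:
    """Concatenate pieces with seam insertions.

    Returns (read, left_cuts, right_cuts): per boundary i, left_cuts[i] is the
    read position one past piece i, right_cuts[i] the start of piece i+1.
    """
    parts = []
    left_cuts = []
    right_cuts = []
    pos = 0
    for i, piece in enumerate(pieces):
        parts.append(piece.seq)
        pos += len(piece.seq)
        if i < len(pieces) - 1:
            left_cuts.append(pos)
            parts.append(insertions[i])
            pos += len(insertions[i])
            right_cuts.append(pos)
    return ("".join(parts), left_cuts, right_cuts)


def _choice(rng: np.random.Generator, mix: dict) -> str:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _build_read(
    rng: np.random.Generator,
    cfg: SimJunctionConfig,
    refs: ReferenceSet,
    mems: _MemCache,
    read_id: str,
) -> TrueRead:
    donor, acceptor = refs.donor, refs.acceptor
    compound = bool(rng.random() < cfg.compound_fraction)
    event = _choice(rng, cfg.event_mix) if compound else None
    inter_kind = _choice(rng, cfg.boundary_mix)

    total_len = int(rng.integers(*cfg.read_length_range))
    n_pieces = 3 if compound else 2
    base_len = max(90, total_len // n_pieces)

    # piece skeletons, left to right
    if not compound:
        plan = [(donor, "+"), (acceptor, "+")]
        events: list[str] = []
    elif event in ("intra_donor", "microdeletion"):
        plan = [(donor, "+"), (donor, "+"), (acceptor, "+")]
        events = [event]
    elif event == "inversion":
        plan = [(donor, "+"), (donor, "-"), (acceptor, "+")]
        events = ["inversion"]
    elif event == "intra_acceptor":
        plan = [(donor, "+"), (acceptor, "+"), (acceptor, "+")]
        events = ["intra_acceptor"]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown event {event!r}")

    for _ in range(MAX_REJECT):
        try:
            pieces: list[_Piece] = []
            insertions: list[str] = []
            planted: list[TrueBoundary] = []
            for i in range(len(plan) - 1):
                lregion, lstrand = plan[i]
                rregion, rstrand = plan[i + 1]
                lt, rt = lregion.oriented(lstrand), rregion.oriented(rstrand)
                lkey, rkey = (lregion.name, lstrand), (rregion.name, rstrand)
                same_region = lregion.name == rregion.name
                intra_colinear = same_region and lstrand == rstrand
                if intra_colinear:
                    # same diagonal family: resume downstream after a gap —
                    # short (microdeletion) or recombination-scale (intra)
                    gap_lo, gap_hi = (
                        cfg.microdel_gap if event == "microdeletion" else cfg.intra_gap
                    )
                    if len(lt) - gap_hi - 120 <= 100:
                        raise ConfigurationError(
                            "reference too short for intra-region events"
                        )
                    kind, ins, ol = "blunt", "", 0
                    for _ in range(50):
                        e = int(rng.integers(100, len(lt) - gap_hi - 120))
                        s = e + int(rng.integers(gap_lo, gap_hi + 1))
                        # clean blunt seam keeps the deletion unambiguous
                        if lt[e] != rt[s] and lt[e - 1] != rt[s - 1]:
                            break
                    else:
                        raise _Retry
                elif same_region:
                    # inversion seam: blunt internal boundary
                    kind = "blunt"
                    e, s, ins, ol = _plant_boundary(rng, cfg, mems, lkey, lt, rkey, rt, "blunt")
                else:
                    kind = inter_kind
                    if kind == "microhomology" and lstrand == "-":
                        # shared tracts are planted forward/forward; after an
                        # inversion the inter-switch seam is joined bluntly
                        kind = "blunt"
                    e, s, ins, ol = _plant_boundary(rng, cfg, mems, lkey, lt, rkey, rt, kind)
                if i == 0:
                    length = min(base_len + int(rng.integers(-40, 41)), e)
                    if length < 80:
                        raise _Retry
                    pieces.append(_Piece(lregion, lstrand, e - length, e))
                else:
                    prev = pieces[-1]
                    if e <= prev.o_start + 50 or e > len(lt):
                        raise _Retry
                    pieces[-1] = _Piece(prev.region, prev.strand, prev.o_start, e)
                next_end = min(s + base_len + int(rng.integers(-40, 41)), len(rt))
                if next_end - s < 80:
                    raise _Retry
                pieces.append(_Piece(rregion, rstrand, s, next_end))
                insertions.append(ins)
                planted.append(TrueBoundary(kind=kind, overlap_len=ol, insertion_seq=ins))

            read, left_cuts, right_cuts = _assemble(pieces, insertions)

            # verify every seam: realized boundary must equal the planted one
            for i in range(len(pieces) - 1):
                lp, rp = pieces[i], pieces[i + 1]
                d_l = lp.o_end - left_cuts[i]
                d_r = rp.o_start - right_cuts[i]
                kind, ol, ins = realized_boundary(
                    read, lp.target, d_l, rp.target, d_r, left_cuts[i], right_cuts[i]
                )
                want = planted[i]
                if (kind, ol, ins) != (want.kind, want.overlap_len, want.insertion_seq):
                    raise _Retry
                e_l = left_cuts[i] + _perfect_right_run(read, lp.target, d_l, left_cuts[i])
                s_r = right_cuts[i] - _perfect_left_run(read, rp.target, d_r, right_cuts[i])
                if not seam_unambiguous(read, lp.target, d_l, rp.target, d_r, e_l, s_r):
                    raise _Retry

            # plant mutations outside protected seam windows
            mutations: list[tuple[int, str, str]] = []
            if cfg.mutation_rate > 0:
                protected = np.zeros(len(read), dtype=bool)
                for i, want in enumerate(planted):
                    pad = max(cfg.seam_protect_min, want.overlap_len + 2)
                    lo = max(0, min(left_cuts[i], right_cuts[i]) - want.overlap_len - pad)
                    hi = min(
                        len(read),
                        max(left_cuts[i], right_cuts[i]) + want.overlap_len + pad,
                    )
                    protected[lo:hi] = True
                hit = np.flatnonzero((rng.random(len(read)) < cfg.mutation_rate) & ~protected)
                if hit.size:
                    chars = list(read)
                    for pos in hit:
                        old = chars[pos]
                        new = _different_base(rng, old)
                        chars[pos] = new
                        mutations.append((int(pos), old, new))
                    read = "".join(chars)

            fragments: list[TrueFragment] = []
            for i, piece in enumerate(pieces):
                qs = right_cuts[i - 1] if i > 0 else 0
                qe = qs + (piece.o_end - piece.o_start)
                fs, fe = piece.forward_interval()
                fragments.append(
                    TrueFragment(
                        region_name=piece.region.name,
                        strand=piece.strand,
                        ref_start=fs,
                        ref_end=fe,
                        query_start=qs,
                        query_end=qe,
                    )
                )
            return TrueRead(
                read_id=read_id,
                seq=read,
                fragments=fragments,
                boundaries=planted,
                events=events,
                mutations=mutations,
                compound=compound,
            )
        except _Retry:
            continue
    raise ConfigurationError(f"read {read_id}: rejection cap hit; config unrealizable")


def simulate_junctions(
    cfg: SimJunctionConfig, refs: ReferenceSet | None = None
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate junction reads with ground truth.

    Returns (reads, truth) where reads is a list of (read_id, sequence).
    Deterministic under ``cfg.seed``; the same seed also reproduces the
    reference set when ``refs`` is not supplied.
    """
    if refs is None:
        refs = make_reference(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from make_reference
    mems = _MemCache()
    truths = [
        _build_read(rng, cfg, refs, mems, f"sim{i:05d}") for i in range(cfg.n_reads)
    ]
    reads = [(t.read_id, t.seq) for t in truths]
    return reads, SimTruth(reads=truths)


# ---------------------------------------------------------------------------
# SHM clone simulation
# ---------------------------------------------------------------------------


@dataclass
class TrueClone:
    clone_id: str
    seq: str
    mutations: list[tuple[int, str, str]]  # (1-based ref pos, ref, alt)
    indels: list[tuple[int, str, int]]  # (1-based ref pos, kind, length)


def make_shm_reference(cfg: SimSHMConfig) -> str:
    """Random germline reference for SHM simulation (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    return _arr_to_str(_random_seq_arr(rng, cfg.ref_length))


def simulate_shm_clones(
    cfg: SimSHMConfig, reference: str | None = None
) -> tuple[list[tuple[str, str]], list[TrueClone]]:
    """Simulate a clone set with planted mutations.

    Per-position substitution rates equal F0 scaled by the hotspot multiplier
    at AID focal positions (RGYW G / WRCY C) and normalised so the mean rate
    over the reference equals F0 exactly; substitution identity follows the
    transition:transversion odds.  Truth lists every planted change.
    """
    if reference is None:
        reference = make_shm_reference(cfg)
    reference = reference.upper()
    rng = np.random.default_rng(cfg.seed + 1)
    L = len(reference)
    mult = np.ones(L)
    for i in range(L):
        if classify_motif(reference, i) in ("hotspot_RGYW", "hotspot_WRCY"):
            mult[i] = cfg.hotspot_bias
    rates = cfg.target_frequency * mult / mult.mean() if mult.mean() > 0 else mult * 0
    rates = np.clip(rates, 0.0, 0.9)

    tb = cfg.transition_bias
    p_transition = tb / (tb + 2.0) if tb + 2.0 > 0 else 0.0
    transition_of = {"A": "G", "G": "A", "C": "T", "T": "C"}

    clones: list[tuple[str, str]] = []
    truth: list[TrueClone] = []
    for c in range(cfg.n_clones):
        clone_id = f"clone{c:04d}"
        hits = np.flatnonzero(rng.random(L) < rates)
        chars = list(reference)
        mutations = []
        for pos in hits:
            ref_base = reference[pos]
            if rng.random() < p_transition:
                alt = transition_of[ref_base]
            else:
                tvs = [b for b in "ACGT" if b != ref_base and b != transition_of[ref_base]]
                alt = tvs[int(rng.integers(0, len(tvs)))]
            chars[pos] = alt
            mutations.append((int(pos) + 1, ref_base, alt))
        indels = []
        if cfg.indel_rate > 0:
            starts = np.flatnonzero(rng.random(L) < cfg.indel_rate)
            # apply right-to-left so earlier coordinates stay valid
            for pos in starts[::-1]:
                length = int(rng.integers(1, 4))
                if rng.random() < 0.5 and pos + length < len(chars):
                    del chars[pos : pos + length]
                    indels.append((int(pos) + 1, "deletion", length))
                else:
                    ins = _arr_to_str(_random_seq_arr(rng, length))
                    chars[pos:pos] = list(ins)
                    indels.append((int(pos) + 1, "insertion", length))
        clones.append((clone_id, "".join(chars)))
        truth.append(
            TrueClone(clone_id=clone_id, seq="".join(chars), mutations=mutations, indels=sorted(indels))
        )
    return clones, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(reads: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Deterministic FASTA writer (fixed wrap, given order)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    """Write ground truth as JSON (full) and TSV (one row per boundary)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump([asdict(t) for t in truth.reads], fh, indent=1)
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("read_id\tboundary\tkind\toverlap_len\tinsertion_seq\tcompound\tevents\n")
        for t in truth.reads:
            for i, b in enumerate(t.boundaries):
                fh.write(
                    f"{t.read_id}\t{i + 1}\t{b.kind}\t{b.overlap_len}\t"
                    f"{b.insertion_seq or '.'}\t{int(t.compound)}\t"
                    f"{','.join(t.events) or '.'}\n"
                )
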