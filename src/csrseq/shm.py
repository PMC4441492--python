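"""Somatic hypermutation profiling.

Calls point mutations in cloned amplicon sequences (e.g. the JH4-intron
region downstream of rearranged VDJ exons) against a germline reference and
builds the standard SHM summaries: per-position spatial distribution,
12-class substitution spectrum with transition/transversion split, per-bp
mutation frequency, indel counts, and hotspot/coldspot motif classes.

Hotspot motifs are the field-standard AID deamination contexts RGYW (mutated
G) and its complement WRCY (mutated C), and the polymerase-eta A:T contexts
WA (mutated A) and its complement TW (mutated T); the coldspot is SYC
(mutated C) and its complement GRS (mutated G).  IUPAC codes: W = A/T,
R = A/G, Y = C/T, S = G/C.  Motif classes are computed on the germline
(reference) strand; the complementary motif pair makes the calling
strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .refdata import ValidationError
from . import stats as _stats

BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
IUPAC = {"W": set("AT"), "R": set("AG"), "Y": set("CT"), "S": set("GC")}

MOTIF_CLASSES = [
    "hotspot_RGYW",
    "hotspot_WRCY",
    "hotspot_WA",
    "hotspot_TW",
    "coldspot",
    "none",
]

SUB_CLASSES = [f"{r}>{a}" for r in BASES for a in BASES if r != a]


@dataclass(frozen=True)
class MutationCall:
    """One substitution called against the germline reference."""

    position: int  # 1-based reference coordinate
    ref_base: str
    alt_base: str
    clone_id: str
    motif_context: str  # 5-mer centred on the position, N-padded at edges
    motif_class: str
    near_indel: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError("MutationCall: ref and alt must differ")
        if len(self.motif_context) != 5:
            raise ValidationError("MutationCall: motif context must be a 5-mer")


@dataclass(frozen=True)
class IndelRecord:
    """A gap in the clone/reference alignment (excluded from the spectrum)."""

    position: int  # 1-based reference coordinate of the first affected base
    length: int
    kind: str  # "insertion" | "deletion"
    clone_id: str
    seq: str = ""


@dataclass
class CloneResult:
    """Per-clone mutation calling outcome."""

    clone_id: str
    aligned: bool
    identity: float
    calls: list[MutationCall] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)


@dataclass
class MutationSpectrum:
    """Aggregate substitution spectrum of a clone set."""

    sub_counts: np.ndarray  # 4x4, rows ref base, cols alt base, diagonal zero
    n_sequences: int
    n_bases: int
    frequency_per_bp: float
    transitions: int
    transversions: int
    at_fraction: float
    gc_fraction: float
    n_insertions: int = 0
    n_deletions: int = 0

    @property
    def total(self) -> int:
        return int(self.sub_counts.sum())

    def class_counts(self) -> dict[str, int]:
        idx = {b: i for i, b in enumerate(BASES)}
        return {
            cls: int(self.sub_counts[idx[cls[0]], idx[cls[2]]]) for cls in SUB_CLASSES
        }

    def as_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "n_bases": self.n_bases,
            "total_mutations": self.total,
            "frequency_per_bp": self.frequency_per_bp,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "at_fraction": self.at_fraction,
            "gc_fraction": self.gc_fraction,
            "n_insertions": self.n_insertions,
            "n_deletions": self.n_deletions,
            "sub_counts": self.class_counts(),
        }


# ---------------------------------------------------------------------------
# motif classification
# ---------------------------------------------------------------------------


def _fits(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq, pattern):
        allowed = IUPAC.get(code, {code})
        if base not in allowed:
            return False
    return True


def motif_context(reference: str, pos0: int) -> str:
    """5-mer centred on 0-based position ``pos0``, N-padded at the edges."""
    out = []
    for i in range(pos0 - 2, pos0 + 3):
        out.append(reference[i] if 0 <= i < len(reference) else "N")
    return "".join(out)


def classify_motif(reference: str, pos0: int) -> str:
    """Hotspot/coldspot class of the germline position ``pos0`` (0-based).

    The mutated (focal) base is the G of RGYW, the C of WRCY, the A of WA,
    the T of TW, the C of SYC and the G of GRS; hotspots take precedence
    over the coldspot.  All patterns are matched on the reference strand.
    """
    ref = reference.upper()
    base = ref[pos0]
    window = lambda lo, hi: ref[lo:hi] if lo >= 0 and hi <= len(ref) else ""
    if base == "G" and _fits(window(pos0 - 1, pos0 + 3), "RGYW"):
        return "hotspot_RGYW"
    if base == "C" and _fits(window(pos0 - 2, pos0 + 2), "WRCY"):
        return "hotspot_WRCY"
    if base == "A" and _fits(window(pos0 - 1, pos0 + 1), "WA"):
        return "hotspot_WA"
    if base == "T" and _fits(window(pos0, pos0 + 2), "TW"):
        return "hotspot_TW"
    if base == "C" and _fits(window(pos0 - 2, pos0 + 1), "SYC"):
        return "coldspot"
    if base == "G" and _fits(window(pos0, pos0 + 3), "GRS"):
        return "coldspot"
    return "none"


# ---------------------------------------------------------------------------
# mutation calling
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    # amplicons may be trimmed relative to the reference: end gaps are free
    aligner.end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def call_clone_mutations(
    clone: str,
    reference: str,
    clone_id: str = "clone",
    min_identity: float = 0.9,
) -> CloneResult:
    """Call substitutions and indels in one clone against the reference.

    Global affine-gap alignment (free end gaps); substitutions become
    :class:`MutationCall` records with motif annotation, gaps become
    :class:`IndelRecord` entries excluded from the substitution spectrum.
    Calls within 1 nt of an indel column are kept but flagged ``near_indel``.
    A clone below ``min_identity`` over its aligned columns is flagged
    unaligned and carries no calls.
    """
    clone = clone.upper()
    reference = reference.upper()
    if not clone or not reference:
        raise ValidationError("call_clone_mutations: empty sequence")
    alignment = _ALIGNER.align(reference, clone)[0]
    tblocks, qblocks = alignment.aligned

    calls: list[MutationCall] = []
    indels: list[IndelRecord] = []
    matches = 0
    cols = 0
    prev_t = prev_q = None
    indel_positions: list[int] = []
    raw: list[tuple[int, str, str]] = []
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            if ts > prev_t:  # deletion in the clone
                indels.append(
                    IndelRecord(
                        position=prev_t + 1,
                        length=ts - prev_t,
                        kind="deletion",
                        clone_id=clone_id,
                        seq=reference[prev_t:ts],
                    )
                )
                indel_positions.extend(range(prev_t, ts))
            if qs > prev_q:  # insertion in the clone
                indels.append(
                    IndelRecord(
                        position=prev_t,  # ref base before the inserted run
                        length=qs - prev_q,
                        kind="insertion",
                        clone_id=clone_id,
                        seq=clone[prev_q:qs],
                    )
                )
                indel_positions.append(prev_t - 1)
                indel_positions.append(prev_t)
        for offset in range(te - ts):
            rbase = reference[ts + offset]
            cbase = clone[qs + offset]
            cols += 1
            if rbase == cbase:
                matches += 1
            elif rbase in BASES and cbase in BASES:
                raw.append((ts + offset, rbase, cbase))
        prev_t, prev_q = te, qe

    identity = matches / cols if cols else 0.0
    if identity < min_identity:
        return CloneResult(clone_id=clone_id, aligned=False, identity=identity)

    indel_set = set(indel_positions)
    for pos0, rbase, cbase in raw:
        near = any(pos0 + d in indel_set for d in (-1, 0, 1))
        calls.append(
            MutationCall(
                position=pos0 + 1,
                ref_base=rbase,
                alt_base=cbase,
                clone_id=clone_id,
                motif_context=motif_context(reference, pos0),
                motif_class=classify_motif(reference, pos0),
                near_indel=near,
            )
        )
    return CloneResult(
        clone_id=clone_id, aligned=True, identity=identity, calls=calls, indels=indels
    )


def profile_clones(
    clones: list[tuple[str, str]],
    reference: str,
    min_identity: float = 0.9,
    collapse_clones: bool = False,
) -> list[CloneResult]:
    """Call mutations for a clone set; optionally collapse clonally related
    sequences (identical mutation sets kept once)."""
    results = [
        call_clone_mutations(seq, reference, clone_id=cid, min_identity=min_identity)
        for cid, seq in clones
    ]
    if collapse_clones:
        seen: set[tuple] = set()
        kept = []
        for res in results:
            key = tuple(sorted((c.position, c.ref_base, c.alt_base) for c in res.calls))
            if res.aligned and key in seen:
                continue
            seen.add(key)
            kept.append(res)
        results = kept
    return results


# ---------------------------------------------------------------------------
# spectrum building and comparison
# ---------------------------------------------------------------------------


def build_spectrum(
    calls: list[MutationCall],
    n_sequences: int,
    analyzed_len: int,
    indels: list[IndelRecord] | None = None,
) -> MutationSpectrum:
    """Aggregate calls into a 12-class spectrum with per-bp frequency.

    frequency_per_bp = #calls / (n_sequences x analyzed_len).
    """
    if n_sequences < 1 or analyzed_len < 1:
        raise ValidationError("build_spectrum: n_sequences and analyzed_len must be >= 1")
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for call in calls:
        counts[idx[call.ref_base], idx[call.alt_base]] += 1
    total = int(counts.sum())
    transitions = sum(
        int(counts[idx[r], idx[a]]) for r, a in TRANSITIONS
    )
    at = sum(int(counts[idx[r]].sum()) for r in "AT")
    indels = indels or []
    return MutationSpectrum(
        sub_counts=counts,
        n_sequences=n_sequences,
        n_bases=n_sequences * analyzed_len,
        frequency_per_bp=total / (n_sequences * analyzed_len),
        transitions=transitions,
        transversions=total - transitions,
        at_fraction=at / total if total else 0.0,
        gc_fraction=(total - at) / total if total else 0.0,
        n_insertions=sum(1 for i in indels if i.kind == "insertion"),
        n_deletions=sum(1 for i in indels if i.kind == "deletion"),
    )


def positional_distribution(
    calls: list[MutationCall], reference_len: int, bin_size: int = 1
) -> np.ndarray:
    """Per-position (or per-bin) mutation load as a percentage of all calls.

    The returned vector sums to 100.
    """
    if not calls:
        raise ValidationError("positional_distribution: no calls")
    n_bins = (reference_len + bin_size - 1) // bin_size
    counts = np.zeros(n_bins, dtype=float)
    for call in calls:
        counts[(call.position - 1) // bin_size] += 1
    return counts / counts.sum() * 100.0


def motif_class_counts(calls: list[MutationCall]) -> dict[str, int]:
    """Mutation counts per hotspot/coldspot motif class."""
    out = {cls: 0 for cls in MOTIF_CLASSES}
    for call in calls:
        out[call.motif_class] += 1
    return out


def compare_spectra(a: MutationSpectrum, b: MutationSpectrum) -> dict:
    """Chi-square over the 12 substitution classes plus a two-tailed Fisher
    test on the indel 2x2 (indel events vs analyzed bases).

    Classes with expected counts below 1 are pooled into a rest category.
    """
    if a.total == 0 or b.total == 0:
        raise ValidationError("compare_spectra: all-zero spectrum")
    ca, cb = a.class_counts(), b.class_counts()
    table = np.array([[ca[c] for c in SUB_CLASSES], [cb[c] for c in SUB_CLASSES]])
    if np.array_equal(table[0], table[1]):
        chi2 = _stats.TestResult(method="pearson_chi2", statistic=0.0, p_value=1.0, df=None)
    else:
        chi2 = _stats.chi2_test(_stats.ContingencyTable(table), pooling="rest")
    ia = a.n_insertions + a.n_deletions
    ib = b.n_insertions + b.n_deletions
    fisher = _stats.fisher_exact_2x2(
        [[ia, a.n_bases - ia], [ib, b.n_bases - ib]]
    )
    return {"spectrum_chi2": chi2, "indel_fisher": fisher}
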