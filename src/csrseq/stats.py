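"""Statistical toolbox for junction and mutation comparisons.

Covers the tests applied to class-switch junction data: the exact two-tailed
Fisher test on 2x2 tables (point-probability tail definition, exact rational
arithmetic internally), Pearson chi-square tests with small-expected-cell
pooling, microhomology (overlap) summaries that exclude insertion-bearing
junctions, and ratio normalization with standard deviations combined by the
rules of error propagation for a quotient (the qPCR/ChIP fold-change
contract).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .refdata import ValidationError

DEFAULT_LONG_MH_BIN = 15  # top histogram bin is ">= 15 bp", the long-MH emphasis


@dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValidationError("contingency table entries must be non-negative")
        if self.counts.sum() == 0:
            raise ValidationError("contingency table must have at least one positive entry")


@dataclass(frozen=True)
class RatioWithSD:
    """A measured quantity with its standard deviation."""

    value: float
    sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError("ratio value must be finite")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass
class TestResult:
    """Outcome of a significance test."""

    method: str
    statistic: float | None
    p_value: float
    df: int | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
        }
        for key, value in self.extra.items():
            out[key] = str(value) if isinstance(value, Fraction) else value
        return out


@dataclass
class OverlapSummary:
    """Microhomology summary of a junction set.

    ``mean_overlap`` averages blunt (OL = 0) and microhomology boundaries;
    insertion-bearing junctions are excluded from the mean and histogram and
    counted in ``n_with_insertion`` only.  ``histogram[i]`` counts OL == i for
    i < ``long_bin`` and the last entry counts OL >= ``long_bin``.
    """

    n_junctions: int
    n_with_insertion: int
    mean_overlap: float | None
    histogram: np.ndarray
    long_bin: int = DEFAULT_LONG_MH_BIN

    @property
    def n_scored(self) -> int:
        return self.n_junctions - self.n_with_insertion

    @property
    def bin_labels(self) -> list[str]:
        return [str(i) for i in range(self.long_bin)] + [f"{self.long_bin}+"]

    def as_dict(self) -> dict:
        return {
            "n_junctions": self.n_junctions,
            "n_with_insertion": self.n_with_insertion,
            "n_scored": self.n_scored,
            "mean_overlap": self.mean_overlap,
            "long_bin": self.long_bin,
            "histogram": {lab: int(c) for lab, c in zip(self.bin_labels, self.histogram)},
        }


# ---------------------------------------------------------------------------
# overlap summaries
# ---------------------------------------------------------------------------


def mean_overlap(boundaries: Sequence, long_bin: int = DEFAULT_LONG_MH_BIN) -> OverlapSummary:
    """Summarise the scored boundary of each junction.

    ``boundaries`` is one BoundaryCall-like object per junction (for compound
    junctions, the single donor->acceptor inter-switch boundary).  Insertion
    boundaries are excluded from the mean, mirroring the convention that
    sequences with insertions at the junction do not enter the overlap
    calculation.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise ValidationError("mean_overlap: empty boundary list")
    ols: list[int] = []
    n_ins = 0
    for b in boundaries:
        if b.kind == "insertion":
            n_ins += 1
        else:
            ols.append(int(b.overlap_len))
    hist = np.zeros(long_bin + 1, dtype=np.int64)
    for ol in ols:
        hist[min(ol, long_bin)] += 1
    mean = float(np.mean(ols)) if ols else None
    return OverlapSummary(
        n_junctions=len(boundaries),
        n_with_insertion=n_ins,
        mean_overlap=mean,
        histogram=hist,
        long_bin=long_bin,
    )


def inter_switch_boundary(call, donor_name: str, acceptor_name: str):
    """The single scored boundary of a junction call: the donor->acceptor seam.

    Returns the first boundary whose flanking fragments are donor-region on
    the left and acceptor-region on the right (forward-strand pairs
    preferred); falls back to the first region-changing boundary.
    """
    pairs = list(zip(call.fragments[:-1], call.fragments[1:], call.boundaries))
    for fwd_only in (True, False):
        for left, right, boundary in pairs:
            if left.region_name == donor_name and right.region_name == acceptor_name:
                if fwd_only and not (left.strand == "+" and right.strand == "+"):
                    continue
                return boundary
    for left, right, boundary in pairs:
        if left.region_name != right.region_name:
            return boundary
    raise ValidationError(f"call {call.read_id!r}: no inter-switch boundary found")


# ---------------------------------------------------------------------------
# exact Fisher test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table: ContingencyTable | Sequence[Sequence[int]]) -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table.

    The two-tailed p-value is the sum of hypergeometric probabilities, over
    all tables with the observed margins, whose probability does not exceed
    that of the observed table (point-probability tail).  Computed with exact
    integer arithmetic; the returned p is the float of an exact rational.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    if table.counts.shape != (2, 2):
        raise ValidationError(f"fisher_exact_2x2 needs a 2x2 table, got {table.counts.shape}")
    (a, b), (c, d) = table.counts.tolist()
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    # P(k) = C(r1,k) C(r2,c1-k) / C(n,c1); compare integer numerators.
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    numer = sum(w for w in weights.values() if w <= observed)
    denom = math.comb(n, c1)
    p = Fraction(numer, denom)
    odds = math.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else math.nan
    return TestResult(
        method="fisher_exact_two_tailed",
        statistic=None,
        p_value=float(p),
        extra={"odds_ratio": odds, "p_exact": p},
    )


# ---------------------------------------------------------------------------
# chi-square tests
# ---------------------------------------------------------------------------


def _pool_columns(counts: np.ndarray, mode: str) -> np.ndarray:
    """Pool columns whose total expected count is < 1.

    mode "adjacent": pool into the neighbouring higher-index column (ordered
    bins, e.g. OL histograms; the top bin, having no higher neighbour, pools
    downward).
    mode "rest": merge all low-expectation columns into a single rest column.
    """
    counts = counts.copy()
    while counts.shape[1] > 1:
        total = counts.sum()
        col = counts.sum(axis=0)
        row = counts.sum(axis=1)
        expected = np.outer(row, col) / total
        # a column is poolable when any of its cells has expected < 1
        low = np.where((expected < 1.0).any(axis=0))[0]
        if low.size == 0:
            break
        if mode == "adjacent":
            j = int(low[0])
            tgt = j + 1 if j + 1 < counts.shape[1] else j - 1
            counts[:, tgt] += counts[:, j]
            counts = np.delete(counts, j, axis=1)
        elif mode == "rest":
            if low.size < 2 and counts.shape[1] - low.size >= 1 and low.size == 1:
                # merge the lone low column with the smallest kept column
                order = np.argsort(counts.sum(axis=0))
                j = int(low[0])
                tgt = int(order[0]) if int(order[0]) != j else int(order[1])
                counts[:, tgt] += counts[:, j]
                counts = np.delete(counts, j, axis=1)
            else:
                keep = np.setdiff1d(np.arange(counts.shape[1]), low)
                rest = counts[:, low].sum(axis=1, keepdims=True)
                counts = np.concatenate([counts[:, keep], rest], axis=1)
        else:
            raise ValidationError(f"unknown pooling mode {mode!r}")
    return counts


def chi2_test(
    table: ContingencyTable | Sequence[Sequence[int]],
    pooling: str = "none",
) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction.  Zero-margin rows/columns are dropped with a
    warning.  ``pooling`` ("adjacent" | "rest" | "none") merges columns with
    expected counts below 1 before computing the statistic; df is
    (r-1)(c-1) after pooling.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts.astype(float)
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("chi2_test: dropping zero-margin rows/columns", stacklevel=2)
        counts = counts[row_ok][:, col_ok]
    if pooling != "none":
        counts = _pool_columns(counts, pooling)
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValidationError("chi2_test: degenerate table after dropping/pooling")
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(method="pearson_chi2", statistic=stat, p_value=p, df=df)


def chi2_goodness_of_fit(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Pearson goodness-of-fit chi-square against given expected counts."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValidationError("observed and expected must be 1-d and same length")
    if (exp <= 0).any():
        raise ValidationError("expected counts must be positive")
    exp = exp * obs.sum() / exp.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(method="pearson_chi2_gof", statistic=stat, p_value=p, df=df)


# ---------------------------------------------------------------------------
# ratio normalization with error propagation
# ---------------------------------------------------------------------------


def ratio_with_propagated_sd(num: RatioWithSD, den: RatioWithSD) -> RatioWithSD:
    """Quotient of two measured quantities with SD from error propagation.

    Relative errors add in quadrature:
    sd = |num/den| * sqrt((sd_num/num)^2 + (sd_den/den)^2).
    A zero numerator is handled as sd = sd_num / |den|.
    """
    if den.value == 0:
        raise ValidationError("ratio_with_propagated_sd: zero denominator")
    value = num.value / den.value
    if num.value == 0:
        return RatioWithSD(0.0, num.sd / abs(den.value))
    sd = abs(value) * math.sqrt((num.sd / num.value) ** 2 + (den.sd / den.value) ** 2)
    return RatioWithSD(value, sd)


# ---------------------------------------------------------------------------
# overlap distribution comparison
# ---------------------------------------------------------------------------


def compare_overlap_distributions(a: OverlapSummary, b: OverlapSummary) -> TestResult:
    """Chi-square on two binned OL histograms stacked as a 2 x k table.

    Bins with expected counts < 1 are pooled into the adjacent higher-OL bin.
    Also reports the difference of mean overlaps (b - a).
    """
    if a.long_bin != b.long_bin:
        raise ValidationError("compare_overlap_distributions: incompatible binnings")
    stacked = np.vstack([a.histogram, b.histogram])
    stacked = stacked[:, stacked.sum(axis=0) > 0]  # bins empty in both groups
    if a.n_scored == 0 or b.n_scored == 0:
        raise ValidationError("compare_overlap_distributions: degenerate histogram")
    if np.array_equal(a.histogram, b.histogram):
        result = TestResult(method="pearson_chi2", statistic=0.0, p_value=1.0, df=None)
    else:
        result = chi2_test(ContingencyTable(stacked), pooling="adjacent")
    dmean = None
    if a.mean_overlap is not None and b.mean_overlap is not None:
        dmean = b.mean_overlap - a.mean_overlap
    result.extra["delta_mean_overlap"] = dmean
    return result
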