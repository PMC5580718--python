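"""Evaluate reconstructed haplotypes against truth or reference sequences.

Two instruments:

* :func:`difference_profile` — pairwise global alignment of a query
  haplotype to a reference, with the percentage of pairwise differences
  and the N-content counted in 10-kb bins (bins over 50% N are masked;
  comparisons failing to align over more than 20% of the reference are
  rejected).

* :func:`phase_accuracy` — assign each stretch of two assembled child
  haplotypes to the better-matching of the two true haplotypes, using
  only *informative* positions (where the truths differ), and report the
  base-weighted fraction assigned correctly, the switch count, and the
  lengths of correctly/incorrectly phased segments.  Positions where the
  truths agree carry no phase signal and inherit the flanking
  assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class DifferenceProfile:
    bins: pd.DataFrame  # bin_start, bin_end, pct_diff, n_content, masked, n_aligned
    rejected: bool
    unaligned_fraction: float


def _cigar_ops(cigar: str):
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def difference_profile(
    query: str,
    reference: str,
    bin_bp: int = 10_000,
    max_fail: float = 0.2,
    n_mask_frac: float = 0.5,
) -> DifferenceProfile:
    """Binned pairwise-difference profile of ``query`` against ``reference``.

    Differences are counted over aligned columns where both sides are
    A/C/G/T; columns with an N on either side count toward the bin's
    N-content.  Reference positions falling in alignment gaps are
    unaligned; if their overall fraction exceeds ``max_fail`` the whole
    comparison is rejected.
    """
    res = edlib.align(query, reference, mode="NW", task="path")
    n_bins = (len(reference) + bin_bp - 1) // bin_bp
    mism = np.zeros(n_bins)
    aligned = np.zeros(n_bins)
    n_cols = np.zeros(n_bins)
    total = np.zeros(n_bins)
    unaligned_ref = 0
    qi = ri = 0
    for ln, op in _cigar_ops(res["cigar"]):
        if op in ("=", "X", "M"):
            for _ in range(ln):
                b = ri // bin_bp
                a, c = query[qi], reference[ri]
                total[b] += 1
                if a == "N" or c == "N":
                    n_cols[b] += 1
                else:
                    aligned[b] += 1
                    if a != c:
                        mism[b] += 1
                qi += 1
                ri += 1
        elif op == "I":
            qi += ln
        elif op == "D":
            unaligned_ref += ln
            for _ in range(ln):
                total[ri // bin_bp] += 1
                ri += 1
    unaligned_fraction = unaligned_ref / len(reference)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(aligned > 0, 100.0 * mism / aligned, np.nan)
        n_frac = np.where(total > 0, n_cols / total, np.nan)
    bins = pd.DataFrame(
        dict(
            bin_start=np.arange(n_bins) * bin_bp,
            bin_end=np.minimum((np.arange(n_bins) + 1) * bin_bp, len(reference)),
            pct_diff=pct,
            n_content=n_frac,
            masked=n_frac > n_mask_frac,
            n_aligned=aligned.astype(int),
        )
    )
    return DifferenceProfile(
        bins=bins,
        rejected=unaligned_fraction > max_fail,
        unaligned_fraction=unaligned_fraction,
    )


def sequence_identity(query: str, reference: str) -> float:
    """Identity over aligned substitution columns, ignoring N columns.

    Columns where either side is N carry no information (unphased sites,
    scaffold joins, injected gaps) and are excluded; alignment gap columns
    are ignored as well, so the statistic reflects base-level agreement of
    the sequence both sides actually assert.
    """
    res = edlib.align(query, reference, mode="NW", task="path")
    match = compared = 0
    qi = ri = 0
    for ln, op in _cigar_ops(res["cigar"]):
        if op in ("=", "X", "M"):
            for _ in range(ln):
                a, b = query[qi], reference[ri]
                if a != "N" and b != "N":
                    compared += 1
                    if a == b:
                        match += 1
                qi += 1
                ri += 1
        elif op == "I":
            qi += ln
        elif op == "D":
            ri += ln
    return match / compared if compared else float("nan")


# ---------------------------------------------------------------------------
# Phase accuracy


@dataclass
class PhaseAccuracy:
    fraction_correct: float  # of assigned informative bases
    fraction_incorrect: float  # of assigned informative bases
    fraction_unassigned: float  # of all informative bases
    n_switches: int
    correct_segment_lengths: list[int] = field(default_factory=list)
    incorrect_segment_lengths: list[int] = field(default_factory=list)
    n_informative: int = 0

    @property
    def fractions_of_total(self) -> tuple[float, float, float]:
        """(correct, incorrect, unassigned) over all informative bases; sums to 1."""
        assigned = 1.0 - self.fraction_unassigned
        return (
            self.fraction_correct * assigned,
            self.fraction_incorrect * assigned,
            self.fraction_unassigned,
        )

    def summary(self) -> dict:
        corr = np.array(self.correct_segment_lengths or [0])
        inc = np.array(self.incorrect_segment_lengths or [0])
        return dict(
            fraction_correct=self.fraction_correct,
            n_switches=self.n_switches,
            median_correct_segment=float(np.median(corr)),
            median_incorrect_segment=float(np.median(inc)),
        )


def _informative_columns(truth_a: str, truth_b: str):
    """Substitution columns of the truth-truth alignment: (posA, baseA, baseB)."""
    res = edlib.align(truth_b, truth_a, mode="NW", task="path")
    cols = []
    ai = bi = 0
    for ln, op in _cigar_ops(res["cigar"]):
        if op in ("=", "M"):
            ai += ln
            bi += ln
        elif op == "X":
            for _ in range(ln):
                a, b = truth_a[ai], truth_b[bi]
                if a != "N" and b != "N":
                    cols.append((ai, a, b))
                ai += 1
                bi += 1
        elif op == "I":
            bi += ln
        elif op == "D":
            ai += ln
    return cols


def _chars_at(seq: str, reference: str, ref_positions: np.ndarray) -> list[str | None]:
    """The ``seq`` character aligned to each requested reference position."""
    res = edlib.align(seq, reference, mode="NW", task="path")
    lookup: dict[int, str] = {}
    wanted = set(int(p) for p in ref_positions)
    qi = ri = 0
    for ln, op in _cigar_ops(res["cigar"]):
        if op in ("=", "X", "M"):
            for _ in range(ln):
                if ri in wanted:
                    lookup[ri] = seq[qi]
                qi += 1
                ri += 1
        elif op == "I":
            qi += ln
        elif op == "D":
            ri += ln
    return [lookup.get(int(p)) for p in ref_positions]


def _segments(votes: np.ndarray, positions: np.ndarray, correct_label: int):
    """Compress per-site votes into segments; return lengths and switches."""
    nz = votes != 0
    v = votes[nz]
    p = positions[nz]
    if len(v) == 0:
        return [], [], 0
    correct_lengths: list[int] = []
    incorrect_lengths: list[int] = []
    switches = 0
    seg_start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or v[i] != v[seg_start]:
            length = int(p[i - 1] - p[seg_start] + 1)
            if v[seg_start] == correct_label:
                correct_lengths.append(length)
            else:
                incorrect_lengths.append(length)
            if i < len(v):
                switches += 1
            seg_start = i
    return correct_lengths, incorrect_lengths, switches


def phase_accuracy(
    assembled: tuple[str, str], truth: tuple[str, str]
) -> PhaseAccuracy:
    """Score two assembled child haplotypes against the two true ones.

    Informative positions are the substitution columns of the truth-truth
    alignment.  Each assembled haplotype votes at every informative
    position for the truth haplotype whose base it carries; the global
    label permutation maximizing the number of correct votes is chosen,
    and accuracy is the correct fraction of all cast votes (N or
    mismatching bases are unassigned and excluded from the denominator).
    """
    truth_a, truth_b = truth
    cols = _informative_columns(truth_a, truth_b)
    if not cols:
        raise ValueError("truth haplotypes are indistinguishable")
    pos_a = np.array([c[0] for c in cols])
    base_a = np.array([c[1] for c in cols])
    base_b = np.array([c[2] for c in cols])

    votes = []
    for seq in assembled:
        chars = _chars_at(seq, truth_a, pos_a)
        v = np.zeros(len(cols), dtype=int)
        for i, ch in enumerate(chars):
            if ch is None or ch == "N":
                continue
            if ch == base_a[i]:
                v[i] = 1  # votes truth A
            elif ch == base_b[i]:
                v[i] = 2  # votes truth B
        votes.append(v)

    # choose the label permutation maximizing correct bases
    perm_identity = int((votes[0] == 1).sum() + (votes[1] == 2).sum())
    perm_swapped = int((votes[0] == 2).sum() + (votes[1] == 1).sum())
    labels = (1, 2) if perm_identity >= perm_swapped else (2, 1)
    correct = max(perm_identity, perm_swapped)
    cast = int((votes[0] != 0).sum() + (votes[1] != 0).sum())
    total = 2 * len(cols)

    n_switches = 0
    correct_lengths: list[int] = []
    incorrect_lengths: list[int] = []
    for v, lab in zip(votes, labels):
        c, i, s = _segments(v, pos_a, lab)
        correct_lengths.extend(c)
        incorrect_lengths.extend(i)
        n_switches += s

    return PhaseAccuracy(
        fraction_correct=correct / cast if cast else float("nan"),
        fraction_incorrect=(cast - correct) / cast if cast else float("nan"),
        fraction_unassigned=(total - cast) / total,
        n_switches=n_switches,
        correct_segment_lengths=correct_lengths,
        incorrect_segment_lengths=incorrect_lengths,
        n_informative=len(cols),
    )
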