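"""Paired-end read processing: trimming, merging and dereplication.

Stages mirror a standard amplicon workflow: per-mate adapter/primer removal
and 3' quality trimming (BWA-style running-sum rule at Q20), overlap merging
of each pair (minimum overlap 50 bp), then exact dereplication of merged
contigs at least 379 bp long into per-sample unique sequences with counts
and frequencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import io
from ._seq import N_BYTE, encode, hamming, phred_array, revcomp
from .errors import ReadError

DEFAULT_Q_THRESHOLD = 20
DEFAULT_MIN_OVERLAP = 50
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_MIN_LENGTH = 379


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class MergedRead:
    seq: str
    qual: str
    overlap_len: int
    mismatches_in_overlap: int


@dataclass
class UniqueSequence:
    """A dereplicated sequence with per-sample abundance evidence."""

    seq: str
    count: int
    frequency: float
    sample_id: str = ""


# ---------------------------------------------------------------------------
# trimming


def _quality_cut_index(qual: np.ndarray, q_threshold: int) -> int:
    """3' cut position by the BWA running-sum rule.

    Keep ``seq[:c]`` where c maximizes sum_{i>=c}(q_threshold - q_i) over the
    removed suffix; no cut if no suffix scores positive.  Ties keep the
    longest read.
    """
    if qual.size == 0:
        return 0
    diffs = (q_threshold - qual).astype(np.int64)
    suffix = np.concatenate([np.cumsum(diffs[::-1])[::-1], [0]])
    # argmax with ties resolved toward the largest index (least trimming)
    best = suffix.size - 1 - int(np.argmax(suffix[::-1]))
    return qual.size if suffix[best] <= 0 else best


def _strip_pattern(seq: str, qual: str, pattern: str, max_mismatch_frac: float):
    """Remove one occurrence of ``pattern`` flush with either read end,
    allowing up to ``max_mismatch_frac`` mismatching positions."""
    lp = len(pattern)
    if lp == 0 or len(seq) < lp:
        return seq, qual
    allowed = int(max_mismatch_frac * lp)
    if hamming(seq[:lp], pattern) <= allowed:
        return seq[lp:], qual[lp:]
    if hamming(seq[-lp:], pattern) <= allowed:
        return seq[:-lp], qual[:-lp]
    return seq, qual


def trim_read(
    seq: str,
    qual: str,
    adapters: Sequence[str] = (),
    primers: Sequence[str] = (),
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[str, str]:
    """Adapter -> primer -> quality trimming of a single mate.

    Raises :class:`ReadError` for malformed records (length mismatch or
    non-Phred+33 quality characters); empty output is allowed.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    if len(seq) != len(qual):
        raise ReadError("sequence/quality length mismatch")
    seq = seq.upper()
    try:
        _ = phred_array(qual)
    except ValueError as exc:
        raise ReadError(str(exc)) from exc
    for pat in adapters:
        seq, qual = _strip_pattern(seq, qual, pat.upper(), max_mismatch_frac)
    for pat in primers:
        seq, qual = _strip_pattern(seq, qual, pat.upper(), max_mismatch_frac)
    cut = _quality_cut_index(phred_array(qual), q_threshold)
    return seq[:cut], qual[:cut]


# ---------------------------------------------------------------------------
# merging


def _overlap_scores(s1: np.ndarray, s2rc: np.ndarray, ov: int) -> tuple[int, int]:
    """(matches, mismatches) in the trailing/leading overlap of length ov.
    Positions involving N never count as matches."""
    a = s1[s1.size - ov :]
    b = s2rc[:ov]
    eq = (a == b) & (a != N_BYTE) & (b != N_BYTE)
    matches = int(np.count_nonzero(eq))
    return matches, ov - matches


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MergedRead | None:
    """Overlap-merge one read pair, or return None if no acceptable overlap.

    Mate 2 is reverse-complemented; every overlap length from ``min_overlap``
    up to the shorter mate is scored as (matches - mismatches), ties going to
    the longest overlap.  The winner is rejected if its mismatch fraction
    exceeds ``max_mismatch_frac``.  At overlap mismatches the higher-quality
    base wins (mate 1 on ties, N always loses) with quality the absolute
    difference; at matches the quality is the maximum of the two.
    """
    s1, q1 = pair.seq1.upper(), pair.qual1
    s2 = revcomp(pair.seq2.upper())
    q2 = pair.qual2[::-1]
    if not s1 or not s2:
        return None
    a1, a2 = encode(s1), encode(s2)
    max_ov = min(len(s1), len(s2))
    if max_ov < min_overlap:
        return None

    best_score, best_ov, best_mm = None, None, None
    for ov in range(min_overlap, max_ov + 1):
        matches, mism = _overlap_scores(a1, a2, ov)
        score = matches - mism
        if best_score is None or score >= best_score:  # >= : ties -> longest
            best_score, best_ov, best_mm = score, ov, mism
    if best_ov is None or best_mm / best_ov > max_mismatch_frac:
        return None
    return _build_merged(s1, q1, s2, q2, best_ov, best_mm)


def _build_merged(
    s1: str, q1: str, s2: str, q2: str, ov: int, mism: int
) -> MergedRead:
    from ._seq import decode, phred_string

    l1 = len(s1)
    b1, b2 = encode(s1)[l1 - ov :], encode(s2)[:ov]
    p1 = phred_array(q1)[l1 - ov :]
    p2 = phred_array(q2)[:ov]

    agree = (b1 == b2) & (b1 != N_BYTE)
    # disagreement: higher-quality base wins (mate 1 on ties), N always loses
    pick2 = (p2 > p1) | ((b1 == N_BYTE) & (b2 != N_BYTE))
    pick2 &= ~((b2 == N_BYTE) & (b1 != N_BYTE))
    mid_b = np.where(agree | ~pick2, b1, b2)
    mid_q = np.where(agree, np.maximum(p1, p2), np.abs(p1 - p2))

    seq = s1[: l1 - ov] + decode(mid_b.astype(np.uint8)) + s2[ov:]
    qual = q1[: l1 - ov] + phred_string(mid_q) + q2[ov:]
    return MergedRead(seq=seq, qual=qual, overlap_len=ov, mismatches_in_overlap=mism)


def merge_pairs_batch(
    pairs: Sequence[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[MergedRead | None]:
    """Vectorized :func:`merge_pair` over many pairs.

    Pairs are grouped by (len1, len2); within a group the overlap scan is a
    single numpy comparison per offset.  Output order matches input order and
    each element equals the single-pair result exactly.
    """
    out: list[MergedRead | None] = [None] * len(pairs)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault((len(p.seq1), len(p.seq2)), []).append(i)

    for (l1, l2), idxs in groups.items():
        if l1 == 0 or l2 == 0 or min(l1, l2) < min_overlap:
            continue
        n = len(idxs)
        A = np.empty((n, l1), dtype=np.uint8)
        B = np.empty((n, l2), dtype=np.uint8)
        for row, i in enumerate(idxs):
            A[row] = encode(pairs[i].seq1.upper())
            B[row] = encode(revcomp(pairs[i].seq2.upper()))
        validA = A != N_BYTE
        validB = B != N_BYTE

        best_score = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
        best_ov = np.zeros(n, dtype=np.int64)
        best_mm = np.zeros(n, dtype=np.int64)
        for ov in range(min_overlap, min(l1, l2) + 1):
            eq = (A[:, l1 - ov :] == B[:, :ov]) & validA[:, l1 - ov :] & validB[:, :ov]
            matches = eq.sum(axis=1)
            score = 2 * matches - ov
            take = score >= best_score  # ties -> longest overlap
            best_score[take] = score[take]
            best_ov[take] = ov
            best_mm[take] = ov - matches[take]

        ok = best_mm <= max_mismatch_frac * best_ov
        for row, i in enumerate(idxs):
            if ok[row]:
                p = pairs[i]
                out[i] = _build_merged(
                    p.seq1.upper(),
                    p.qual1,
                    revcomp(p.seq2.upper()),
                    p.qual2[::-1],
                    int(best_ov[row]),
                    int(best_mm[row]),
                )
    return out


# ---------------------------------------------------------------------------
# dereplication


def dereplicate(
    merged: Iterable[str | MergedRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    sample_id: str = "",
) -> tuple[list[UniqueSequence], int]:
    """Collapse identical sequences (upper-cased) into unique records.

    Sequences shorter than ``min_length`` are dropped before grouping; the
    returned denominator is the number of reads surviving that filter.
    Output is sorted by count descending, ties lexicographically by sequence.
    """
    counter: Counter[str] = Counter()
    for m in merged:
        s = (m.seq if isinstance(m, MergedRead) else m).upper()
        if len(s) >= min_length:
            counter[s] += 1
    denominator = sum(counter.values())
    uniques = [
        UniqueSequence(seq=s, count=c, frequency=c / denominator, sample_id=sample_id)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return uniques, denominator


# ---------------------------------------------------------------------------
# per-sample driver


@dataclass
class ProcessResult:
    sample_id: str
    uniques: list[UniqueSequence]
    denominator: int  # "processed reads": merged contigs surviving the length filter
    report: dict


def process_sample(
    r1_path: str | Path,
    r2_path: str | Path,
    sample_id: str,
    adapters: Sequence[str] = (),
    primers_fwd: Sequence[str] = (),
    primers_rev: Sequence[str] = (),
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> ProcessResult:
    """Run trim -> merge -> dereplicate on one sample's FASTQ pair.

    ``primers_fwd``/``primers_rev`` are the patterns stripped from mate 1 and
    mate 2 respectively (typically the locus primer and the reverse
    complement of the opposite primer).  The report preserves exact read
    conservation: pairs_in = merged + merge_rejected + trim_dropped.
    """
    pairs: list[ReadPair] = []
    trim_dropped = 0
    n_in = 0
    for (t1, s1, u1), (t2, s2, u2) in zip(
        io.iter_fastq(r1_path), io.iter_fastq(r2_path)
    ):
        n_in += 1
        try:
            ts1, tq1 = trim_read(s1, u1, adapters, primers_fwd, q_threshold, max_mismatch_frac)
            ts2, tq2 = trim_read(s2, u2, adapters, primers_rev, q_threshold, max_mismatch_frac)
        except ReadError:
            trim_dropped += 1
            continue
        if not ts1 or not ts2:
            trim_dropped += 1
            continue
        pairs.append(ReadPair(t1.split()[0], ts1, tq1, ts2, tq2))

    merged_all = merge_pairs_batch(pairs, min_overlap, max_mismatch_frac)
    merged = [m for m in merged_all if m is not None]
    merge_rejected = len(pairs) - len(merged)

    uniques, denominator = dereplicate(merged, min_length, sample_id)
    report = {
        "sample_id": sample_id,
        "pairs_in": n_in,
        "trim_dropped": trim_dropped,
        "merged": len(merged),
        "merge_rejected": merge_rejected,
        "length_filtered_out": len(merged) - denominator,
        "processed_reads": denominator,
        "merged_contigs": len(merged),
        "n_unique": len(uniques),
    }
    return ProcessResult(sample_id, uniques, denominator, report)


def uniques_to_frame(uniques: Sequence[UniqueSequence]):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [u.sample_id for u in uniques],
            "seq": [u.seq for u in uniques],
            "count": [u.count for u in uniques],
            "frequency": [u.frequency for u in uniques],
        }
    )
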