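"""Chimera removal, positive-control error calibration and threshold filter.

This is the statistical core of the pipeline: tissue-derived positive
controls of known haplotype measure the combined PCR + sequencing error as
the frequency of the most abundant unique sequence that is *not* the known
haplotype; the maximum rate across controls, rounded up to the next whole
percent, becomes the per-sample frequency threshold below which unique
sequences are treated as error or non-target.  Chimeric amplicons are
flagged beforehand by a deterministic two-parent crossover test in the
spirit of UCHIME de novo (a simplified, exactly-verifiable variant, not a
clone of the chunked heuristic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._seq import encode
from .errors import CalibrationError
from .readproc import UniqueSequence

DEFAULT_ABUNDANCE_SKEW = 2.0
DEFAULT_MIN_DIFFS_TO_PARENT = 2


# ---------------------------------------------------------------------------
# chimera detection


def detect_chimeras(
    uniques: Sequence[UniqueSequence],
    abundance_skew: float = DEFAULT_ABUNDANCE_SKEW,
    min_diffs_to_parent: int = DEFAULT_MIN_DIFFS_TO_PARENT,
) -> list[bool]:
    """Flag unique sequences explainable as two-parent single-breakpoint
    crossovers of more abundant, earlier-accepted sequences.

    Processing descends by abundance (input must be sorted by count
    descending).  A candidate is chimeric iff two previously accepted
    parents exist, each with count >= ``abundance_skew`` x the candidate's
    count, some breakpoint k makes parentA[:k] + parentB[k:] reproduce the
    candidate exactly, and the candidate differs from each single parent by
    at least ``min_diffs_to_parent`` substitutions.  Flagged sequences are
    not available as parents for later candidates.
    """
    counts = [u.count for u in uniques]
    if counts != sorted(counts, reverse=True):
        raise ValueError("uniques must be sorted by count descending")

    flags = [False] * len(uniques)
    # group by length: a perfect crossover of equal-length parents has their length
    by_len: dict[int, list[int]] = {}
    for i, u in enumerate(uniques):
        by_len.setdefault(len(u.seq), []).append(i)

    for L, idxs in by_len.items():
        if L == 0 or len(idxs) < 3:
            continue
        mat = np.stack([encode(uniques[i].seq) for i in idxs])
        cnt = np.array([uniques[i].count for i in idxs], dtype=np.float64)
        grp_flags = _flag_group(mat, cnt, L, abundance_skew, min_diffs_to_parent)
        for row, f in enumerate(grp_flags):
            flags[idxs[row]] = bool(f)
    return flags


def _crossover_exists(neq: np.ndarray, valid: np.ndarray, L: int) -> np.ndarray:
    """Per-candidate crossover test from a parent-mismatch tensor.

    ``neq``: (n_cand, n_parent, L) candidate-vs-parent disagreement;
    ``valid``: (n_cand, n_parent) parents with enough diffs.  A candidate is
    flagged iff its max prefix agreement plus max suffix agreement over
    valid parents spans L (a single parent can never span L with >=2 diffs).
    """
    if neq.shape[1] == 0:
        return np.zeros(neq.shape[0], dtype=bool)
    any_diff = neq.any(axis=2)
    lp = np.where(any_diff, np.argmax(neq, axis=2), L)
    ls = np.where(any_diff, np.argmax(neq[:, :, ::-1], axis=2), L)
    lp = np.where(valid, lp, -1)
    ls = np.where(valid, ls, -1)
    ok = valid.sum(axis=1) >= 2
    return ok & (lp.max(axis=1) + ls.max(axis=1) >= L)


def _flag_group(
    mat: np.ndarray,
    cnt: np.ndarray,
    L: int,
    abundance_skew: float,
    min_diffs: int,
    chunk: int = 256,
) -> np.ndarray:
    n = mat.shape[0]
    flags = np.zeros(n, dtype=bool)
    if abundance_skew > 1.0:
        # counts are non-increasing, so every candidate in a count class has
        # the same parent pool: earlier-accepted rows with count >= skew*c,
        # all of which lie in strictly earlier classes.
        starts = [0] + [i for i in range(1, n) if cnt[i] != cnt[i - 1]] + [n]
        for s, e in zip(starts[:-1], starts[1:]):
            need = abundance_skew * cnt[s]
            pool = np.flatnonzero((cnt >= need) & ~flags & (np.arange(n) < s))
            if pool.size < 2:
                continue
            P = mat[pool]  # (n_parent, L)
            for cs in range(s, e, chunk):
                rows = slice(cs, min(cs + chunk, e))
                neq = mat[rows, None, :] != P[None, :, :]
                valid = neq.sum(axis=2) >= min_diffs
                flags[rows] = _crossover_exists(neq, valid, L)
    else:
        # skew <= 1: parents may share the candidate's count class; fall back
        # to strict sequential processing.
        accepted: list[int] = []
        for row in range(n):
            pool = np.array(
                [r for r in accepted if cnt[r] >= abundance_skew * cnt[row]],
                dtype=np.int64,
            )
            if pool.size >= 2:
                neq = mat[row][None, None, :] != mat[pool][None, :, :]
                valid = neq.sum(axis=2) >= min_diffs
                flags[row] = _crossover_exists(neq, valid, L)[0]
            if not flags[row]:
                accepted.append(row)
    return flags


# ---------------------------------------------------------------------------
# error calibration


def ceil_percent(rate: float) -> float:
    """Round an error rate up to the next whole percent (0.017 -> 0.02)."""
    return math.ceil(rate * 100.0 - 1e-9) / 100.0


def raw_max(rate: float) -> float:
    return rate


ROUNDING_RULES: dict[str, Callable[[float], float]] = {
    "ceil-percent": ceil_percent,
    "raw-max": raw_max,
}


@dataclass
class ErrorCalibration:
    """Positive-control error rates and the derived frequency threshold."""

    per_control_rate: dict[str, float]
    max_rate: float
    mean_rate: float
    sd_rate: float
    threshold: float
    rounding: str = "ceil-percent"
    excluded_controls: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_control_rate": self.per_control_rate,
            "max_rate": self.max_rate,
            "mean_rate": self.mean_rate,
            "sd_rate": self.sd_rate,
            "threshold": self.threshold,
            "rounding": self.rounding,
            "excluded_controls": self.excluded_controls,
        }

    def summary(self) -> str:
        lines = ["Positive-control error calibration", "-" * 40]
        for cid, r in sorted(self.per_control_rate.items()):
            lines.append(f"  {cid:<12s} error rate {100 * r:6.3f}%")
        lines += [
            f"  max  {100 * self.max_rate:.3f}%   mean {100 * self.mean_rate:.3f}%"
            f"   sd {100 * self.sd_rate:.3f}%",
            f"  threshold ({self.rounding}): {100 * self.threshold:.2f}% of processed reads",
        ]
        return "\n".join(lines)


def calibrate_error(
    controls: Mapping[str, Sequence[UniqueSequence]],
    known: Mapping[str, str],
    denominators: Mapping[str, int] | None = None,
    rounding: str = "ceil-percent",
) -> ErrorCalibration:
    """Derive the error threshold from positive-control libraries.

    For each control, the rate is the read count of the most abundant unique
    sequence whose sequence is not exactly the known haplotype, divided by
    the control's processed-read denominator.  The threshold is the rounding
    rule applied to the maximum rate across controls.

    ``known`` maps control id -> known haplotype *sequence*; "less than 100%
    identity" is exact string inequality in dereplicated sequence space.
    Controls with zero surviving reads are excluded with a warning; if all
    are empty a :class:`CalibrationError` is raised.
    """
    if not controls:
        raise CalibrationError("no positive controls supplied")
    if rounding not in ROUNDING_RULES:
        raise ValueError(f"unknown rounding rule {rounding!r}")

    rates: dict[str, float] = {}
    excluded: list[str] = []
    for cid, uniques in controls.items():
        if cid not in known:
            raise CalibrationError(f"no known haplotype for control {cid!r}")
        denom = (
            denominators[cid]
            if denominators is not None
            else sum(u.count for u in uniques)
        )
        if denom <= 0 or not uniques:
            warnings.warn(f"positive control {cid} has no surviving reads; excluded")
            excluded.append(cid)
            continue
        known_seq = known[cid].upper()
        err = [u for u in uniques if u.seq.upper() != known_seq]
        top_err = max(err, key=lambda u: u.count, default=None)
        rates[cid] = (top_err.count / denom) if top_err is not None else 0.0
    if not rates:
        raise CalibrationError("all positive controls were empty")

    vals = np.array(list(rates.values()), dtype=float)
    max_rate = float(vals.max())
    mean_rate = float(vals.mean())
    sd_rate = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    threshold = ROUNDING_RULES[rounding](max_rate)
    return ErrorCalibration(
        per_control_rate=rates,
        max_rate=max_rate,
        mean_rate=mean_rate,
        sd_rate=sd_rate,
        threshold=threshold,
        rounding=rounding,
        excluded_controls=excluded,
    )


# ---------------------------------------------------------------------------
# threshold filter


def apply_threshold(
    uniques: Sequence[UniqueSequence],
    threshold: float,
    chimera_flags: Sequence[bool] | None = None,
) -> list[UniqueSequence]:
    """Retain unique sequences with frequency >= threshold.

    Sequences strictly below the threshold are removed, as are any flagged
    chimeric regardless of frequency.  Idempotent and monotone in the
    threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if chimera_flags is None:
        chimera_flags = [False] * len(uniques)
    if len(chimera_flags) != len(uniques):
        raise ValueError("chimera_flags length mismatch")
    return [
        u
        for u, chim in zip(uniques, chimera_flags)
        if not chim and u.frequency >= threshold
    ]
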