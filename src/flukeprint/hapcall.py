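"""Assignment of retained sequences to reference haplotypes.

Each retained (threshold-filtered) unique sequence is globally aligned
against a local database of known control-region haplotypes (both strands);
exact matches are called as the known haplotype, near matches supported by a
sufficient read fraction become provisional novel haplotypes, and everything
else is rejected as low-evidence or non-target.  Samples with no accepted
sequence are reported as failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from . import io
from ._seq import revcomp
from .errors import ConfigurationError
from .readproc import UniqueSequence

DEFAULT_NOVEL_MIN_FRACTION = 0.20
DEFAULT_NONTARGET_IDENTITY_FLOOR = 0.98

STATUS_KNOWN = "known"
STATUS_NOVEL = "novel"
STATUS_REJECTED_LOW_FRACTION = "rejected_low_fraction"
STATUS_REJECTED_NONTARGET = "rejected_nontarget"
STATUS_FAILED = "failed_sample"


@dataclass
class ReferenceDB:
    """Local database of known haplotypes (unique ids, distinct sequences)."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ConfigurationError("reference database is empty")
        self.seqs = {k: v.upper() for k, v in self.seqs.items()}
        rev = {}
        for hid, s in self.seqs.items():
            if s in rev:
                raise ConfigurationError(
                    f"reference sequences must be distinct ({hid} == {rev[s]})"
                )
            rev[s] = hid
        self._by_seq = rev

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        return cls(io.read_fasta(path))

    @property
    def alignment_length(self) -> int:
        return min(len(s) for s in self.seqs.values())

    def exact_lookup(self, seq: str) -> str | None:
        return self._by_seq.get(seq.upper())

    def __len__(self) -> int:
        return len(self.seqs)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _identity(aligner: Align.PairwiseAligner, ref: str, query: str) -> tuple[float, int]:
    aln = aligner.align(ref, query)[0]
    counts = aln.counts()
    columns = aln.length
    return (counts.identities / columns if columns else 0.0), columns


def best_reference_hit(
    query: str, db: ReferenceDB
) -> tuple[str, float, int]:
    """Best global-alignment hit of a query against the reference panel.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1; identity is
    matching columns / alignment columns.  Both the query and its reverse
    complement are tried; ties go to the lexicographically smallest
    haplotype id.  Returns (haplotype_id, identity, alignment_columns).
    """
    if len(db) == 0:
        raise ConfigurationError("empty reference database")
    query = query.upper()
    exact = db.exact_lookup(query) or db.exact_lookup(revcomp(query))
    if exact is not None:
        return exact, 1.0, len(query)

    aligner = _make_aligner()
    rc = revcomp(query)
    best: tuple[str, float, int] | None = None
    for hid in sorted(db.seqs):
        ref = db.seqs[hid]
        ident_f, cols_f = _identity(aligner, ref, query)
        ident_r, cols_r = _identity(aligner, ref, rc)
        ident, cols = (ident_f, cols_f) if ident_f >= ident_r else (ident_r, cols_r)
        if best is None or ident > best[1] + 1e-12:
            best = (hid, ident, cols)
    assert best is not None
    return best


@dataclass
class HaplotypeCall:
    sample_id: str
    haplotype_id: str | None
    status: str
    best_hit_id: str | None
    identity: float
    read_count: int
    fraction_of_processed_reads: float
    rank: str | None  # "primary" / "secondary" for accepted calls
    seq: str | None = None


def call_sample(
    sample_id: str,
    retained: Sequence[UniqueSequence],
    db: ReferenceDB,
    novel_min_fraction: float = DEFAULT_NOVEL_MIN_FRACTION,
    nontarget_identity_floor: float = DEFAULT_NONTARGET_IDENTITY_FLOOR,
) -> list[HaplotypeCall]:
    """Call haplotypes for one sample from its retained unique sequences.

    Decision rules per sequence: identity 1.0 -> known; identity in
    [floor, 1) with read fraction >= ``novel_min_fraction`` -> provisional
    novel haplotype; identity >= floor but fraction below -> rejected (low
    fraction); identity < floor -> rejected non-target.  The most abundant
    accepted call is ranked primary, the rest secondary; a sample with no
    accepted call yields a single failed_sample record.
    """
    ordered = sorted(retained, key=lambda u: (-u.count, u.seq))
    calls: list[HaplotypeCall] = []
    novel_n = 0
    for u in ordered:
        hit_id, identity, _cols = best_reference_hit(u.seq, db)
        if identity >= 1.0 - 1e-12:
            status, hap_id = STATUS_KNOWN, hit_id
        elif identity >= nontarget_identity_floor:
            if u.frequency >= novel_min_fraction:
                novel_n += 1
                status, hap_id = STATUS_NOVEL, f"novel-{novel_n}"
            else:
                status, hap_id = STATUS_REJECTED_LOW_FRACTION, None
        else:
            status, hap_id = STATUS_REJECTED_NONTARGET, None
        calls.append(
            HaplotypeCall(
                sample_id=sample_id,
                haplotype_id=hap_id,
                status=status,
                best_hit_id=hit_id,
                identity=identity,
                read_count=u.count,
                fraction_of_processed_reads=u.frequency,
                rank=None,
                seq=u.seq,
            )
        )

    accepted = [c for c in calls if c.status in (STATUS_KNOWN, STATUS_NOVEL)]
    if not accepted:
        evidence = calls[0] if calls else None
        return [
            HaplotypeCall(
                sample_id=sample_id,
                haplotype_id=None,
                status=STATUS_FAILED,
                best_hit_id=evidence.best_hit_id if evidence else None,
                identity=evidence.identity if evidence else 0.0,
                read_count=evidence.read_count if evidence else 0,
                fraction_of_processed_reads=(
                    evidence.fraction_of_processed_reads if evidence else 0.0
                ),
                rank=None,
                seq=evidence.seq if evidence else None,
            )
        ]
    accepted[0].rank = "primary"
    for c in accepted[1:]:
        c.rank = "secondary"
    return calls


@dataclass
class CohortCalls:
    """Cohort-level call table with a registry of novel haplotype sequences."""

    calls: list[HaplotypeCall]
    novel_seqs: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in self.calls],
                "haplotype_id": [c.haplotype_id for c in self.calls],
                "status": [c.status for c in self.calls],
                "best_hit_id": [c.best_hit_id for c in self.calls],
                "identity": [c.identity for c in self.calls],
                "read_count": [c.read_count for c in self.calls],
                "fraction_of_processed_reads": [
                    c.fraction_of_processed_reads for c in self.calls
                ],
                "rank": [c.rank for c in self.calls],
                "seq": [c.seq for c in self.calls],
            }
        )


def call_cohort(
    retained_by_sample: Mapping[str, Sequence[UniqueSequence]],
    db: ReferenceDB,
    novel_min_fraction: float = DEFAULT_NOVEL_MIN_FRACTION,
    nontarget_identity_floor: float = DEFAULT_NONTARGET_IDENTITY_FLOOR,
) -> CohortCalls:
    """Call every sample and unify provisional novel ids across the cohort.

    Samples are processed in sorted id order; distinct novel sequences are
    numbered novel-1, novel-2, ... in first-seen order, so identical novel
    sequences found in different samples share one id (deterministic).
    """
    registry: dict[str, str] = {}
    all_calls: list[HaplotypeCall] = []
    for sid in sorted(retained_by_sample):
        for call in call_sample(
            sid,
            retained_by_sample[sid],
            db,
            novel_min_fraction,
            nontarget_identity_floor,
        ):
            if call.status == STATUS_NOVEL:
                if call.seq not in registry:
                    registry[call.seq] = f"novel-{len(registry) + 1}"
                call.haplotype_id = registry[call.seq]
            all_calls.append(call)
    return CohortCalls(calls=all_calls, novel_seqs={v: k for k, v in registry.items()})
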