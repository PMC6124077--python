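"""Synthetic eDNA amplicon cohort generator with known ground truth.

Emulates a targeted mitochondrial control-region amplicon survey of harbour
porpoise in stratified coastal waters: a local reference database of known
haplotypes, per-sample paired-end MiSeq-style reads (water samples carrying
one or two haplotypes, tissue-derived positive controls of known haplotype,
read-free negative controls), PCR chimeras, non-target contaminant reads and
primer-decorated read layouts, plus a qPCR plate simulated from a known
standard curve.  Every stochastic choice flows from a single integer seed, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from ._seq import BASE_BYTES, indices_to_str, revcomp
from .errors import ConfigurationError

# Minimum overlap the downstream merge stage requires; the config invariant
# 2*read_length - amplicon_length >= this keeps simulated pairs mergeable.
MERGE_MIN_OVERLAP = 50

#: Locus-specific amplification primers (5'->3', forward / reverse).
FORWARD_PRIMER = "TACTCCTTGAAAAAGCCCATTGTA"
REVERSE_PRIMER = "ATGGTCCTGAAGTAAGAACCAGATG"

ROLE_EDNA = "edna"
ROLE_POSITIVE = "positive_control"
ROLE_NEGATIVE = "negative_control"


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults describe the emulated survey: a 58-haplotype reference panel,
    ~450 bp control-region amplicon sequenced 2x300, four tissue positive
    controls, two strata of water samples with one or (10% of the time) two
    contributing animals, and 0.3%/base substitution error.
    """

    seed: int = 0
    n_haplotypes: int = 58
    amplicon_length_bp: int = 450
    read_length_bp: int = 300
    per_base_error_rate: float = 0.003
    chimera_fraction: float = 0.02
    contaminant_fraction: float = 0.01
    reads_per_sample: int = 10_000
    n_samples: int = 20
    n_positive_controls: int = 4
    n_negative_controls: int = 2
    n_strata: int = 2
    n_circulating_haplotypes: int = 8
    stratum_haplotype_freqs: Sequence[Sequence[float]] | None = None
    multi_haplotype_prob: float = 0.10
    minor_fraction_range: tuple[float, float] = (0.20, 0.45)
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    min_subs_from_ancestor: int = 1
    max_subs_from_ancestor: int = 30

    def __post_init__(self) -> None:
        probs = {
            "per_base_error_rate": self.per_base_error_rate,
            "chimera_fraction": self.chimera_fraction,
            "contaminant_fraction": self.contaminant_fraction,
            "multi_haplotype_prob": self.multi_haplotype_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.minor_fraction_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                "minor_fraction_range must lie within (0, 0.5], "
                f"got {self.minor_fraction_range}"
            )
        if self.read_length_bp < 50:
            raise ConfigurationError("read_length_bp must be >= 50")
        if 2 * self.read_length_bp - self.amplicon_length_bp < MERGE_MIN_OVERLAP:
            raise ConfigurationError(
                "read pairs would not overlap by the merge minimum: need "
                f"2*read_length - amplicon_length >= {MERGE_MIN_OVERLAP}"
            )
        if self.n_haplotypes < 1:
            raise ConfigurationError("n_haplotypes must be >= 1")
        if self.stratum_haplotype_freqs is not None:
            freqs = [np.asarray(v, dtype=float) for v in self.stratum_haplotype_freqs]
            if len(freqs) != self.n_strata:
                raise ConfigurationError(
                    "stratum_haplotype_freqs must provide one vector per stratum"
                )
            for v in freqs:
                if v.ndim != 1 or v.size == 0 or (v < 0).any():
                    raise ConfigurationError("frequency vectors must be non-negative 1-D")
                if abs(v.sum() - 1.0) > 1e-9:
                    raise ConfigurationError("frequency vectors must sum to 1 within 1e-9")
            self.stratum_haplotype_freqs = [v.tolist() for v in freqs]

    def to_json(self, path: str | Path) -> None:
        io.write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = io.read_json(path)
        data["minor_fraction_range"] = tuple(data["minor_fraction_range"])
        return cls(**data)


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    role: str
    stratum: str
    haplotypes: dict[str, float]  # haplotype id -> mixing proportion
    n_reads: int
    n_chimeric: int = 0
    n_contaminant: int = 0

    def __post_init__(self) -> None:
        if self.haplotypes:
            total = sum(self.haplotypes.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError("mixing proportions must sum to 1")
        if self.role == ROLE_NEGATIVE and self.n_reads != 0:
            raise ConfigurationError("negative controls must emit zero target reads")


@dataclass
class TruthTable:
    entries: list[SampleTruth]

    def __iter__(self):
        return iter(self.entries)

    def by_id(self) -> dict[str, SampleTruth]:
        return {e.sample_id: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "sample_id": e.sample_id,
                    "role": e.role,
                    "stratum": e.stratum,
                    "haplotypes": ";".join(
                        f"{h}:{p:.6f}" for h, p in sorted(e.haplotypes.items())
                    ),
                    "n_reads": e.n_reads,
                    "n_chimeric": e.n_chimeric,
                    "n_contaminant": e.n_contaminant,
                }
            )
        return pd.DataFrame(rows)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_reference_db(
    config: SimConfig, fasta_path: str | Path | None = None
) -> dict[str, str]:
    """Create the reference panel of known control-region haplotypes.

    Haplotypes are ``min_subs_from_ancestor``..``max_subs_from_ancestor``
    substitutions away from a common random ancestral sequence, pairwise
    distinct, equal length, with stable ids CR001, CR002, ...
    """
    L = config.amplicon_length_bp
    if L < 379:
        raise ConfigurationError("amplicon_length_bp must be >= 379")
    if config.n_haplotypes > 4**min(L, 32):  # 4^32 already dwarfs any real panel
        raise ConfigurationError("cannot make that many distinct sequences")
    rng = _stream(config.seed, 0)
    ancestor = rng.integers(0, 4, size=L)
    seqs: dict[str, str] = {}
    seen: set[str] = set()
    for i in range(config.n_haplotypes):
        for _attempt in range(1000):
            k = int(
                rng.integers(
                    config.min_subs_from_ancestor, config.max_subs_from_ancestor + 1
                )
            )
            pos = rng.choice(L, size=k, replace=False)
            hap = ancestor.copy()
            hap[pos] = (hap[pos] + rng.integers(1, 4, size=k)) % 4
            s = indices_to_str(hap)
            if s not in seen:
                break
        else:
            raise ConfigurationError("could not generate pairwise-distinct haplotypes")
        seen.add(s)
        seqs[f"CR{i + 1:03d}"] = s
    if fasta_path is not None:
        io.write_fasta(fasta_path, seqs)
    return seqs


def _contaminant_sequence(config: SimConfig, refs: dict[str, str]) -> str:
    """Random non-target sequence (<70% identity to every reference)."""
    rng = _stream(config.seed, 1)
    L = config.amplicon_length_bp
    ref_arrays = [np.frombuffer(s.encode(), dtype=np.uint8) for s in refs.values()]
    for _ in range(100):
        cand = BASE_BYTES[rng.integers(0, 4, size=L)]
        if all(
            np.count_nonzero(cand == r) / L < 0.70 for r in ref_arrays if r.size == L
        ):
            return cand.tobytes().decode()
    raise ConfigurationError("could not draw a contaminant below 70% identity")


def build_truth(config: SimConfig, refs: dict[str, str]) -> tuple[TruthTable, pd.DataFrame]:
    """Assign strata, haplotype mixtures and metadata for the whole cohort.

    Returns the truth table and a sample-metadata frame (sample id, role,
    known haplotype for controls, stratum, latitude/longitude, date).
    """
    rng = _stream(config.seed, 2)
    hap_ids = list(refs)
    circ = hap_ids[: min(config.n_circulating_haplotypes, len(hap_ids))]
    if config.stratum_haplotype_freqs is None:
        freqs = [rng.dirichlet(np.ones(len(circ))) for _ in range(config.n_strata)]
    else:
        freqs = [np.asarray(v, dtype=float) for v in config.stratum_haplotype_freqs]
        circ = hap_ids[: len(freqs[0])]
        if any(len(v) != len(circ) for v in freqs):
            raise ConfigurationError("frequency vectors must match haplotype count")

    entries: list[SampleTruth] = []
    meta_rows: list[dict] = []
    start = pd.Timestamp("2016-06-01")

    def _meta(sample_id, role, known, stratum):
        meta_rows.append(
            {
                "sample_id": sample_id,
                "role": role,
                "known_haplotype": known,
                "stratum": stratum,
                "latitude": round(54.5 + 4.5 * rng.random(), 5),
                "longitude": round(-136.0 + 5.5 * rng.random(), 5),
                "date": (start + pd.Timedelta(days=int(rng.integers(0, 120)))).date().isoformat(),
            }
        )

    for i in range(config.n_samples):
        sid = f"HP{i + 1:03d}"
        stratum_idx = i % config.n_strata
        stratum = f"S{stratum_idx + 1}"
        f = freqs[stratum_idx]
        primary = circ[int(rng.choice(len(circ), p=f))]
        haps = {primary: 1.0}
        if len(circ) > 1 and rng.random() < config.multi_haplotype_prob:
            others = [h for h in circ if h != primary]
            w = np.array([f[circ.index(h)] for h in others])
            w = w / w.sum() if w.sum() > 0 else np.full(len(others), 1 / len(others))
            minor = others[int(rng.choice(len(others), p=w))]
            lo, hi = config.minor_fraction_range
            m = float(rng.uniform(lo, hi))
            haps = {primary: 1.0 - m, minor: m}
        entries.append(SampleTruth(sid, ROLE_EDNA, stratum, haps, config.reads_per_sample))
        _meta(sid, ROLE_EDNA, "", stratum)

    for i in range(config.n_positive_controls):
        sid = f"POS{i + 1:02d}"
        hap = hap_ids[i % len(hap_ids)]
        entries.append(SampleTruth(sid, ROLE_POSITIVE, "", {hap: 1.0}, config.reads_per_sample))
        _meta(sid, ROLE_POSITIVE, hap, "")

    for i in range(config.n_negative_controls):
        sid = f"NEG{i + 1:02d}"
        entries.append(SampleTruth(sid, ROLE_NEGATIVE, "", {}, 0))
        _meta(sid, ROLE_NEGATIVE, "", "")

    return TruthTable(entries), pd.DataFrame(meta_rows)


def _quality_char(rate: float) -> str:
    q = 40 if rate <= 0 else min(40, round(-10.0 * math.log10(rate)))
    return chr(33 + q)


def simulate_sample_reads(
    config: SimConfig,
    truth: SampleTruth,
    refs: dict[str, str],
    contaminant: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Simulate the paired-end reads for one sample.

    Each read pair derives from one template — a primer-flanked haplotype,
    a single-breakpoint two-parent chimera, or the cohort contaminant.  The
    forward read is the first ``read_length_bp`` bases of the template, the
    reverse read is the reverse complement of the last ``read_length_bp``
    bases; substitution errors hit each mate independently at
    ``per_base_error_rate`` and qualities are the matching constant Phred
    score.  Realized chimera/contaminant counts are written back onto the
    truth entry.

    Returns (R1 records, R2 records) as (title, seq, qual) tuples.
    """
    if rng is None:
        rng = _stream(config.seed, 3, _sample_stream_key(truth.sample_id))
    n = truth.n_reads
    truth.n_chimeric = 0
    truth.n_contaminant = 0
    if n == 0:
        return [], []
    for h in truth.haplotypes:
        if h not in refs:
            raise ConfigurationError(f"unknown haplotype id {h!r} in truth table")

    fwd = config.forward_primer.upper()
    rev = config.reverse_primer.upper()
    hap_ids = sorted(truth.haplotypes)
    props = np.array([truth.haplotypes[h] for h in hap_ids])
    L_hap = config.amplicon_length_bp
    Lt = len(fwd) + L_hap + len(rev)
    if Lt < config.read_length_bp:
        raise ConfigurationError("template shorter than the read length")

    # base-index (0..3) encodings
    base_index = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i

    def enc(s: str) -> np.ndarray:
        return base_index[np.frombuffer(s.encode(), dtype=np.uint8)]

    hap_arr = np.stack([enc(refs[h]) for h in hap_ids])
    fwd_arr, rev_rc_arr = enc(fwd), enc(revcomp(rev))

    u = rng.random(n)
    is_chim = u < config.chimera_fraction
    is_cont = (~is_chim) & (u < config.chimera_fraction + config.contaminant_fraction)
    hap_choice = rng.choice(len(hap_ids), size=n, p=props)

    inserts = hap_arr[hap_choice]  # (n, L_hap)
    if is_chim.any():
        nc = int(is_chim.sum())
        pa = rng.choice(len(hap_ids), size=nc, p=props)
        pb = rng.choice(len(hap_ids), size=nc, p=props)
        bp = rng.integers(50, L_hap - 50 + 1, size=nc)
        chim = hap_arr[pa].copy()
        col = np.arange(L_hap)
        take_b = col[None, :] >= bp[:, None]
        chim[take_b] = hap_arr[pb][take_b]
        inserts[is_chim] = chim
    if is_cont.any():
        if contaminant is None:
            contaminant = _contaminant_sequence(config, refs)
        inserts[is_cont] = enc(contaminant)

    templates = np.concatenate(
        [
            np.broadcast_to(fwd_arr, (n, len(fwd))),
            inserts,
            np.broadcast_to(rev_rc_arr, (n, len(rev))),
        ],
        axis=1,
    )

    def _read_with_errors(mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        if config.per_base_error_rate > 0:
            mask = rng.random(out.shape) < config.per_base_error_rate
            if mask.any():
                out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        return out

    r1 = _read_with_errors(templates[:, : config.read_length_bp])
    # reverse read: revcomp of the template's last read_length bases
    rc_templates = 3 - templates[:, ::-1]
    r2 = _read_with_errors(rc_templates[:, : config.read_length_bp])

    qual = _quality_char(config.per_base_error_rate) * config.read_length_bp
    recs1, recs2 = [], []
    for i in range(n):
        title = f"{truth.sample_id}.{i + 1}"
        recs1.append((title, indices_to_str(r1[i]), qual))
        recs2.append((title, indices_to_str(r2[i]), qual))

    truth.n_chimeric = int(is_chim.sum())
    truth.n_contaminant = int(is_cont.sum())
    return recs1, recs2


def _sample_stream_key(sample_id: str) -> int:
    # stable small integer from the sample id (ASCII sum is enough: ids are
    # unique short strings and the key is combined with the spawn hierarchy)
    return sum((i + 1) * ord(c) for i, c in enumerate(sample_id)) % (2**31)


def simulate_qpcr_plate(
    standards: Sequence[float],
    unknowns: Sequence[tuple[str, float]],
    slope: float = -3.32,
    intercept: float = 24.0,
    noise_sd: float = 0.2,
    detection_cutoff: float = 45.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate Ct values from a known standard curve.

    Ct = slope*log10(conc) + intercept + Normal(0, noise_sd); wells whose Ct
    exceeds ``detection_cutoff`` (or with conc <= 0) are flagged undetermined
    (Ct = NaN).  ``unknowns`` are (sample_id, true concentration) pairs;
    non-amplifying negatives may be passed with concentration 0.
    """
    if slope >= 0:
        raise ConfigurationError("standard-curve slope must be negative")
    if any(c <= 0 for c in standards):
        raise ConfigurationError("standard concentrations must be > 0")
    if rng is None:
        rng = np.random.default_rng(0)

    rows = []
    well = 1

    def _ct(conc: float) -> float:
        if conc <= 0:
            return math.nan
        ct = slope * math.log10(conc) + intercept + rng.normal(0.0, noise_sd)
        return ct if ct <= detection_cutoff else math.nan

    for conc in standards:
        ct = _ct(conc)
        rows.append(
            {
                "well": f"W{well:03d}",
                "sample_id": f"STD{well:02d}",
                "role": "standard",
                "known_concentration": conc,
                "ct": ct,
            }
        )
        well += 1
    for sid, conc in unknowns:
        ct = _ct(conc)
        rows.append(
            {
                "well": f"W{well:03d}",
                "sample_id": sid,
                "role": "unknown",
                "known_concentration": math.nan,
                "ct": ct,
            }
        )
        well += 1
    return pd.DataFrame(rows)


DEFAULT_STANDARDS = [1.3 * 10**-k for k in range(6)]  # 1.3 ng/ul .. 1.3e-5 ng/ul


@dataclass
class SimulatedDataset:
    """Paths and in-memory truth for one simulated cohort."""

    outdir: Path
    reference_fasta: Path
    reads_dir: Path
    metadata_tsv: Path
    truth_tsv: Path
    qpcr_tsv: Path
    refs: dict[str, str] = field(repr=False)
    truth: TruthTable = field(repr=False)
    qpcr_truth: dict[str, float] = field(repr=False)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate a full cohort on disk: reference FASTA, per-sample paired
    FASTQ, metadata TSV, truth TSV and a qPCR plate TSV."""
    outdir = Path(outdir)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)

    refs = generate_reference_db(config, outdir / "reference.fasta")
    contaminant = _contaminant_sequence(config, refs)
    truth, metadata = build_truth(config, refs)

    for entry in truth:
        rng = _stream(config.seed, 3, _sample_stream_key(entry.sample_id))
        r1, r2 = simulate_sample_reads(config, entry, refs, contaminant, rng)
        io.write_fastq_gz(reads_dir / f"{entry.sample_id}_R1.fastq.gz", r1)
        io.write_fastq_gz(reads_dir / f"{entry.sample_id}_R2.fastq.gz", r2)

    # qPCR plate: log-normal eDNA concentrations around the survey median
    qrng = _stream(config.seed, 4)
    edna_ids = [e.sample_id for e in truth if e.role == ROLE_EDNA]
    concs = 10 ** qrng.normal(math.log10(0.0033), 0.75, size=len(edna_ids))
    unknowns = list(zip(edna_ids, concs.tolist()))
    unknowns += [
        (e.sample_id, 0.0) for e in truth if e.role == ROLE_NEGATIVE
    ]
    plate = simulate_qpcr_plate(DEFAULT_STANDARDS, unknowns, rng=qrng)

    io.write_tsv(metadata, outdir / "metadata.tsv")
    io.write_tsv(truth.to_frame(), outdir / "truth.tsv")
    io.write_tsv(plate, outdir / "qpcr.tsv")
    config.to_json(outdir / "config.json")

    return SimulatedDataset(
        outdir=outdir,
        reference_fasta=outdir / "reference.fasta",
        reads_dir=reads_dir,
        metadata_tsv=outdir / "metadata.tsv",
        truth_tsv=outdir / "truth.tsv",
        qpcr_tsv=outdir / "qpcr.tsv",
        refs=refs,
        truth=truth,
        qpcr_truth=dict(unknowns),
    )
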