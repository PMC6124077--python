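"""End-to-end orchestration: FASTQ cohort -> haplotype calls -> statistics.

The run order is: per-sample read processing, chimera flagging, error
calibration from positive controls, threshold filtering, haplotype calling,
and (when at least two strata carry accepted calls) differentiation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import denoise, hapcall, io, popgen, readproc
from ._seq import revcomp
from .errors import ConfigurationError
from .synthdata import FORWARD_PRIMER, REVERSE_PRIMER, ROLE_EDNA, ROLE_POSITIVE


@dataclass
class PipelineParams:
    """Tunables of the full pipeline (defaults = the standard protocol)."""

    q_threshold: int = readproc.DEFAULT_Q_THRESHOLD
    min_overlap: int = readproc.DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = readproc.DEFAULT_MAX_MISMATCH_FRAC
    min_length: int = readproc.DEFAULT_MIN_LENGTH
    abundance_skew: float = denoise.DEFAULT_ABUNDANCE_SKEW
    min_diffs_to_parent: int = denoise.DEFAULT_MIN_DIFFS_TO_PARENT
    rounding: str = "ceil-percent"
    novel_min_fraction: float = hapcall.DEFAULT_NOVEL_MIN_FRACTION
    nontarget_identity_floor: float = hapcall.DEFAULT_NONTARGET_IDENTITY_FLOOR
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    adapters: tuple[str, ...] = ()
    include_secondary: bool = True
    n_perm: int = popgen.DEFAULT_N_PERM
    seed: int = 0


@dataclass
class PipelineResult:
    reports: dict[str, dict]
    calibration: denoise.ErrorCalibration
    calls: hapcall.CohortCalls
    retained: dict[str, list[readproc.UniqueSequence]]
    diff: popgen.DiffResult | None
    dataset: popgen.StrataDataset | None = field(default=None, repr=False)

    @property
    def success_rate(self) -> float:
        """Fraction of eDNA samples with at least one accepted haplotype."""
        df = self.calls.to_frame()
        edna = df[df["sample_id"].isin(self._edna_ids)]
        ok = edna[edna["status"].isin(["known", "novel"])]["sample_id"].nunique()
        return ok / len(self._edna_ids) if self._edna_ids else float("nan")

    _edna_ids: list[str] = field(default_factory=list, repr=False)


def run_pipeline(
    reads_dir: str | Path,
    reference_fasta: str | Path,
    metadata_tsv: str | Path,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole pipeline on a cohort directory.

    ``reads_dir`` holds ``{sample_id}_R1.fastq.gz`` / ``_R2`` pairs for every
    sample listed in the metadata TSV (columns: sample_id, role,
    known_haplotype, stratum, ...).  Positive controls calibrate the error
    threshold; eDNA samples are filtered and called against the reference
    FASTA.  If ``outdir`` is given, call tables and reports are written
    there.
    """
    params = params or PipelineParams()
    reads_dir = Path(reads_dir)
    metadata = io.read_tsv(metadata_tsv).fillna("")
    db = hapcall.ReferenceDB.from_fasta(reference_fasta)

    primers_fwd = [params.forward_primer, revcomp(params.reverse_primer)]
    primers_rev = [params.reverse_primer, revcomp(params.forward_primer)]

    reports: dict[str, dict] = {}
    uniques_by_sample: dict[str, list[readproc.UniqueSequence]] = {}
    flags_by_sample: dict[str, list[bool]] = {}
    for _, row in metadata.iterrows():
        sid = row["sample_id"]
        r1 = reads_dir / f"{sid}_R1.fastq.gz"
        r2 = reads_dir / f"{sid}_R2.fastq.gz"
        if not r1.exists():
            raise ConfigurationError(f"missing reads for sample {sid}: {r1}")
        res = readproc.process_sample(
            r1,
            r2,
            sid,
            adapters=params.adapters,
            primers_fwd=primers_fwd,
            primers_rev=primers_rev,
            q_threshold=params.q_threshold,
            min_overlap=params.min_overlap,
            max_mismatch_frac=params.max_mismatch_frac,
            min_length=params.min_length,
        )
        reports[sid] = res.report
        uniques_by_sample[sid] = res.uniques
        flags_by_sample[sid] = denoise.detect_chimeras(
            res.uniques, params.abundance_skew, params.min_diffs_to_parent
        )
        reports[sid]["chimeric_uniques"] = int(sum(flags_by_sample[sid]))

    # calibration from positive controls (chimeras already flagged/removed)
    controls: dict[str, list[readproc.UniqueSequence]] = {}
    known: dict[str, str] = {}
    denoms: dict[str, int] = {}
    for _, row in metadata.iterrows():
        if row["role"] != ROLE_POSITIVE:
            continue
        sid = row["sample_id"]
        hap_id = row["known_haplotype"]
        if hap_id not in db.seqs:
            raise ConfigurationError(
                f"control {sid} references unknown haplotype {hap_id!r}"
            )
        controls[sid] = denoise.apply_threshold(
            uniques_by_sample[sid], 0.0, flags_by_sample[sid]
        )
        known[sid] = db.seqs[hap_id]
        denoms[sid] = reports[sid]["processed_reads"]
    calibration = denoise.calibrate_error(
        controls, known, denominators=denoms, rounding=params.rounding
    )

    # threshold filter + calls on eDNA samples
    edna_ids = metadata.loc[metadata["role"] == ROLE_EDNA, "sample_id"].tolist()
    retained = {
        sid: denoise.apply_threshold(
            uniques_by_sample[sid], calibration.threshold, flags_by_sample[sid]
        )
        for sid in edna_ids
    }
    calls = hapcall.call_cohort(
        retained,
        db,
        novel_min_fraction=params.novel_min_fraction,
        nontarget_identity_floor=params.nontarget_identity_floor,
    )

    # differentiation tests over strata, when testable
    diff = None
    dataset = None
    try:
        refs_plus = dict(db.seqs)
        dataset = popgen.StrataDataset.from_calls(
            calls.to_frame(), metadata, refs_plus,
            include_secondary=params.include_secondary,
        )
        strata = {st for _s, _h, st in dataset.observations}
        haps = {h for _s, h, _t in dataset.observations}
        if len(strata) >= 2 and len(haps) >= 2 and len(dataset.observations) >= 3:
            diff = popgen.differentiation_tests(
                dataset, n_perm=params.n_perm, seed=params.seed
            )
    except (ValueError, KeyError):
        diff = None

    result = PipelineResult(
        reports=reports,
        calibration=calibration,
        calls=calls,
        retained=retained,
        diff=diff,
        dataset=dataset,
        _edna_ids=edna_ids,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(calls.to_frame(), outdir / "calls.tsv")
        io.write_json(reports, outdir / "processing_report.json")
        io.write_json(calibration.to_dict(), outdir / "calibration.json")
        if calls.novel_seqs:
            io.write_fasta(outdir / "novel_haplotypes.fasta", calls.novel_seqs)
        if diff is not None:
            io.write_json(
                {
                    "phi_st": diff.phi_st,
                    "phi_p": diff.phi_p,
                    "sigma2_among": diff.sigma2_among,
                    "sigma2_within": diff.sigma2_within,
                    "chi2": diff.chi2,
                    "chi2_df": diff.chi2_df,
                    "chi2_p_perm": diff.chi2_p_perm,
                    "chi2_p_asymptotic": diff.chi2_p_asymptotic,
                    "n_perm": diff.n_perm,
                    "seed": diff.seed,
                    "status": diff.status,
                },
                outdir / "differentiation.json",
            )
            if diff.table is not None:
                diff.table.to_csv(outdir / "haplotype_by_stratum.tsv", sep="\t")
    return result
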