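"""Population differentiation from haplotype observations across strata.

Phi_ST is the AMOVA fixation analogue: squared pairwise nucleotide
distances between the haplotypes of observations are partitioned into
among- and within-stratum variance components, and significance is assessed
by permuting stratum labels.  A haplotype-by-stratum chi-square homogeneity
test (asymptotic and permutation p-values) complements it, weighting all
haplotype differences equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError

DEFAULT_N_PERM = 1000

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"


@dataclass
class StrataDataset:
    """Haplotype observations with stratum labels and their sequences.

    ``observations`` rows are (sample_id, haplotype_id, stratum); every
    observed haplotype must have an equal-length sequence in ``seqs``.
    """

    observations: list[tuple[str, str, str]]
    seqs: dict[str, str]
    distance_model: str = "hamming"

    def __post_init__(self) -> None:
        self.seqs = {k: v.upper() for k, v in self.seqs.items()}
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError("haplotype sequences must be aligned to equal length")
        for _sid, hap, _st in self.observations:
            if hap not in self.seqs:
                raise ValueError(f"observation references unknown haplotype {hap!r}")

    @classmethod
    def from_calls(
        cls,
        calls: pd.DataFrame,
        metadata: pd.DataFrame,
        refs: Mapping[str, str],
        include_secondary: bool = True,
        trim_to: int | None = None,
    ) -> "StrataDataset":
        """Build from a cohort call table plus sample metadata.

        Accepted (known/novel) calls each contribute one observation —
        secondary haplotypes reflect a second contributing animal — unless
        ``include_secondary`` is False.  Novel haplotype sequences come from
        the call table itself; known ones from ``refs``.  ``trim_to`` trims
        all sequences to a common leading interval (defaults to the shortest
        sequence present).
        """
        acc = calls[calls["status"].isin(["known", "novel"])].copy()
        if not include_secondary:
            acc = acc[acc["rank"] == "primary"]
        strat = metadata.set_index("sample_id")["stratum"]
        obs: list[tuple[str, str, str]] = []
        seqs: dict[str, str] = {}
        for _, row in acc.iterrows():
            stratum = strat.get(row["sample_id"], "")
            if not isinstance(stratum, str) or not stratum:
                continue
            hap = row["haplotype_id"]
            obs.append((row["sample_id"], hap, stratum))
            if hap not in seqs:
                seqs[hap] = (
                    refs[hap] if row["status"] == "known" else row["seq"]
                ).upper()
        if trim_to is None and seqs:
            trim_to = min(len(s) for s in seqs.values())
        if trim_to is not None:
            seqs = {k: v[:trim_to] for k, v in seqs.items()}
        return cls(observations=obs, seqs=seqs)

    def haplotype_by_stratum(self) -> pd.DataFrame:
        df = pd.DataFrame(self.observations, columns=["sample_id", "haplotype_id", "stratum"])
        return pd.crosstab(df["haplotype_id"], df["stratum"])


@dataclass
class DiffResult:
    """Differentiation statistics with their permutation inference."""

    n_obs: int
    n_strata: int
    n_perm: int
    seed: int | None
    status: str = STATUS_OK
    phi_st: float | None = None
    phi_p: float | None = None
    sigma2_among: float | None = None
    sigma2_within: float | None = None
    chi2: float | None = None
    chi2_df: int | None = None
    chi2_p_perm: float | None = None
    chi2_p_asymptotic: float | None = None
    table: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Population differentiation",
            "-" * 44,
            f"observations: {self.n_obs}   strata: {self.n_strata}"
            f"   permutations: {self.n_perm} (seed={self.seed})",
        ]
        if self.status != STATUS_OK:
            lines.append(f"status: {self.status}")
        if self.phi_st is not None:
            lines.append(
                f"Phi_ST = {self.phi_st:.3f}   permutation p = {self.phi_p:.4g}"
            )
            lines.append(
                f"  sigma2 among = {self.sigma2_among:.4g}   "
                f"sigma2 within = {self.sigma2_within:.4g}"
            )
        if self.chi2 is not None:
            lines.append(
                f"chi2 = {self.chi2:.2f} (df={self.chi2_df})   "
                f"permutation p = {self.chi2_p_perm:.4g}   "
                f"asymptotic p = {self.chi2_p_asymptotic:.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# distances


def pairwise_distance_matrix(dataset: StrataDataset) -> np.ndarray:
    """Observation-by-observation matrix of nucleotide differences."""
    haps = sorted(dataset.seqs)
    idx = {h: i for i, h in enumerate(haps)}
    mats = np.stack(
        [np.frombuffer(dataset.seqs[h].encode(), dtype=np.uint8) for h in haps]
    )
    # haplotype-level distances, then expand to observations
    hd = (mats[:, None, :] != mats[None, :, :]).sum(axis=2)
    obs_idx = np.array([idx[hap] for _s, hap, _t in dataset.observations])
    return hd[np.ix_(obs_idx, obs_idx)].astype(np.float64)


# ---------------------------------------------------------------------------
# AMOVA Phi_ST


def _phi_from_labels(d2: np.ndarray, codes: np.ndarray, n_strata: int) -> float:
    """Phi_ST from squared distances and integer stratum codes."""
    N = d2.shape[0]
    K = n_strata
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    sum_nk2 = 0.0
    for k in range(K):
        mask = codes == k
        nk = int(mask.sum())
        if nk == 0:
            continue
        sum_nk2 += nk * nk
        if nk > 1:
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub.sum() / 2.0 / nk
    ss_among = ss_total - ss_within
    k_eff = len(set(codes.tolist()))
    ms_among = ss_among / (k_eff - 1)
    ms_within = ss_within / (N - k_eff)
    n_prime = (N - sum_nk2 / N) / (k_eff - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def phi_st(
    dataset: StrataDataset,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> DiffResult:
    """AMOVA Phi_ST with a label-permutation test.

    Sums of squares come from squared pairwise distances (SS_total =
    (1/N)sum_{i<j} d^2; SS_within the analogous per-stratum sums); the
    permutation p-value includes the observed statistic in the null set:
    p = (1 + #{permuted Phi >= observed}) / (n_perm + 1).
    """
    labels = [st for _s, _h, st in dataset.observations]
    strata = sorted(set(labels))
    N = len(labels)
    if len(strata) < 2:
        raise ValueError("Phi_ST requires at least two strata")
    if N < 3:
        raise ValueError("Phi_ST requires at least three observations")
    if N == len(strata):
        raise ValueError("every stratum is a singleton: no within-stratum variance")

    D = pairwise_distance_matrix(dataset)
    codes = np.array([strata.index(s) for s in labels])
    result = DiffResult(n_obs=N, n_strata=len(strata), n_perm=n_perm, seed=seed)
    if not D.any():
        result.status = STATUS_MONOMORPHIC
        result.phi_st, result.phi_p = 0.0, 1.0
        result.sigma2_among, result.sigma2_within = 0.0, 0.0
        return result

    d2 = D**2
    obs = _phi_from_labels(d2, codes, len(strata))

    # variance components at the observed labelling (recomputed for reporting)
    K = len(strata)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = sum(
        d2[np.ix_(codes == k, codes == k)].sum() / 2.0 / max(int((codes == k).sum()), 1)
        for k in range(K)
        if (codes == k).sum() > 1
    )
    ms_among = (ss_total - ss_within) / (K - 1)
    ms_within = ss_within / (N - K)
    n_prime = (N - sum(int((codes == k).sum()) ** 2 for k in range(K)) / N) / (K - 1)
    result.sigma2_within = float(ms_within)
    result.sigma2_among = float((ms_among - ms_within) / n_prime)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _phi_from_labels(d2, perm, len(strata)) >= obs - 1e-12:
            ge += 1
    result.phi_st = float(obs)
    result.phi_p = (1 + ge) / (n_perm + 1)
    return result


# ---------------------------------------------------------------------------
# chi-square homogeneity


def _chi2_stat(table: np.ndarray) -> float:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    N = table.sum()
    expected = rows @ cols / N
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(cells.sum())


def chi2_test(
    dataset: StrataDataset,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> DiffResult:
    """Haplotype-by-stratum chi-square test of frequency homogeneity.

    Reports the statistic over cells with positive expectation, the
    asymptotic p on (H-1)(K-1) degrees of freedom, and a label-permutation p
    using the same (+1/+1) convention as :func:`phi_st`.
    """
    df = pd.DataFrame(dataset.observations, columns=["sample_id", "haplotype_id", "stratum"])
    table = pd.crosstab(df["haplotype_id"], df["stratum"])
    H, K = table.shape
    if H < 2 or K < 2:
        raise ValueError("chi-square test needs >= 2 haplotypes and >= 2 strata")

    obs_mat = table.to_numpy(dtype=np.float64)
    chi2 = _chi2_stat(obs_mat)
    dof = (H - 1) * (K - 1)
    p_asym = float(stats.chi2.sf(chi2, dof))

    haps = df["haplotype_id"].to_numpy()
    labels = df["stratum"].to_numpy()
    hap_codes = pd.factorize(haps)[0]
    lab_codes = pd.factorize(labels)[0]
    n_hap = hap_codes.max() + 1
    n_lab = lab_codes.max() + 1

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab_codes)
        tab = np.zeros((n_hap, n_lab))
        np.add.at(tab, (hap_codes, perm), 1.0)
        if _chi2_stat(tab) >= chi2 - 1e-12:
            ge += 1

    return DiffResult(
        n_obs=len(df),
        n_strata=K,
        n_perm=n_perm,
        seed=seed,
        chi2=chi2,
        chi2_df=dof,
        chi2_p_perm=(1 + ge) / (n_perm + 1),
        chi2_p_asymptotic=p_asym,
        table=table,
    )


def differentiation_tests(
    dataset: StrataDataset,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> DiffResult:
    """Run both Phi_ST and chi-square and merge into one result."""
    phi = phi_st(dataset, n_perm=n_perm, seed=seed)
    chi = chi2_test(dataset, n_perm=n_perm, seed=seed)
    phi.chi2 = chi.chi2
    phi.chi2_df = chi.chi2_df
    phi.chi2_p_perm = chi.chi2_p_perm
    phi.chi2_p_asymptotic = chi.chi2_p_asymptotic
    phi.table = chi.table
    return phi
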