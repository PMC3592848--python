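"""SNP- and subject-level quality control.

The exclusion cascade mirrors the genotyping-study workflow: assay failures
(all-missing SNPs), monoallelic calls, replicate concordance, SNP completion,
Hardy-Weinberg disequilibrium in controls, subject completion, minor-allele
frequency, and the Tarone minimum-attainable-significance filter for
uninformative discrete tests. A SNP failing several filters is charged to the
first failing one.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_model import Dataset, GenotypeMatrix, SnpAnnotation, SubjectTable, ValidationError

__all__ = [
    "QcConfig",
    "QcReport",
    "completion_rate",
    "concordance_rate",
    "hwe_exact_p",
    "maf",
    "min_attainable_p",
    "apply_qc",
]


@dataclasses.dataclass
class QcConfig:
    """Thresholds for the QC cascade.

    min_snp_completion / min_subject_completion: minimum fraction of
    non-missing calls (default 0.90, exclusion when strictly below).
    min_concordance: minimum replicate concordance (default 0.95).
    hwe_alpha: exact HWE p-value threshold in controls (default 1e-5,
    exclusion when strictly below).
    min_maf: minimum minor-allele frequency (default 0.10, exclusion when
    strictly below — MAF exactly at the boundary is kept).
    min_attainable_alpha: Tarone filter — drop SNPs whose smallest achievable
    two-sided p given the marginal totals exceeds this value; ``None``
    disables the filter.
    maf_population: 'controls' or 'all' — where MAF (and the minor allele)
    is evaluated.
    """

    min_snp_completion: float = 0.90
    min_subject_completion: float = 0.90
    min_concordance: float = 0.95
    hwe_alpha: float = 1e-5
    min_maf: float = 0.10
    min_attainable_alpha: float | None = None
    maf_population: str = "controls"


@dataclasses.dataclass
class QcReport:
    """Ordered per-filter exclusion counts and surviving dimensions."""

    snp_exclusions: dict[str, list[str]]
    subject_exclusions: dict[str, list[str]]
    n_snps_in: int = 0
    n_subjects_in: int = 0
    n_snps_out: int = 0
    n_subjects_out: int = 0

    def counts(self) -> dict[str, int]:
        out = {f"snp:{k}": len(v) for k, v in self.snp_exclusions.items()}
        out.update({f"subject:{k}": len(v) for k, v in self.subject_exclusions.items()})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"axis": "snp", "filter": k, "n_excluded": len(v)}
            for k, v in self.snp_exclusions.items()
        ] + [
            {"axis": "subject", "filter": k, "n_excluded": len(v)}
            for k, v in self.subject_exclusions.items()
        ]
        return pd.DataFrame(rows, columns=["axis", "filter", "n_excluded"])


def completion_rate(dosages: np.ndarray) -> float:
    """Fraction of non-missing calls in a dosage vector."""
    v = np.asarray(dosages, dtype=float)
    if v.size == 0:
        raise ValueError("empty dosage vector")
    return float(np.sum(~np.isnan(v)) / v.size)


def concordance_rate(replicate_a: np.ndarray, replicate_b: np.ndarray) -> float | None:
    """Fraction of pairwise-complete positions with equal dosage.

    Returns ``None`` (undefined, flagged upstream) when no position is
    non-missing in both replicates.
    """
    a = np.asarray(replicate_a, dtype=float)
    b = np.asarray(replicate_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors differ in length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        return None
    return float(np.mean(a[ok] == b[ok]))


def _hwe_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` diploid subjects and ``n_a`` copies of the minor allele, the
    heterozygote count h has support {h : h ≡ n_a (mod 2), 0 ≤ h ≤ min(n_a,
    2n−n_a)} and
    ``Pr(h) ∝ n! / (n_AA! h! n_aa!) · 2^h`` with ``n_AA=(n_a−h)/2``.
    Returned log-probabilities are normalised.
    """
    h_max = min(n_a, 2 * n - n_a)
    hs = np.arange(n_a % 2, h_max + 1, 2)
    n_hom_minor = (n_a - hs) // 2
    n_hom_major = n - n_hom_minor - hs
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(n_hom_major + 1)
        + hs * math.log(2.0)
    )
    logp -= np.max(logp)
    logp -= math.log(np.exp(logp).sum())
    return hs, logp


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than that of the observed table
    (two-sided by probability ordering). Monomorphic sites give p = 1.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = n_het + 2 * n_hom_minor
    n_a = min(n_a, 2 * n - n_a)  # symmetric under allele relabelling
    if n_a == 0:
        return 1.0
    hs, logp = _hwe_log_probs(n, n_a)
    obs = n_het
    idx = np.flatnonzero(hs == obs)
    if idx.size == 0:
        raise ValueError("heterozygote count incompatible with allele parity")
    log_obs = logp[idx[0]]
    # include outcomes with Pr <= Pr(obs), with a relative tolerance for ties
    sel = logp <= log_obs + 1e-10
    return float(min(1.0, np.exp(logp[sel]).sum()))


def maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency ``min(f, 1-f)`` from a dosage vector."""
    v = np.asarray(dosages, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("all genotypes missing")
    f = float(v.sum() / (2.0 * v.size))
    return min(f, 1.0 - f)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def _enumerate_tables(case_total: int, m: tuple[int, int, int]) -> np.ndarray:
    """All case genotype-count triples (a0, a1, a2) feasible under the
    margins: 0 ≤ a_i ≤ m_i, sum = case_total."""
    rows = []
    for a0 in range(max(0, case_total - m[1] - m[2]), min(m[0], case_total) + 1):
        rest = case_total - a0
        for a1 in range(max(0, rest - m[2]), min(m[1], rest) + 1):
            rows.append((a0, a1, rest - a1))
    return np.array(rows, dtype=int)


def min_attainable_p(
    case_total: int, control_total: int, genotype_margins: tuple[int, int, int]
) -> float:
    """Smallest two-sided p-value achievable by any 2x3 case-control table
    with the given margins (the Tarone informativeness bound).

    Each feasible table's p-value is the exact conditional (multivariate
    hypergeometric) tail probability under the ordering induced by the
    Cochran-Armitage trend statistic ``T = a1 + 2 a2`` (two-sided around its
    conditional expectation); the minimum over feasible tables is returned.
    """
    m = tuple(int(x) for x in genotype_margins)
    n = case_total + control_total
    if case_total < 0 or control_total < 0 or any(x < 0 for x in m):
        raise ValueError("negative counts")
    if sum(m) != n:
        raise ValueError("genotype margins do not sum to the subject total")
    if n == 0:
        raise ValueError("empty table")
    if case_total == 0 or control_total == 0 or max(m) == n:
        return 1.0  # degenerate: only one feasible table / monomorphic

    tables = _enumerate_tables(case_total, m)
    logp = (
        _log_comb(m[0], tables[:, 0])
        + _log_comb(m[1], tables[:, 1])
        + _log_comb(m[2], tables[:, 2])
        - _log_comb(n, case_total)
    )
    prob = np.exp(logp)
    t_stat = tables[:, 1] + 2 * tables[:, 2]
    mu = float((prob * t_stat).sum())
    dev = np.abs(t_stat - mu)
    # two-sided p per table: total prob of tables at least as extreme;
    # ties in the deviation (exact for symmetric margins, blurred by float
    # noise that grows with the statistic) share one p, so the tolerance
    # scales with the deviation magnitude
    # the minimum is attained by the most extreme tie-run
    order = np.argsort(-dev)
    csum = np.cumsum(prob[order])
    tol = 1e-9 * (1.0 + dev[order[0]])
    j = 0
    while j + 1 < len(order) and dev[order[j + 1]] >= dev[order[0]] - tol:
        j += 1
    return float(min(1.0, csum[j]))


def _snp_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    v = dosage[~np.isnan(dosage)]
    return int(np.sum(v == 0)), int(np.sum(v == 1)), int(np.sum(v == 2))


def apply_qc(
    dataset: Dataset,
    config: QcConfig | None = None,
    replicate_pairs: list[tuple[str, str]] | None = None,
) -> tuple[Dataset, QcReport]:
    """Run the full exclusion cascade and return the filtered dataset with an
    itemised report.

    Filter order: assay failure (all-missing SNP), monoallelic, replicate
    concordance (when ``replicate_pairs`` maps subject-id pairs), SNP
    completion, HWE in controls, subject completion, MAF, Tarone. Raises with
    the report attached when nothing survives.
    """
    config = config or QcConfig()
    g = dataset.genotypes.dosages
    status = dataset.subjects.table["status"]
    report = QcReport(snp_exclusions={}, subject_exclusions={},
                      n_snps_in=g.shape[1], n_subjects_in=g.shape[0])

    remaining = list(g.columns)

    def exclude(name: str, failing: list[str]) -> None:
        report.snp_exclusions[name] = failing
        for s in failing:
            remaining.remove(s)

    vals = {s: g[s].to_numpy(dtype=float) for s in g.columns}

    exclude("assay_failure", [s for s in remaining if np.all(np.isnan(vals[s]))])
    exclude("monoallelic", [s for s in remaining
                            if np.unique(vals[s][~np.isnan(vals[s])]).size == 1])

    if replicate_pairs:
        failing = []
        for s in remaining:
            col = g[s]
            rates = []
            for a, b in replicate_pairs:
                r = concordance_rate(np.atleast_1d(col.loc[a]), np.atleast_1d(col.loc[b]))
                if r is not None:
                    rates.append(r)
            if rates and float(np.mean(rates)) < config.min_concordance:
                failing.append(s)
        exclude("concordance", failing)
    else:
        report.snp_exclusions["concordance"] = []

    exclude("snp_completion",
            [s for s in remaining if completion_rate(vals[s]) < config.min_snp_completion])

    controls = status == 0
    failing = []
    for s in remaining:
        v = vals[s][controls.to_numpy()]
        c0, c1, c2 = _snp_counts(v)
        if c0 + c1 + c2 == 0:
            continue
        if hwe_exact_p(c0, c1, c2) < config.hwe_alpha:
            failing.append(s)
    exclude("hwe_controls", failing)

    # subject completion over surviving SNPs
    sub_g = g[remaining]
    if remaining:
        comp = sub_g.notna().to_numpy().mean(axis=1)
    else:
        comp = np.ones(g.shape[0])
    bad_subjects = [str(sid) for sid, c in zip(g.index, comp) if c < config.min_subject_completion]
    report.subject_exclusions["subject_completion"] = bad_subjects
    keep_subjects = g.index[~g.index.isin(bad_subjects)]

    maf_rows = (
        keep_subjects[status.loc[keep_subjects] == 0]
        if config.maf_population == "controls"
        else keep_subjects
    )
    failing = []
    for s in remaining:
        v = g.loc[maf_rows, s].to_numpy(dtype=float)
        if v[~np.isnan(v)].size == 0 or maf(v) < config.min_maf:
            failing.append(s)
    exclude("maf", failing)

    if config.min_attainable_alpha is not None:
        n_case = int((status.loc[keep_subjects] == 1).sum())
        n_ctrl = int((status.loc[keep_subjects] == 0).sum())
        failing = []
        for s in remaining:
            v = g.loc[keep_subjects, s].to_numpy(dtype=float)
            c0, c1, c2 = _snp_counts(v)
            n_obs = c0 + c1 + c2
            frac = n_obs / (n_case + n_ctrl) if (n_case + n_ctrl) else 1.0
            nc = int(round(n_case * frac))
            if min_attainable_p(nc, n_obs - nc, (c0, c1, c2)) > config.min_attainable_alpha:
                failing.append(s)
        exclude("tarone", failing)
    else:
        report.snp_exclusions["tarone"] = []

    report.n_snps_out = len(remaining)
    report.n_subjects_out = len(keep_subjects)
    if not remaining or len(keep_subjects) == 0:
        err = ValidationError("QC excluded every SNP or subject")
        err.report = report  # type: ignore[attr-defined]
        raise err

    filtered = Dataset(
        genotypes=GenotypeMatrix(g.loc[keep_subjects, remaining]),
        subjects=SubjectTable(dataset.subjects.table.loc[keep_subjects],
                              birth_year_bounds=dataset.subjects.birth_year_bounds),
        annotation=SnpAnnotation(dataset.annotation.table.loc[remaining]),
        pathways=dataset.pathways,
        merge_report=dataset.merge_report,
    )
    return filtered, report
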