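"""Adaptive rank truncated product (ARTP) p-value combination.

Per-SNP trend p-values are combined hierarchically — SNPs into gene regions,
regions into pathways, pathways into an overall summary — against a single
shared permutation null. For each unit and candidate truncation point j the
rank truncated product statistic ``W_j = Σ log p_(i)`` over the j smallest
member p-values is computed on the observed data (row 0) and on every
permuted dataset (rows 1..B, case/control labels permuted with covariates
travelling with subjects, so LD and covariate structure are preserved). The
per-row significance of each W_j is estimated by its rank among the other
rows, the adaptive statistic is the minimum over j, and its own significance
is again assessed by rank — the construction that lets one permutation layer
serve every level of the hierarchy.

All permutation p-values use the add-one convention (1 + count)/(B + 1), so
they live on the lattice {1/(B+1), ..., 1} and never vanish.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .association import ModelSpec, build_design, fit_logistic, trend_p_matrix
from .data_model import Dataset

__all__ = [
    "TruncationSet",
    "PermutationPValueMatrix",
    "ArtpResult",
    "build_permutation_matrix",
    "rtp_statistic",
    "artp_combine",
    "pathway_analysis",
]


@dataclasses.dataclass
class TruncationSet:
    """Ordered candidate truncation points, capped at the group size."""

    points: tuple[int, ...]

    def __post_init__(self) -> None:
        pts = tuple(int(j) for j in self.points)
        if not pts or any(j < 1 for j in pts) or list(pts) != sorted(set(pts)):
            raise ValueError("truncation points must be distinct positive integers, ascending")
        self.points = pts

    def capped(self, size: int) -> tuple[int, ...]:
        out = tuple(j for j in self.points if j <= size)
        return out if out else (size,)

    @classmethod
    def default(cls, size: int, cap: int = 10) -> "TruncationSet":
        return cls(tuple(range(1, min(size, cap) + 1)))


@dataclasses.dataclass
class PermutationPValueMatrix:
    """(B+1) x K matrix of per-unit p-values; row 0 = observed labels."""

    values: np.ndarray
    columns: tuple[str, ...]
    seed: int | None
    B: int
    n_nonconverged: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.B + 1, len(self.columns)):
            raise ValueError("matrix shape must be (B+1, n_units)")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def observed(self) -> np.ndarray:
        return self.values[0]


@dataclasses.dataclass
class ArtpResult:
    label: str
    p: float
    selected_truncation: int
    B: int

    @property
    def mc_standard_error(self) -> float:
        return float(np.sqrt(self.p * (1.0 - self.p) / self.B))


def build_permutation_matrix(
    dataset: Dataset,
    B: int,
    spec: ModelSpec | None = None,
    seed: int = 0,
    adjusted_in_permutations: bool | None = None,
) -> PermutationPValueMatrix:
    """Per-SNP trend p-values on the observed data and B label permutations.

    Case/control labels are permuted across subjects while all covariates
    and genotypes stay attached to their subject, preserving the LD and
    covariate structure under the null. ``adjusted_in_permutations=False``
    (the speed knob, and the default when the spec itself is crude) uses the
    vectorised covariate-free trend fit for all rows; the adjusted variant
    refits the full covariate model in every permutation.
    """
    spec = spec or ModelSpec()
    if adjusted_in_permutations is None:
        adjusted_in_permutations = spec.adjusted
    rng = np.random.default_rng(seed)
    y0 = dataset.status
    n = y0.size
    Y = np.empty((B + 1, n), dtype=float)
    Y[0] = y0
    for b in range(1, B + 1):
        Y[b] = y0[rng.permutation(n)]
    G = dataset.genotypes.values()
    snp_ids = tuple(dataset.genotypes.snp_ids)

    n_nonconverged = 0
    if not adjusted_in_permutations:
        P = trend_p_matrix(Y, G)
    else:
        design = build_design(dataset.subjects.table, spec)
        P = np.ones((B + 1, G.shape[1]))
        for b in range(B + 1):
            for k in range(G.shape[1]):
                g = G[:, k]
                ok = ~np.isnan(g) & ~design.isna().any(axis=1).to_numpy()
                if np.nanvar(g[ok]) == 0:
                    continue
                X = design.loc[ok].copy()
                X["dosage"] = g[ok]
                fit = fit_logistic(Y[b, ok], X)
                if not fit.converged or "dosage" not in fit.column_names:
                    n_nonconverged += 1
                    continue  # cell stays 1, tallied
                j = fit.column_names.index("dosage")
                from scipy import stats as _st

                z2 = fit.params[j] ** 2 / fit.cov_params[j, j]
                P[b, k] = float(_st.chi2.sf(z2, df=1))
    P = np.clip(P, 1.0 / (B + 1), 1.0)
    return PermutationPValueMatrix(values=P, columns=snp_ids, seed=seed, B=B,
                                   n_nonconverged=n_nonconverged)


def rtp_statistic(p: Sequence[float], j: int) -> float:
    """Rank truncated product statistic: sum of logs of the j smallest
    p-values (more negative = more significant)."""
    p = np.asarray(p, dtype=float)
    if not 1 <= j <= p.size:
        raise ValueError(f"truncation point {j} outside 1..{p.size}")
    if np.any(p <= 0):
        raise ValueError("p-values must be positive (floor permutation p at 1/(B+1))")
    return float(np.sum(np.log(np.sort(p)[:j])))


def _rank_le_probs(W: np.ndarray) -> np.ndarray:
    """Per-row significance estimates from rank among the other rows.

    For a (B+1,) statistic column: ``s_b = (1 + #{b' != b : W_b' <= W_b}) /
    (B + 1)``; ties count as <= for every row alike.
    """
    order = np.sort(W)
    # count_le includes the row itself, so #{b' != b} = count_le - 1
    count_le = np.searchsorted(order, W, side="right")
    return count_le.astype(float) / W.size


def artp_combine(
    M: PermutationPValueMatrix,
    groups: Mapping[str, Sequence[str]],
    J: TruncationSet | None = None,
) -> tuple[dict[str, ArtpResult], PermutationPValueMatrix]:
    """Combine unit columns into group-level ARTP p-values.

    Returns the per-group results and the next level's permutation matrix:
    each group's column holds, for every row b, the adaptive statistic
    ``MinP^(b) = min_j s_j^(b)`` — the row's group-level p-value estimate —
    so the same permutation layer carries the hierarchy upward.
    """
    B = M.B
    col_index = {c: i for i, c in enumerate(M.columns)}
    results: dict[str, ArtpResult] = {}
    next_cols: list[str] = []
    next_vals = np.empty((B + 1, len(groups)))

    for gi, (label, members) in enumerate(groups.items()):
        if len(members) == 0:
            raise ValueError(f"group {label!r} has no members")
        idx = [col_index[m] for m in members]
        sub = M.values[:, idx]                     # (B+1, k)
        pts = (J or TruncationSet.default(len(idx))).capped(len(idx))
        sorted_logs = np.log(np.sort(sub, axis=1))
        cum = np.cumsum(sorted_logs, axis=1)       # W_j at column j-1
        W = cum[:, [j - 1 for j in pts]]           # (B+1, L)
        s = np.column_stack([_rank_le_probs(W[:, l]) for l in range(W.shape[1])])
        min_p = s.min(axis=1)                      # (B+1,)
        sel = int(pts[int(np.argmin(s[0]))])
        group_p = (1.0 + np.sum(min_p[1:] <= min_p[0])) / (B + 1.0)
        results[label] = ArtpResult(label=label, p=float(group_p),
                                    selected_truncation=sel, B=B)
        next_cols.append(label)
        next_vals[:, gi] = min_p

    next_M = PermutationPValueMatrix(values=next_vals, columns=tuple(next_cols),
                                     seed=M.seed, B=B,
                                     n_nonconverged=M.n_nonconverged)
    return results, next_M


@dataclasses.dataclass
class PathwayAnalysisResult:
    region_results: dict[str, ArtpResult]
    pathway_results: dict[str, ArtpResult]
    overall: ArtpResult
    n_genes_per_pathway: dict[str, int]
    not_estimable: tuple[str, ...] = ()


def pathway_analysis(
    dataset: Dataset,
    B: int = 10_000,
    seed: int = 0,
    spec: ModelSpec | None = None,
    J_region: TruncationSet | None = None,
    J_pathway: TruncationSet | None = None,
    overlap: str = "with",
    adjusted_in_permutations: bool | None = None,
    snp_matrix: PermutationPValueMatrix | None = None,
) -> PathwayAnalysisResult:
    """Full hierarchical combination: SNPs -> regions -> pathways -> overall.

    ``overlap='without'`` drops every multi-allocated gene region from all
    of its pathways before combining; pathways emptied by the removal are
    reported as not estimable. A precomputed SNP-level permutation matrix
    may be supplied to share one permutation layer between the with/without
    variants.
    """
    if overlap not in ("with", "without"):
        raise ValueError("overlap must be 'with' or 'without'")
    M = snp_matrix if snp_matrix is not None else build_permutation_matrix(
        dataset, B=B, spec=spec, seed=seed,
        adjusted_in_permutations=adjusted_in_permutations,
    )

    region_groups = {r: snps for r, snps in dataset.snps_by_region().items()}
    region_results, M_region = artp_combine(M, region_groups, J_region)

    pw_regions = dataset.pathways.regions_by_pathway(drop_overlap=(overlap == "without"))
    # restrict to regions actually present in the dataset; keep every pathway
    # of the map visible so emptied ones can be reported as not estimable
    present = set(region_groups)
    all_pathways = dataset.pathways.pathways
    pathway_groups = {
        pw: [r for r in pw_regions.get(pw, []) if r in present]
        for pw in sorted(all_pathways)
    }
    not_estimable = tuple(pw for pw, rs in pathway_groups.items() if not rs)
    pathway_groups = {pw: rs for pw, rs in pathway_groups.items() if rs}
    if not pathway_groups:
        raise ValueError("no pathway has any member region after overlap handling")
    pathway_results, M_pathway = artp_combine(M_region, pathway_groups, J_pathway)

    overall_groups = {"overall": list(M_pathway.columns)}
    overall_results, _ = artp_combine(M_pathway, overall_groups, J_pathway)

    return PathwayAnalysisResult(
        region_results=region_results,
        pathway_results=pathway_results,
        overall=overall_results["overall"],
        n_genes_per_pathway={pw: len(rs) for pw, rs in pathway_groups.items()},
        not_estimable=not_estimable,
    )
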