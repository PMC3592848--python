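"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated by
expectation-maximisation over the unphased likelihood: only double
heterozygotes are phase-ambiguous, and the E-step splits them between the
cis and trans configurations in proportion to the current haplotype
frequency products. D' and r^2 are then computed from the fitted
frequencies. This is the standard approach for dosage data without phase
(the one used by Haploview).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .data_model import Dataset

__all__ = ["HaplotypeFreqs", "em_haplotype_freqs", "dprime_rsq", "pairwise_ld"]


class MonomorphicLocusError(ValueError):
    """LD is undefined when a locus carries a single allele."""


@dataclasses.dataclass
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes.

    Allele coding: 1 = minor. ``f11`` is the minor-minor haplotype, ``f12``
    minor at locus 1 / major at locus 2, etc.
    """

    f11: float
    f12: float
    f21: float
    f22: float
    log_likelihood: float = float("nan")
    n_iter: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.f11, self.f12, self.f21, self.f22])

    @property
    def p1(self) -> float:
        """Minor-allele frequency at locus 1."""
        return self.f11 + self.f12

    @property
    def q1(self) -> float:
        """Minor-allele frequency at locus 2."""
        return self.f11 + self.f21


def _pair_log_likelihood(f: np.ndarray, counts: dict[tuple[int, int], int]) -> float:
    f11, f12, f21, f22 = np.maximum(f, 1e-300)
    ll = 0.0
    for (g1, g2), n in counts.items():
        if n == 0:
            continue
        # genotype-pair probability as a sum over compatible haplotype pairs
        probs = 0.0
        hap_p = {(1, 1): f11, (1, 0): f12, (0, 1): f21, (0, 0): f22}
        for h1, h2 in itertools.product(hap_p, repeat=2):
            if h1[0] + h2[0] == g1 and h1[1] + h2[1] == g2:
                probs += hap_p[h1] * hap_p[h2]
        ll += n * np.log(max(probs, 1e-300))
    return float(ll)


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-10,
                       max_iter: int = 1000) -> HaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from dosage vectors.

    Pairs with either dosage missing are dropped. Starts from linkage
    equilibrium (products of the observed allele frequencies); converges when
    the largest frequency change is below ``tol``.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValueError("no pairwise-complete genotypes")
    if a.min() == a.max() or b.min() == b.max():
        raise MonomorphicLocusError("monomorphic locus: LD undefined")

    counts: dict[tuple[int, int], int] = {}
    for ga, gb in zip(a.astype(int), b.astype(int)):
        counts[(ga, gb)] = counts.get((ga, gb), 0) + 1
    n = a.size
    n_dh = counts.get((1, 1), 0)  # double heterozygotes: ambiguous phase

    # unambiguous haplotype contributions (two per subject)
    base = np.zeros(4)  # order: 11, 12, 21, 22
    for (ga, gb), cnt in counts.items():
        if (ga, gb) == (1, 1):
            continue
        # outside the double-het cell the haplotype decomposition is forced:
        # locus1 carries ga minor copies, locus2 gb, pair greedily
        h11 = min(ga, gb)
        h12 = ga - h11
        h21 = gb - h11
        h22 = 2 - h11 - h12 - h21
        base += cnt * np.array([h11, h12, h21, h22], dtype=float)

    p1 = (base[0] + base[1] + n_dh) / (2.0 * n)
    q1 = (base[0] + base[2] + n_dh) / (2.0 * n)
    f = np.array([p1 * q1, p1 * (1 - q1), (1 - p1) * q1, (1 - p1) * (1 - q1)])
    f = np.maximum(f, 1e-12)
    f /= f.sum()

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split double heterozygotes between cis (11/22) and trans (12/21)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        expected = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new_f = expected / (2.0 * n)
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            break
        f = new_f
    ll = _pair_log_likelihood(f, counts)
    return HaplotypeFreqs(*map(float, f), log_likelihood=ll, n_iter=n_iter)


def dprime_rsq(f: HaplotypeFreqs) -> tuple[float, float]:
    """Lewontin's D' and the r^2 allelic correlation from haplotype
    frequencies.

    ``D = f11 - p1 q1``; ``D' = |D| / Dmax`` with ``Dmax`` the tightest of
    the frequency bounds in the direction of D; ``r^2 = D^2 / (p1(1-p1)
    q1(1-q1))``.
    """
    p1, q1 = f.p1, f.q1
    if not (0 < p1 < 1) or not (0 < q1 < 1):
        raise MonomorphicLocusError("degenerate margins: LD undefined")
    d = f.f11 - p1 * q1
    if d > 0:
        dmax = min(p1 * (1 - q1), (1 - p1) * q1)
    else:
        dmax = min(p1 * q1, (1 - p1) * (1 - q1))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    rsq = d * d / (p1 * (1 - p1) * q1 * (1 - q1))
    return float(min(dprime, 1.0)), float(min(rsq, 1.0))


def pairwise_ld(dataset: Dataset, region: str | None = None,
                controls_only: bool = True) -> pd.DataFrame:
    """Long-format pairwise D'/r^2 table for the SNPs of one gene region
    (or all SNPs when ``region`` is None), by default in controls only."""
    g = dataset.genotypes.dosages
    if controls_only:
        g = g.loc[dataset.subjects.table["status"] == 0]
    if region is not None:
        snps = dataset.snps_by_region().get(region)
        if not snps:
            raise KeyError(f"no SNPs annotated to region {region!r}")
    else:
        snps = list(g.columns)
    rows = []
    for i, a in enumerate(snps):
        for b in snps[i + 1:]:
            va = g[a].to_numpy(dtype=float)
            vb = g[b].to_numpy(dtype=float)
            n_pairs = int((~np.isnan(va) & ~np.isnan(vb)).sum())
            try:
                freqs = em_haplotype_freqs(va, vb)
                dp, r2 = dprime_rsq(freqs)
            except (MonomorphicLocusError, ValueError):
                dp, r2 = float("nan"), float("nan")
            rows.append({"snp_a": a, "snp_b": b, "dprime": dp, "rsq": r2, "n": n_pairs})
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "dprime", "rsq", "n"])
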