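"""Core population-genetic statistics on diploid genotype matrices.

Covers the diversity and relatedness battery of a SNP-array breed study:
observed heterozygosity, method-of-moments individual inbreeding F, the
Weir & Cockerham (1984) F_ST estimator (per-site components and genome-wide
ratio of averages), an additive-model PCA on dosages, genotypic LD r^2, and
PLINK-style method-of-moments IBS -> IBD estimation (pi-hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# allele frequencies


def group_allele_freqs(gm: GenotypeMatrix, groups=None) -> pd.DataFrame:
    """Per-group per-site allele-2 frequency, called chromosomes and het count.

    Returns a long DataFrame with columns group, site, freq, n_chrom, n_het.
    """
    if groups is None:
        groups = [g for g in dict.fromkeys(gm.groups)]
    rows = []
    for g in groups:
        idx = gm.group_index(g)
        calls = gm.calls[idx]
        called = calls != MISSING
        n_chrom = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
        n_het = (calls == 1).sum(axis=0)
        rows.append(pd.DataFrame({
            "group": g, "site": np.arange(gm.n_sites),
            "freq": freq, "n_chrom": n_chrom, "n_het": n_het,
        }))
    return pd.concat(rows, ignore_index=True)


def allele_freq(gm: GenotypeMatrix, group: str) -> np.ndarray:
    """Allele-2 frequency per site within one group (NaN where uncalled)."""
    idx = gm.group_index(group)
    calls = gm.calls[idx]
    called = calls != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# heterozygosity and inbreeding


def observed_heterozygosity(gm: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-group observed heterozygosity.

    H_o per sample is the fraction of its called sites that are heterozygous;
    the group value is the mean over members. Samples without called sites
    get NaN.
    """
    called = (gm.calls != MISSING).sum(axis=1)
    het = (gm.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    per_sample = pd.Series(ho, index=gm.sample_ids, name="H_o")
    per_group = per_sample.groupby(gm.groups).mean()
    return per_sample, per_group


def inbreeding_f(gm: GenotypeMatrix, reference_freqs: np.ndarray | None = None) -> pd.Series:
    """Method-of-moments individual inbreeding coefficient.

    F = (O_hom - E_hom) / (L - E_hom) with O_hom the observed homozygous-site
    count, E_hom = sum over called sites of (1 - 2 p q) the Hardy-Weinberg
    expectation, and L the number of called sites. By default expected
    homozygosity uses each sample's own group frequencies.
    """
    out = np.full(gm.n_samples, np.nan)
    freq_by_group = {}
    for i in range(gm.n_samples):
        if reference_freqs is not None:
            p = reference_freqs
        else:
            g = gm.groups[i]
            if g not in freq_by_group:
                freq_by_group[g] = allele_freq(gm, g)
            p = freq_by_group[g]
        calls = gm.calls[i]
        ok = (calls != MISSING) & ~np.isnan(p)
        # only polymorphic sites carry information about F
        poly = ok & (p > 0) & (p < 1)
        L = poly.sum()
        if L == 0:
            continue
        obs_hom = (calls[poly] != 1).sum()
        exp_hom = (1.0 - 2.0 * p[poly] * (1.0 - p[poly])).sum()
        denom = L - exp_hom
        if denom <= 0:
            continue
        out[i] = (obs_hom - exp_hom) / denom
    return pd.Series(out, index=gm.sample_ids, name="F")


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


@dataclass
class FstResult:
    """Per-site WC variance components and genome-wide pairwise values."""

    groups: list
    per_site: dict          # (g1, g2) -> DataFrame with a, b, c, theta
    matrix: pd.DataFrame    # symmetric genome-wide ratio-of-averages

    def genome_wide(self, g1, g2) -> float:
        return float(self.matrix.loc[g1, g2])

    def per_site_theta(self, g1, g2) -> np.ndarray:
        key = (g1, g2) if (g1, g2) in self.per_site else (g2, g1)
        return self.per_site[key]["theta"].to_numpy()


def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Per-site WC (1984) a, b, c components for two populations."""
    r = 2.0
    comps = []
    for calls in (calls_a, calls_b):
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)                 # diploid counts
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = (calls == 1).sum(axis=0) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2) | np.isnan(pbar)
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, groups=None) -> FstResult:
    """Weir-Cockerham pairwise F_ST over groups.

    The genome-wide value is the ratio of summed per-site components
    sum(a) / sum(a + b + c); per-site theta values (which may be negative)
    are retained for ancestry-informative-marker selection.
    """
    if groups is None:
        groups = [g for g in dict.fromkeys(gm.groups)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if gm.group_index(g).size < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    per_site = {}
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            a, b, c = _wc_components(gm.calls[gm.group_index(g1)],
                                     gm.calls[gm.group_index(g2)])
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = a / (a + b + c)
            per_site[(g1, g2)] = pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})
            ok = ~np.isnan(a)
            gw = np.nansum(a[ok]) / np.nansum((a + b + c)[ok])
            mat.loc[g1, g2] = mat.loc[g2, g1] = gw
    return FstResult(groups=groups, per_site=per_site, matrix=mat)


# ---------------------------------------------------------------------------
# PCA


def pca(gm: GenotypeMatrix, n_components: int = 10, standardize: bool = False):
    """PCA of the additive dosage matrix.

    Missing calls are mean-imputed per site before centering; with
    ``standardize`` each site is scaled by 1/sqrt(p(1-p)) (the
    frequency-standardized variant). Returns (coords DataFrame indexed by
    sample, explained-variance fractions).
    """
    d = gm.dosages()
    mean = np.nanmean(d, axis=0)
    if np.isnan(mean).any():
        raise ValueError("site with no called genotypes")
    inds = np.where(np.isnan(d))
    d[inds] = mean[inds[1]]
    x = d - mean
    if standardize:
        p = mean / 2.0
        scale = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        x = x / scale
    if not np.any(x):
        raise ValueError("zero-variance genotype matrix")
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2
    frac = ev / ev.sum()
    k = min(n_components, len(s))
    coords = pd.DataFrame(u[:, :k] * s[:k], index=gm.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return coords, frac[:k]


# ---------------------------------------------------------------------------
# LD r^2


def ld_r2(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of dosages over shared called samples."""
    a, b = gm.calls[:, site_i], gm.calls[:, site_j]
    ok = (a != MISSING) & (b != MISSING)
    x, y = a[ok].astype(float), b[ok].astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# method-of-moments IBD (PLINK-style)


def _ibs_expectations(freqs: np.ndarray, n_chrom: np.ndarray):
    """Expected per-site IBS-state probabilities given IBD state.

    Uses unbiased falling-factorial estimators of the allele-frequency
    moments, so the expectations account for frequencies being estimated from
    a finite sample of ``n_chrom`` chromosomes per site.
    """
    T = n_chrom.astype(float)
    k = freqs * T          # allele-2 count
    kq = T - k

    def ff(x, m):
        out = np.ones_like(x)
        for i in range(m):
            out = out * np.maximum(x - i, 0.0)
        return out

    def moment(mp, mq):
        return ff(k, mp) * ff(kq, mq) / ff(T, mp + mq)

    p2q2 = moment(2, 2)
    p3q = moment(3, 1)
    pq3 = moment(1, 3)
    p4 = moment(4, 0)
    q4 = moment(0, 4)
    p2q = moment(2, 1)
    pq2 = moment(1, 2)
    p3 = moment(3, 0)
    q3 = moment(0, 3)

    e0_z0 = 2 * p2q2
    e1_z0 = 4 * p3q + 4 * pq3
    e2_z0 = p4 + q4 + 4 * p2q2
    e1_z1 = 2 * p2q + 2 * pq2
    e2_z1 = p3 + q3 + p2q + pq2
    return e0_z0, e1_z0, e2_z0, e1_z1, e2_z1


def ibd_pihat(gm: GenotypeMatrix, pair: tuple, freqs: np.ndarray | None = None,
              n_chrom: np.ndarray | None = None, min_sites: int = 100) -> dict:
    """PLINK-style method-of-moments IBD sharing for one sample pair.

    Returns a dict with P0, P1, P2 (probabilities of sharing 0/1/2 alleles
    IBD), ``pi_hat`` = P1/2 + P2 truncated to [0, 1], the number of shared
    called sites, and a ``low_confidence`` flag when that number is below
    ``min_sites``. Frequencies default to the whole-matrix estimate.
    """
    i = gm.sample_ids.index(pair[0])
    j = gm.sample_ids.index(pair[1])
    if freqs is None:
        called = gm.calls != MISSING
        n_chrom = 2 * called.sum(axis=0).astype(float)
        alt = np.where(called, gm.calls, 0).sum(axis=0)
        freqs = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    elif n_chrom is None:
        n_chrom = np.full(gm.n_sites, 2.0 * gm.n_samples)

    a, b = gm.calls[i], gm.calls[j]
    ok = (a != MISSING) & (b != MISSING) & ~np.isnan(freqs)
    ok &= (freqs > 0) & (freqs < 1) & (n_chrom >= 4)
    n_shared = int(ok.sum())
    ibs = 2 - np.abs(a[ok].astype(int) - b[ok].astype(int))
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    n2 = float((ibs == 2).sum())

    e0_z0, e1_z0, e2_z0, e1_z1, e2_z1 = _ibs_expectations(freqs[ok], n_chrom[ok])
    E0_z0, E1_z0, E2_z0 = e0_z0.sum(), e1_z0.sum(), e2_z0.sum()
    E1_z1, E2_z1 = e1_z1.sum(), e2_z1.sum()

    z0 = n0 / E0_z0 if E0_z0 > 0 else 0.0
    z1 = (n1 - z0 * E1_z0) / E1_z1 if E1_z1 > 0 else 0.0
    z2 = (n2 - z0 * E2_z0 - z1 * E2_z1) / n_shared if n_shared else 0.0
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    if z.sum() > 0:
        z = z / z.sum()
    pihat = float(np.clip(z[1] / 2 + z[2], 0.0, 1.0))
    return {"P0": float(z[0]), "P1": float(z[1]), "P2": float(z[2]),
            "pi_hat": pihat, "n_sites": n_shared,
            "low_confidence": n_shared < min_sites}


def ibd_matrix(gm: GenotypeMatrix, sample_ids=None, freqs=None) -> pd.DataFrame:
    """pi-hat for every pair among ``sample_ids`` (default: all samples)."""
    if sample_ids is None:
        sample_ids = list(gm.sample_ids)
    rows = []
    for i in range(len(sample_ids)):
        for j in range(i + 1, len(sample_ids)):
            res = ibd_pihat(gm, (sample_ids[i], sample_ids[j]), freqs=freqs)
            rows.append({"id1": sample_ids[i], "id2": sample_ids[j], **res})
    return pd.DataFrame(rows)


__all__ = [
    "group_allele_freqs", "allele_freq", "observed_heterozygosity",
    "inbreeding_f", "FstResult", "pairwise_fst", "pca", "ld_r2",
    "ibd_pihat", "ibd_matrix",
]
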