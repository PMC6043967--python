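"""Quality-control filtering cascade for SNP-array genotype matrices.

The canonical cascade is: drop sex chromosomes, drop samples then sites with
call rate <= threshold (default 95%), LD-prune with a sliding window of 50
SNPs at r^2 > 0.2, and optionally keep only complete-case sites. Each step
returns a new matrix and the cascade reports the surviving counts per stage.
"""

from __future__ import annotations

import numpy as np

from .containers import MISSING, GenotypeMatrix

DEFAULT_SEX_ALIASES = ("x", "y", "chrx", "chry", "39", "chr39")


def drop_sex_chromosomes(gm: GenotypeMatrix, aliases=DEFAULT_SEX_ALIASES) -> GenotypeMatrix:
    """Remove sites whose chromosome label matches a sex-chromosome alias."""
    labels = gm.sites["chrom"].astype(str).str.lower()
    keep = ~labels.isin([a.lower() for a in aliases])
    return gm.take_sites(np.flatnonzero(keep.to_numpy()))


def filter_call_rate(gm: GenotypeMatrix, threshold: float = 0.95) -> GenotypeMatrix:
    """Drop samples, then sites, with call rate <= ``threshold``.

    The inequality is non-strict on the removal side: a call rate exactly at
    the threshold is removed. Samples are filtered first; site call rates are
    then recomputed over the surviving samples.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    keep_samples = np.flatnonzero(gm.sample_call_rate() > threshold)
    if keep_samples.size == 0:
        raise ValueError("call-rate filter removed every sample")
    gm = gm.take_samples(keep_samples)
    keep_sites = np.flatnonzero(gm.site_call_rate() > threshold)
    return gm.take_sites(keep_sites)


def pairwise_complete_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs squared dosage correlation with pairwise-complete samples.

    Pairs with fewer than 2 shared called samples or zero variance at either
    site get r^2 = 0.
    """
    valid = (calls != MISSING).astype(float)
    x = np.where(calls == MISSING, 0, calls).astype(float)
    n = valid.T @ valid                     # shared called samples per pair
    sx = x.T @ valid                        # sum of x_i over shared samples
    sxx = (x * x).T @ valid
    cov = n * (x.T @ x) - sx * sx.T
    var_x = n * sxx - sx * sx               # variance term of site i within pair (i, j)
    denom = var_x * var_x.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((denom > 0) & (n >= 2), cov * cov / denom, 0.0)
    return r2


def ld_prune(gm: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.2) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on genotypic r^2.

    Within each window (advanced by ``step_snps``, never crossing a chromosome
    boundary) every pair of still-kept sites with r^2 > ``r2_max`` triggers a
    removal: the site with the lower call rate goes; ties remove the
    right-hand (later) site. Passes repeat left to right until no site is
    removed (removals shift surviving sites into shared windows), so the
    operation is idempotent: re-pruning the output removes nothing.
    """
    if window_snps < 2:
        raise ValueError("window must span at least 2 SNPs")
    keep = np.ones(gm.n_sites, dtype=bool)
    call_rate = gm.site_call_rate()
    chroms = gm.sites["chrom"].to_numpy()

    def one_pass() -> bool:
        removed = False
        alive = np.flatnonzero(keep)
        bounds = {}
        for k, j in enumerate(alive):
            c = chroms[j]
            bounds.setdefault(c, [k, k])
            bounds[c][1] = k
        for c, (lo, hi) in bounds.items():
            for w0 in range(lo, hi + 1, step_snps):
                w1 = min(w0 + window_snps, hi + 1)
                win = alive[w0:w1]
                r2 = pairwise_complete_r2(gm.calls[:, win])
                for a in range(len(win)):
                    i = win[a]
                    if not keep[i]:
                        continue
                    for b in range(a + 1, len(win)):
                        j = win[b]
                        if not keep[i]:
                            break
                        if not keep[j]:
                            continue
                        if r2[a, b] > r2_max:
                            removed = True
                            if call_rate[i] < call_rate[j]:
                                keep[i] = False
                            else:
                                keep[j] = False
                if w1 == hi + 1:
                    break
        return removed

    while one_pass():
        pass
    return gm.take_sites(np.flatnonzero(keep))


def remove_missing_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites with zero missing calls."""
    keep = (gm.calls != MISSING).all(axis=0)
    return gm.take_sites(np.flatnonzero(keep))


def qc_cascade(gm: GenotypeMatrix, call_rate: float = 0.95, drop_sex: bool = True,
               ld_window: int = 50, ld_step: int = 5, ld_r2: float = 0.2,
               complete_cases: bool = False) -> tuple[GenotypeMatrix, dict]:
    """Run the full cascade; returns the filtered matrix and a stage report."""
    report = {"input": {"samples": gm.n_samples, "sites": gm.n_sites}}
    if drop_sex:
        gm = drop_sex_chromosomes(gm)
        report["autosomal"] = {"samples": gm.n_samples, "sites": gm.n_sites}
    gm = filter_call_rate(gm, call_rate)
    report["quality_pruned"] = {"samples": gm.n_samples, "sites": gm.n_sites}
    gm = ld_prune(gm, ld_window, ld_step, ld_r2)
    report["ld_pruned"] = {"samples": gm.n_samples, "sites": gm.n_sites}
    if complete_cases:
        gm = remove_missing_sites(gm)
        report["complete_cases"] = {"samples": gm.n_samples, "sites": gm.n_sites}
    return gm, report


__all__ = [
    "drop_sex_chromosomes", "filter_call_rate", "ld_prune",
    "remove_missing_sites", "qc_cascade", "DEFAULT_SEX_ALIASES",
]
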