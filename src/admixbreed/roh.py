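"""Runs of homozygosity: detection, F_ROH, summaries, shared regions.

A run is a maximal stretch of consecutive SNPs (within one chromosome) that
contains at most ``max_het`` heterozygous and ``max_missing`` missing calls,
with no inter-SNP gap above ``max_gap_kb``; candidate runs are trimmed of
leading/trailing non-homozygous sites and kept if they span at least
``min_snps`` SNPs and ``min_kb`` kb. Coordinates are the first and last SNP
positions of the run (1-based, inclusive). Scanning is greedy left to right:
when a budget would be exceeded the current run closes and the scan restarts
just after the violating site, so runs never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Intervals


@dataclass
class ROHParams:
    min_snps: int = 25
    min_kb: float = 500.0
    max_het: int = 1
    max_missing: int = 2
    max_gap_kb: float = 1000.0

    def __post_init__(self):
        if min(self.min_snps, self.min_kb, self.max_het, self.max_missing,
               self.max_gap_kb) < 0:
            raise ValueError("ROH parameters must be non-negative")


@dataclass
class ROHSet:
    """Per-sample homozygous runs."""

    runs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample", "chrom", "start", "end", "n_snps", "n_het", "n_missing"]))

    def for_sample(self, sample) -> pd.DataFrame:
        return self.runs[self.runs["sample"] == sample]

    def total_length(self, sample) -> float:
        sub = self.for_sample(sample)
        return float((sub["end"] - sub["start"]).sum())


def _scan_chromosome(pos, calls, params: ROHParams):
    """Greedy ROH scan over one chromosome of one sample."""
    runs = []
    n = len(pos)
    i = 0
    max_gap = params.max_gap_kb * 1000.0

    def flush(lo, hi, het, miss):
        # trim to homozygous called endpoints
        while lo <= hi and calls[lo] != 0 and calls[lo] != 2:
            if calls[lo] == 1:
                het -= 1
            else:
                miss -= 1
            lo += 1
        while hi >= lo and calls[hi] != 0 and calls[hi] != 2:
            if calls[hi] == 1:
                het -= 1
            else:
                miss -= 1
            hi -= 1
        if lo > hi:
            return
        n_snps = hi - lo + 1
        length = pos[hi] - pos[lo]
        if n_snps >= params.min_snps and length >= params.min_kb * 1000.0:
            runs.append((int(pos[lo]), int(pos[hi]), n_snps, het, miss))

    while i < n:
        # seek a called homozygous start
        if calls[i] != 0 and calls[i] != 2:
            i += 1
            continue
        lo = i
        het = miss = 0
        j = i
        while j + 1 < n:
            nxt = calls[j + 1]
            if pos[j + 1] - pos[j] > max_gap:
                break
            if nxt == 1 and het + 1 > params.max_het:
                break
            if nxt == MISSING and miss + 1 > params.max_missing:
                break
            j += 1
            if nxt == 1:
                het += 1
            elif nxt == MISSING:
                miss += 1
        flush(lo, j, het, miss)
        # restart just past the run; a violating het/missing site at j+1 is
        # skipped by the seek loop above
        i = j + 1
    return runs


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None,
               samples=None) -> ROHSet:
    """Detect homozygous runs for the requested samples (default: all)."""
    if params is None:
        params = ROHParams()
    if samples is None:
        samples = list(gm.sample_ids)
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    rows = []
    for sid in samples:
        i = gm.sample_ids.index(sid)
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            pos = pos_all[idx]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"sites unsorted on chromosome {chrom}")
            for start, end, n_snps, het, miss in _scan_chromosome(
                    pos, gm.calls[i, idx], params):
                rows.append((sid, chrom, start, end, n_snps, het, miss))
    return ROHSet(pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "n_het", "n_missing"]))


def froh(rohset: ROHSet, sample, covered_length: float) -> float:
    """Fraction of the SNP-covered genome lying in runs of homozygosity."""
    if covered_length <= 0:
        raise ValueError("covered length must be positive")
    return rohset.total_length(sample) / covered_length


def froh_all(rohset: ROHSet, gm: GenotypeMatrix) -> pd.Series:
    cov = gm.covered_length()
    return pd.Series({s: froh(rohset, s, cov) for s in gm.sample_ids}, name="F_ROH")


def roh_summary(rohset: ROHSet, groups: dict, bin_kb: float = 500.0) -> pd.DataFrame:
    """Per-group mean run count, mean run length and a length histogram.

    ``groups`` maps sample id -> group label. Histogram bins are ``bin_kb``
    wide starting at zero; the returned frame has one row per group with
    count/length means and SDs and the histogram as a list column.
    """
    rows = []
    by_group: dict = {}
    for sid, g in groups.items():
        by_group.setdefault(g, []).append(sid)
    for g, sids in by_group.items():
        counts, lengths = [], []
        for sid in sids:
            sub = rohset.for_sample(sid)
            counts.append(len(sub))
            lengths += list((sub["end"] - sub["start"]).to_numpy())
        lengths = np.asarray(lengths, dtype=float)
        if len(lengths):
            edges = np.arange(0, lengths.max() + bin_kb * 1000, bin_kb * 1000)
            hist = np.histogram(lengths, bins=edges)[0].tolist()
        else:
            hist = []
        rows.append({
            "group": g,
            "mean_count": float(np.mean(counts)),
            "sd_count": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
            "mean_length_kb": float(lengths.mean() / 1000) if len(lengths) else np.nan,
            "sd_length_kb": float(lengths.std(ddof=1) / 1000) if len(lengths) > 1 else 0.0,
            "histogram": hist,
        })
    return pd.DataFrame(rows)


def shared_roh_regions(rohset: ROHSet, samples) -> Intervals:
    """Genomic regions inside a run of homozygosity in every listed sample.

    Interval intersection of the per-sample ROH unions; run coordinates
    (1-based inclusive SNP positions) are converted to BED half-open.
    """
    result = None
    for sid in samples:
        sub = rohset.for_sample(sid)
        iv = Intervals(pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["start"].to_numpy() - 1,
            "end": sub["end"].to_numpy(),
            "label": "",
        })) if len(sub) else Intervals()
        result = iv if result is None else result.intersect(iv)
        if len(result) == 0:
            return Intervals()
    return result if result is not None else Intervals()


__all__ = ["ROHParams", "ROHSet", "detect_roh", "froh", "froh_all",
           "roh_summary", "shared_roh_regions"]
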