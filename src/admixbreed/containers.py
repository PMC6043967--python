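"""Core in-memory containers shared by every stage of the pipeline.

The central object is :class:`GenotypeMatrix`: diploid SNP-array-style calls
(0/1/2 copies of the second allele, ``-1`` for missing) for samples carrying a
group label (``breed``, ``wild_parent``, ``dom_parent`` or ``other``) over a
sorted site table. :class:`HaplotypeSet` holds two binary haplotypes per sample
aligned to the same site index, :class:`GeneticMap` converts physical to
genetic distance (default 100 Mb = 1 Morgan), and :class:`Intervals` is a
minimal BED-convention (0-based, half-open) interval set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VALID_GROUPS = ("breed", "wild_parent", "dom_parent", "other")

SITE_COLUMNS = ["chrom", "pos", "allele1", "allele2"]


def _site_table(chrom, pos, allele1=None, allele2=None) -> pd.DataFrame:
    n = len(pos)
    if allele1 is None:
        allele1 = ["A"] * n
    if allele2 is None:
        allele2 = ["B"] * n
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "allele1": np.asarray(allele1, dtype=object),
            "allele2": np.asarray(allele2, dtype=object),
        }
    )


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for labelled samples over a sorted site table.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, row order of ``calls``.
    groups : ndarray of str
        Group label per sample, one of ``breed``, ``wild_parent``,
        ``dom_parent``, ``other``.
    sites : DataFrame
        Columns ``chrom``, ``pos`` (1-based bp), ``allele1``, ``allele2``;
        positions strictly increasing within each chromosome.
    calls : ndarray, int8, shape (n_samples, n_sites)
        Copies of ``allele2`` (0, 1, 2) or ``-1`` for missing.
    """

    sample_ids: list
    groups: np.ndarray
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.groups = np.asarray(self.groups, dtype=object)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids")
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls outside {0,1,2,missing}")
        for g in np.unique(self.groups):
            if g not in VALID_GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_index(self, group: str) -> np.ndarray:
        """Row indices of the samples in ``group``."""
        return np.flatnonzero(self.groups == group)

    # -- subsetting --------------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            groups=self.groups.copy(),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=self.groups[idx].copy(),
            sites=self.sites.copy().reset_index(drop=True),
            calls=self.calls[idx].copy(),
        )

    # -- rates -------------------------------------------------------------
    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def site_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def dosages(self) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def covered_length(self) -> float:
        """Total bp spanned by the SNPs: sum over chromosomes of last-first."""
        total = 0
        for _, sub in self.sites.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            total += int(p[-1] - p[0])
        return float(total)


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes, two rows per sample, over a shared site table.

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``;
    values are copies of ``allele2`` (0/1). The pair must sum to the genotype
    call at every non-missing site of the matching :class:`GenotypeMatrix`.
    """

    sample_ids: list
    sites: pd.DataFrame
    haplotypes: np.ndarray  # int8, (2*n_samples, n_sites)
    phased: bool = True

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.sites)):
            raise ValueError("haplotype array shape mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def hap_ids(self) -> list:
        return [f"{s}_h{k}" for s in self.sample_ids for k in (1, 2)]

    def to_genotypes(self, groups=None) -> GenotypeMatrix:
        calls = self.haplotypes[0::2] + self.haplotypes[1::2]
        if groups is None:
            groups = np.array(["other"] * len(self.sample_ids), dtype=object)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            groups=np.asarray(groups, dtype=object),
            sites=self.sites.copy().reset_index(drop=True),
            calls=calls,
        )

    def check_consistent(self, gm: GenotypeMatrix) -> None:
        """Raise if pair sums mismatch genotype calls at non-missing sites."""
        if list(gm.sample_ids) != list(self.sample_ids):
            raise ValueError("sample ids differ")
        sums = self.haplotypes[0::2] + self.haplotypes[1::2]
        ok = (gm.calls == MISSING) | (sums == gm.calls)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"haplotype pair sum mismatches genotype for sample "
                f"{gm.sample_ids[i]} at site index {j}"
            )


class GeneticMap:
    """Physical-to-genetic distance conversion.

    Default is linear with ``rate`` Morgans per bp (1e-8, i.e. 100 Mb = 1
    Morgan). A per-chromosome table of (bp, Morgans) anchor points can be
    supplied instead; conversion then interpolates linearly between anchors
    and extrapolates with the terminal segment rate.
    """

    def __init__(self, rate: float = 1e-8, tables: dict | None = None):
        if rate <= 0:
            raise ValueError("rate must be positive")
        self.rate = rate
        self.tables = {}
        if tables:
            for chrom, tab in tables.items():
                bp = np.asarray([t[0] for t in tab], dtype=float)
                cm = np.asarray([t[1] for t in tab], dtype=float)
                if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                    raise ValueError(f"map table for {chrom} not monotone")
                self.tables[str(chrom)] = (bp, cm)

    def bp_to_morgans(self, chrom, bp) -> np.ndarray | float:
        bp_arr = np.asarray(bp, dtype=float)
        if np.any(bp_arr < 0):
            raise ValueError("bp must be non-negative")
        key = str(chrom)
        if key in self.tables:
            xs, ys = self.tables[key]
            out = np.interp(bp_arr, xs, ys)
        else:
            out = bp_arr * self.rate
        return float(out) if np.isscalar(bp) else out

    def chrom_length_morgans(self, chrom, length_bp: int) -> float:
        return float(self.bp_to_morgans(chrom, length_bp))


@dataclass
class Intervals:
    """BED-convention genomic intervals: 0-based, half-open, start < end."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label"])
    )

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        if "label" not in df.columns:
            df["label"] = ""
        df = df[["chrom", "start", "end", "label"]]
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] >= df["end"]).any():
                raise ValueError("interval with start >= end")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "Intervals":
        return Intervals(self.records.sort_values(["chrom", "start", "end"]))

    def total_length(self) -> int:
        if not len(self.records):
            return 0
        return int((self.records["end"] - self.records["start"]).sum())

    def merged(self) -> "Intervals":
        """Union of the intervals (overlapping/adjacent runs merged)."""
        out = []
        for chrom, sub in self.sorted().records.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for _, r in sub.iterrows():
                if cur_s is None:
                    cur_s, cur_e = r["start"], r["end"]
                elif r["start"] <= cur_e:
                    cur_e = max(cur_e, r["end"])
                else:
                    out.append((chrom, cur_s, cur_e, ""))
                    cur_s, cur_e = r["start"], r["end"]
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e, ""))
        return Intervals(pd.DataFrame(out, columns=["chrom", "start", "end", "label"]))

    def intersect(self, other: "Intervals") -> "Intervals":
        """Intersection of the two merged interval unions."""
        a = self.merged().records
        b = other.merged().records
        out = []
        for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
            xa = a[a["chrom"] == chrom][["start", "end"]].to_numpy()
            xb = b[b["chrom"] == chrom][["start", "end"]].to_numpy()
            i = j = 0
            while i < len(xa) and j < len(xb):
                s = max(xa[i, 0], xb[j, 0])
                e = min(xa[i, 1], xb[j, 1])
                if s < e:
                    out.append((chrom, int(s), int(e), ""))
                if xa[i, 1] < xb[j, 1]:
                    i += 1
                else:
                    j += 1
        return Intervals(pd.DataFrame(out, columns=["chrom", "start", "end", "label"]))


__all__ = [
    "MISSING",
    "VALID_GROUPS",
    "GenotypeMatrix",
    "HaplotypeSet",
    "GeneticMap",
    "Intervals",
]
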