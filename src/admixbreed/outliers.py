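"""Ancestry-informative-marker panels and outlier-region consolidation.

Panel 1 comes from local-ancestry deconvolution (blocks fixed for one
ancestry across the whole cohort), panel 2 from shared runs of homozygosity,
and panel 3 from allele-frequency differentiation: among the SNPs where the
two parental populations are fixed for opposite alleles (per-site parental
F_ST = 1), the breed's 1% with the lowest F_ST against one parent marks
regions where the breed resembles that parent only ("wolf-like" /
"dog-like" SNPs or 10-SNP blocks). Candidate sites and blocks are expanded
by +-50 kb and the panels merged into one table with per-region method
provenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Intervals
from .stats import allele_freq, pairwise_fst


def fixed_diff_sites(gm: GenotypeMatrix, wolf_group: str = "wild_parent",
                     dog_group: str = "dom_parent") -> np.ndarray:
    """Site indices where the parental groups are fixed for opposite alleles.

    Requires the within-group frequency on called chromosomes to be exactly 0
    in one parent and exactly 1 in the other (per-site parental F_ST = 1).
    """
    pw = allele_freq(gm, wolf_group)
    pdg = allele_freq(gm, dog_group)
    ok = ~np.isnan(pw) & ~np.isnan(pdg)
    fixed = ok & (((pw == 1.0) & (pdg == 0.0)) | ((pw == 0.0) & (pdg == 1.0)))
    return np.flatnonzero(fixed)


def aim_select(gm: GenotypeMatrix, fixed_sites: np.ndarray, fraction: float = 0.01,
               unit: str = "snp", block_size: int = 10,
               breed_group: str = "breed", wolf_group: str = "wild_parent",
               dog_group: str = "dom_parent"):
    """Select wolf-like and dog-like markers among fixed-difference sites.

    Scores each fixed-difference SNP (or non-overlapping ``block_size``-SNP
    block of them, scored by mean per-site value) by WC F_ST between the
    breed and each parent, and retains the lowest-``fraction`` quantile per
    contrast; ties at the boundary are all retained. Returns a dict with
    ``wolf_like`` and ``dog_like`` index arrays (site indices for unit="snp",
    block row indices plus a block table for unit="block10").
    """
    if len(fixed_sites) == 0:
        raise ValueError("no fixed-difference sites to select from")
    if unit not in ("snp", "block10"):
        raise ValueError("unit must be 'snp' or 'block10'")
    fst = pairwise_fst(gm, [breed_group, wolf_group, dog_group])
    t_bw = fst.per_site_theta(breed_group, wolf_group)
    t_bd = fst.per_site_theta(breed_group, dog_group)
    # WC theta is undefined for a monomorphic pair; when the breed is fixed
    # for the same allele as the parent that is zero differentiation, the
    # strongest possible "like that parent" signal
    pb = allele_freq(gm, breed_group)
    for theta, pp in ((t_bw, allele_freq(gm, wolf_group)),
                      (t_bd, allele_freq(gm, dog_group))):
        same = np.isnan(theta) & (np.abs(pb - pp) < 1e-12)
        theta[same] = 0.0

    if unit == "snp":
        scores_w = t_bw[fixed_sites]
        scores_d = t_bd[fixed_sites]
        items = fixed_sites
        table = None
    else:
        chroms = gm.sites["chrom"].to_numpy()[fixed_sites]
        blocks, bw, bd = [], [], []
        for chrom in dict.fromkeys(chroms):
            members = fixed_sites[chroms == chrom]
            for lo in range(0, len(members) - block_size + 1, block_size):
                sel = members[lo:lo + block_size]
                blocks.append((chrom, sel[0], sel[-1]))
                bw.append(np.nanmean(t_bw[sel]))
                bd.append(np.nanmean(t_bd[sel]))
        if not blocks:
            raise ValueError("not enough fixed-difference sites to form a block")
        scores_w = np.asarray(bw)
        scores_d = np.asarray(bd)
        items = np.arange(len(blocks))
        table = pd.DataFrame(blocks, columns=["chrom", "first_site", "last_site"])

    def lowest(scores):
        ok = ~np.isnan(scores)
        if fraction >= 1.0:
            return items[ok]
        cut = np.quantile(scores[ok], fraction)
        return items[ok & (scores <= cut)]

    out = {"wolf_like": lowest(scores_w), "dog_like": lowest(scores_d),
           "scores_wolf": scores_w, "scores_dog": scores_d}
    if table is not None:
        out["blocks"] = table
    overlap = np.intersect1d(out["wolf_like"], out["dog_like"])
    out["ambiguous"] = overlap
    return out


def expand_intervals(gm: GenotypeMatrix, site_indices=None, block_spans=None,
                     flank_bp: int = 50_000, chrom_lengths: dict | None = None,
                     label: str = "", merge: bool = False) -> Intervals:
    """Expand SNPs or blocks into +-``flank_bp`` genomic intervals.

    ``site_indices`` yields per-SNP windows [pos-1-flank, pos+flank) clipped
    to [0, chrom length); ``block_spans`` is an iterable of
    (chrom, start_bp, end_bp) spans expanded the same way. Overlapping
    windows are merged only when ``merge`` is set.
    """
    if chrom_lengths is None:
        raise ValueError("chromosome lengths are required for clipping")
    rows = []
    if site_indices is not None:
        chroms = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        for j in np.asarray(site_indices):
            chrom = chroms[j]
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome length for {chrom!r}")
            s = max(0, int(pos[j]) - 1 - flank_bp)
            e = min(int(chrom_lengths[chrom]), int(pos[j]) + flank_bp)
            rows.append((chrom, s, e, label))
    if block_spans is not None:
        for chrom, s_bp, e_bp in block_spans:
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome length for {chrom!r}")
            s = max(0, int(s_bp) - 1 - flank_bp)
            e = min(int(chrom_lengths[chrom]), int(e_bp) + flank_bp)
            rows.append((chrom, s, e, label))
    iv = Intervals(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
    return iv.merged() if merge else iv


def consolidate(panels: dict) -> pd.DataFrame:
    """Merge named panels into one outlier table with method provenance.

    ``panels`` maps panel name -> (Intervals, direction) with direction
    ``wolf_like`` or ``dog_like``. Overlapping intervals of the same
    direction are grouped transitively into one record listing every
    contributing method; records of conflicting direction are kept separate
    and flagged.
    """
    rows = []
    for name, (iv, direction) in panels.items():
        for _, r in iv.records.iterrows():
            rows.append({"chrom": r["chrom"], "start": int(r["start"]),
                         "end": int(r["end"]), "method": name,
                         "direction": direction})
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "methods", "n_methods", "conflict"])
    df = pd.DataFrame(rows).sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    out = []
    for (chrom, direction), sub in df.groupby(["chrom", "direction"]):
        sub = sub.sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            # half-open intervals: touching records share no base, stay apart
            if cur is None or r["start"] >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": r["start"], "end": r["end"],
                       "direction": direction, "methods": {r["method"]}}
            else:
                cur["end"] = max(cur["end"], r["end"])
                cur["methods"].add(r["method"])
        if cur is not None:
            out.append(cur)

    result = pd.DataFrame(out)
    result["n_methods"] = result["methods"].map(len)
    result["methods"] = result["methods"].map(lambda s: ",".join(sorted(s)))
    # a region claimed in both directions is a conflict; flag every record
    # overlapping an opposite-direction record
    result["conflict"] = False
    for chrom, sub in result.groupby("chrom"):
        w = sub[sub["direction"] == "wolf_like"]
        d = sub[sub["direction"] == "dog_like"]
        for wi, wr in w.iterrows():
            for di, dr in d.iterrows():
                if wr["start"] < dr["end"] and dr["start"] < wr["end"]:
                    result.loc[wi, "conflict"] = True
                    result.loc[di, "conflict"] = True
    return result.sort_values(["chrom", "start"]).reset_index(drop=True)


__all__ = ["fixed_diff_sites", "aim_select", "expand_intervals", "consolidate"]
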