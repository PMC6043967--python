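"""Text-format readers and writers: PLINK PED/MAP, BED3+, haplotype TSV.

Conventions: PED/MAP positions are 1-based; BED output is 0-based half-open.
The PED family column carries the sample's group label so that a round trip
preserves it; ``0 0`` genotypes are missing. Phased haplotypes are exchanged
as a plain TSV with one row per site and two 0/1 columns per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING, VALID_GROUPS, GenotypeMatrix, GeneticMap, HaplotypeSet, Intervals

logger = logging.getLogger(__name__)


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    The family id column is interpreted as the group label when it is one of
    the known labels, else ``other``. Sites out of positional order in the MAP
    are sorted (with a logged warning). Plain MAP files carry no allele
    columns, so allele1/allele2 are assigned in lexical order of the observed
    alleles — a deterministic convention independent of sample order.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    n_sites = len(map_df)

    sample_ids, groups, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_sites:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_sites}"
                )
            fam, iid = parts[0], parts[1]
            groups.append(fam if fam in VALID_GROUPS else "other")
            sample_ids.append(iid)
            rows.append(parts[6:])

    n_samples = len(sample_ids)
    alleles = np.array(rows, dtype=object).reshape(n_samples, n_sites, 2) if rows else np.empty((0, n_sites, 2), dtype=object)

    calls = np.full((n_samples, n_sites), MISSING, dtype=np.int8)
    a1 = np.array(["A"] * n_sites, dtype=object)
    a2 = np.array(["B"] * n_sites, dtype=object)
    for j in range(n_sites):
        col = alleles[:, j, :]
        observed = [x for x in col.ravel() if x != "0"]
        uniq = sorted(set(observed))
        if len(uniq) > 2:
            raise ValueError(
                f"site {map_df['snp_id'][j]} has more than 2 alleles: {uniq}"
            )
        if uniq:
            a1[j] = uniq[0]
            a2[j] = uniq[1] if len(uniq) > 1 else ("B" if uniq[0] != "B" else "b")
        for i in range(n_samples):
            x, y = col[i]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a2[j]) + (y == a2[j])

    sites = pd.DataFrame(
        {"chrom": map_df["chrom"].astype(object), "pos": map_df["pos"].astype(np.int64),
         "allele1": a1, "allele2": a2}
    )

    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    if not np.array_equal(order, np.arange(n_sites)):
        logger.warning("%s: sites out of positional order; reordering by (chrom, pos)", map_path)
        sites = sites.iloc[order].reset_index(drop=True)
        calls = calls[:, order]

    return GenotypeMatrix(sample_ids=sample_ids, groups=np.array(groups, dtype=object),
                          sites=sites, calls=calls)


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK text PED/MAP pair."""
    with open(map_path, "w") as fh:
        for j, r in gm.sites.iterrows():
            fh.write(f"{r['chrom']}\tsnp{j}\t0\t{r['pos']}\n")
    a1 = gm.sites["allele1"].to_numpy()
    a2 = gm.sites["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [str(gm.groups[i]), str(sid), "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_sites):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a1[j], a1[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def write_bed_intervals(iv: Intervals, path) -> None:
    """Write intervals as BED3+label, sorted by chrom then start; no merging."""
    df = iv.sorted().records
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            line = f"{r['chrom']}\t{r['start']}\t{r['end']}"
            if r["label"]:
                line += f"\t{r['label']}"
            fh.write(line + "\n")


def write_haplotype_tsv(hs: HaplotypeSet, path) -> None:
    """Site rows x haplotype columns (``<sample>_h1``, ``<sample>_h2``), 0/1."""
    df = pd.DataFrame(hs.haplotypes.T, columns=hs.hap_ids())
    out = pd.concat([hs.sites[["chrom", "pos"]].reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path, sites=None) -> HaplotypeSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    sample_ids = []
    for c in hap_cols:
        if c.endswith("_h1"):
            sample_ids.append(c[:-3])
    site_df = pd.DataFrame(
        {"chrom": df["chrom"].astype(object), "pos": df["pos"].astype(np.int64),
         "allele1": "A", "allele2": "B"}
    )
    if sites is not None:
        site_df = sites.reset_index(drop=True)
    haps = df[hap_cols].to_numpy(dtype=np.int8).T
    return HaplotypeSet(sample_ids=sample_ids, sites=site_df, haplotypes=haps)


def read_genetic_map_tsv(path, rate: float = 1e-8) -> GeneticMap:
    """Read a (chrom, bp, cM) TSV into a :class:`GeneticMap`.

    Chromosomes absent from the table fall back to the linear rate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tables = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("bp")
        tables[chrom] = list(zip(sub["bp"], sub["cm"] / 100.0))
    return GeneticMap(rate=rate, tables=tables)


def write_pedigree_tsv(ped, path) -> None:
    rows = []
    for rec in ped.records():
        rows.append((rec.id, rec.sire or "0", rec.dam or "0",
                     rec.pop_label or ".", rec.generation))
    pd.DataFrame(rows, columns=["id", "sire", "dam", "pop_label", "generation"]).to_csv(
        path, sep="\t", index=False)


def read_pedigree_tsv(path):
    from .pedigree import Pedigree
    df = pd.read_csv(path, sep="\t", dtype=str)
    ped = Pedigree()
    for _, r in df.iterrows():
        ped.add(
            r["id"],
            sire=None if r["sire"] in ("0", None) else r["sire"],
            dam=None if r["dam"] in ("0", None) else r["dam"],
            pop_label=None if r["pop_label"] in (".", None) else r["pop_label"],
            generation=int(r["generation"]),
        )
    return ped


__all__ = [
    "read_plink_text", "write_plink_text", "write_bed_intervals",
    "write_haplotype_tsv", "read_haplotype_tsv", "read_genetic_map_tsv",
    "write_pedigree_tsv", "read_pedigree_tsv",
]
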