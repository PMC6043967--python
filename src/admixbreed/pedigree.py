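"""Pedigree quantities by Wright path counting.

Implements the tabular recursive kinship algorithm on a sire/dam pedigree:
founders have self-kinship 1/2 and zero kinship to everyone else; for a
non-founder i with parents (s, d),

    f(i, j) = [f(s, j) + f(d, j)] / 2      for j earlier than i,
    f(i, i) = [1 + f(s, d)] / 2.

From the kinship matrix follow the coefficient of inbreeding COI(i) =
f(sire_i, dam_i), Wright's coefficient of relatedness
COR(i, j) = 2 f(i, j) / sqrt((1 + COI_i)(1 + COI_j)), and the expected
founder-ancestry fraction (mean of parental fractions, a martingale down the
pedigree). These are the pedigree-side counterparts of the genomic F_ROH and
IBD pi-hat statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    pop_label: str | None
    generation: int


class Pedigree:
    """Directed acyclic sire/dam records with founder population labels."""

    def __init__(self):
        self._records: dict[str, PedigreeRecord] = {}

    def add(self, id, sire=None, dam=None, pop_label=None, generation=0):
        if id in self._records:
            raise ValueError(f"duplicate pedigree id {id!r}")
        if (sire is None) != (dam is None):
            raise ValueError(f"{id!r}: both parents or neither must be known")
        if sire is None and pop_label is None:
            raise ValueError(f"founder {id!r} must carry a population label")
        for p in (sire, dam):
            if p is not None and p not in self._records:
                raise ValueError(f"{id!r}: parent {p!r} not yet in pedigree")
        self._records[id] = PedigreeRecord(id, sire, dam, pop_label, generation)

    def __contains__(self, id) -> bool:
        return id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[PedigreeRecord]:
        return list(self._records.values())

    def ids(self) -> list[str]:
        return list(self._records)

    def record(self, id) -> PedigreeRecord:
        if id not in self._records:
            raise KeyError(f"unknown pedigree id {id!r}")
        return self._records[id]

    def founders(self) -> list[str]:
        return [r.id for r in self._records.values() if r.sire is None]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self._records.values():
            g.add_node(r.id)
            if r.sire is not None:
                g.add_edge(r.sire, r.id)
                g.add_edge(r.dam, r.id)
        return g

    def topological_order(self) -> list[str]:
        g = self.graph()
        try:
            cycles = list(nx.find_cycle(g))
        except nx.NetworkXNoCycle:
            cycles = []
        if cycles:
            raise ValueError(f"pedigree contains a cycle: {cycles}")
        # insertion order already respects parents-before-offspring (enforced
        # by add); keep it for determinism
        return list(self._records)


def kinship_matrix(ped: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Full kinship matrix f(i, j) over all individuals, tabular recursion."""
    order = ped.topological_order()
    index = {id_: k for k, id_ in enumerate(order)}
    n = len(order)
    f = np.zeros((n, n))
    for i, id_ in enumerate(order):
        rec = ped.record(id_)
        if rec.sire is None:
            f[i, i] = 0.5
            continue
        s, d = index[rec.sire], index[rec.dam]
        for j in range(i):
            f[i, j] = f[j, i] = 0.5 * (f[s, j] + f[d, j])
        f[i, i] = 0.5 * (1.0 + f[s, d])
    return f, order


def coi(ped: Pedigree, id) -> float:
    """Coefficient of inbreeding: kinship of the parents (0 for founders)."""
    rec = ped.record(id)
    if rec.sire is None:
        return 0.0
    f, order = kinship_matrix(ped)
    index = {x: k for k, x in enumerate(order)}
    return float(f[index[rec.sire], index[rec.dam]])


def coi_all(ped: Pedigree) -> dict[str, float]:
    f, order = kinship_matrix(ped)
    index = {x: k for k, x in enumerate(order)}
    out = {}
    for rec in ped.records():
        if rec.sire is None:
            out[rec.id] = 0.0
        else:
            out[rec.id] = float(f[index[rec.sire], index[rec.dam]])
    return out


def cor(ped: Pedigree, i, j, normalize: bool = True) -> float:
    """Wright's coefficient of relatedness between two individuals.

    With ``normalize=False`` the raw numerator relationship 2 f(i, j) is
    returned instead (the additive-relationship convention some pedigree
    software reports).
    """
    f, order = kinship_matrix(ped)
    index = {x: k for k, x in enumerate(order)}
    if i not in index or j not in index:
        raise KeyError("unknown pedigree id")
    fij = f[index[i], index[j]]
    if not normalize:
        return float(2.0 * fij)
    ci, cj = coi_all(ped)[i], coi_all(ped)[j]
    return float(2.0 * fij / np.sqrt((1.0 + ci) * (1.0 + cj)))


def cor_matrix(ped: Pedigree, ids=None, normalize: bool = True):
    """COR for every pair among ``ids`` from one kinship evaluation."""
    f, order = kinship_matrix(ped)
    index = {x: k for k, x in enumerate(order)}
    if ids is None:
        ids = order
    sel = np.array([index[i] for i in ids])
    sub = 2.0 * f[np.ix_(sel, sel)]
    if normalize:
        self_k = np.array([f[index[i], index[i]] for i in ids])
        scale = np.sqrt(2.0 * self_k)        # sqrt(1 + COI)
        sub = sub / np.outer(scale, scale)
    return pd.DataFrame(sub, index=ids, columns=ids)


def expected_ancestry_fraction(ped: Pedigree, founder_label: str) -> dict[str, float]:
    """Expected fraction of the genome tracing to founders with the label.

    Founder fraction is 1 for founders carrying ``founder_label``, 0 for other
    labelled founders; each non-founder is the mean of its parents.
    """
    out: dict[str, float] = {}
    for id_ in ped.topological_order():
        rec = ped.record(id_)
        if rec.sire is None:
            if rec.pop_label is None:
                raise ValueError(f"founder {id_!r} has no population label")
            out[id_] = 1.0 if rec.pop_label == founder_label else 0.0
        else:
            out[id_] = 0.5 * (out[rec.sire] + out[rec.dam])
    return out


__all__ = [
    "Pedigree", "PedigreeRecord", "kinship_matrix", "coi", "coi_all", "cor",
    "cor_matrix", "expected_ancestry_fraction",
]
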