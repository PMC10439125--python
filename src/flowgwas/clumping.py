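"""Greedy LD clumping and novelty classification.

The conditional analysis runs independently per trait, so one causal
signal can surface as different conditionally significant variants for
different traits.  Clumping partitions the pooled set into groups of
variants connected by chains of pairwise LD r^2 above a threshold
(connected components of the thresholded LD graph — equivalent to the
iterative pair-merging formulation), and each clump is then classified
as novel or known per cell type against a prior catalogue of published
variant–cell-type associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CLUMP_R2 = 0.8

#: published cell-type assignment of the classical complete-blood-count
#: traits used when matching prior-catalogue signals by cell type
CCBC_CELL_TYPES: dict[str, str] = {
    "MPV": "platelet",
    "PCT": "platelet",
    "PDW": "platelet",
    "PLT#": "platelet",
    "HCT": "red_cell",
    "HGB": "red_cell",
    "HLSR#": "red_cell",
    "HLSR%": "red_cell",
    "IRF": "red_cell",
    "MCH": "red_cell",
    "MCHC": "red_cell",
    "MCV": "red_cell",
    "RBC#": "red_cell",
    "NEUT#": "neutrophil",
    "EO#": "eosinophil",
    "BASO#": "basophil",
    "MONO#": "monocyte",
    "LYMPH#": "lymphocyte",
}


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Raises for constant vectors, where r^2 is undefined.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("r^2 undefined for a constant dosage vector")
    c = np.cov(a, b, ddof=0)
    return float(c[0, 1] ** 2 / (c[0, 0] * c[1, 1]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class Clump:
    members: list[str]
    traits: set[str] = field(default_factory=set)
    cell_types: set[str] = field(default_factory=set)
    novelty: dict[str, bool] = field(default_factory=dict)


def greedy_clump(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window: int | None = 10_000_000,
) -> list[list[str]]:
    """Partition variants into LD clumps (connected components).

    Edges join pairs with r^2 strictly above ``r2_threshold``.  Pairs on
    different chromosomes have r^2 defined as zero; with a ``window``,
    pairs further apart than the window are not evaluated (pass ``None``
    for exact all-pairs mode).  The result is canonical: connected
    components do not depend on input order.
    """
    m = len(variants)
    uf = _UnionFind(m)
    chroms = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy()
    for i in range(m):
        for j in range(i + 1, m):
            if chroms[i] != chroms[j]:
                continue
            if window is not None and abs(int(pos[i]) - int(pos[j])) > window:
                continue
            if ld_r2(dosages[:, i], dosages[:, j]) > r2_threshold:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    ids = variants["id"].tolist()
    for i in range(m):
        groups.setdefault(uf.find(i), []).append(ids[i])
    return [sorted(g, key=lambda v: ids.index(v)) for _, g in sorted(groups.items())]


def classify_novelty(
    clumps: list[list[str]],
    assignments: pd.DataFrame,
    catalogue: pd.DataFrame,
    trait_cell_type: dict[str, str],
    clump_dosages: dict[str, np.ndarray],
    catalogue_dosages: dict[str, np.ndarray],
    r2_threshold: float = DEFAULT_CLUMP_R2,
    variant_chrom: dict[str, str] | None = None,
) -> list[Clump]:
    """Flag each clump novel/known per cell type.

    ``assignments`` maps member variants to the traits they are
    conditionally significant for; ``trait_cell_type`` maps traits to
    cell types; the catalogue carries previously reported variants with
    their cell-type labels (and dosages in the analysis sample, for LD).
    A clump is *novel* for cell type X iff it contains at least one
    variant associated with an X trait and no member is in strong LD
    (r^2 > threshold, same chromosome) with any catalogue variant of
    cell type X.
    """
    out = []
    for members in clumps:
        cl = Clump(members=list(members))
        for v in members:
            for t in assignments.loc[assignments["variant"] == v, "trait"]:
                if t not in trait_cell_type:
                    raise ValueError(f"trait {t!r} missing from the cell-type map")
                cl.traits.add(t)
                cl.cell_types.add(trait_cell_type[t])
        for ct in sorted(cl.cell_types):
            known = False
            for _, row in catalogue.loc[catalogue["cell_type"] == ct].iterrows():
                cvec = catalogue_dosages.get(row["id"])
                if cvec is None:
                    continue
                for v in members:
                    if (
                        variant_chrom is not None
                        and "chrom" in row
                        and str(variant_chrom.get(v)) != str(row["chrom"])
                    ):
                        continue  # cross-chromosome r^2 is defined as 0
                    try:
                        if ld_r2(clump_dosages[v], cvec) > r2_threshold:
                            known = True
                            break
                    except ValueError:
                        continue
                if known:
                    break
            cl.novelty[ct] = not known
        out.append(cl)
    return out
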