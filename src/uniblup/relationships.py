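"""Pedigree, genomic, and combined single-step relationship matrices.

Implements the numerator relationship matrix A by the tabular-method
recursion (with inbreeding), the VanRaden genomic relationship G = WW'/N,
and the combined single-step matrix H in both its direct block form

    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21,   H12 = A12 A22^-1 G,
    H22 = G,

and the shortcut inverse

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]],

where block 2 indexes the genotyped animals.  G built from fewer markers than
animals is rank-deficient, so G is blended with a small weight on A22 before
any inversion (standard single-step practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .genotypes import ScaledGenotypes
from .pedigree import UNKNOWN, Pedigree

Kind = Literal["A", "A_inverse", "A22", "G", "H", "H_inverse"]

__all__ = [
    "RelationshipStructure",
    "build_numerator_relationship",
    "build_genomic_relationship",
    "blend_genomic",
    "build_H_direct",
    "build_H_inverse",
    "invert",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class RelationshipStructure:
    """A labelled symmetric matrix (or its inverse) over an ordered id index."""

    ids: list[str]
    values: np.ndarray
    kind: Kind
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relationship structure")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with {n} ids"
            )
        if n:
            asym = np.abs(self.values - self.values.T).max()
            if asym > _SYMMETRY_TOL * max(1.0, np.abs(self.values).max()):
                raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3g})")
        # exact symmetry downstream
        self.values = 0.5 * (self.values + self.values.T)
        if not self.kind.endswith("inverse") and n:
            if np.diag(self.values).min() < 0:
                raise ValueError("negative diagonal in relationship matrix")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, ids) -> "RelationshipStructure":
        """Extract the block over ``ids`` (not valid for inverse kinds)."""
        if self.kind.endswith("inverse"):
            raise ValueError("submatrix of an inverse is not the inverse of a submatrix")
        rows = np.array([self._index[a] for a in ids])
        return RelationshipStructure(
            list(ids), self.values[np.ix_(rows, rows)], self.kind
        )

    def indices_of(self, ids) -> np.ndarray:
        return np.array([self._index[a] for a in ids], dtype=np.int64)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, index_label="animal"
        )

    def to_triplets(self, path, tol: float = 0.0) -> None:
        """Lower-triangle coordinate triplets ``id_i,id_j,value`` (text)."""
        with open(path, "w") as fh:
            fh.write("row,col,value\n")
            for i in range(len(self.ids)):
                for j in range(i + 1):
                    v = float(self.values[i, j])
                    if abs(v) > tol:
                        fh.write(f"{self.ids[i]},{self.ids[j]},{v!r}\n")


def build_numerator_relationship(pedigree: Pedigree) -> RelationshipStructure:
    """Numerator relationship matrix A by the tabular method.

    a_ii = 1 + F_i where F_i is the inbreeding coefficient (half the
    relationship between the parents); unknown parents contribute zero
    relationship.  Requires a topologically ordered pedigree, which the
    :class:`Pedigree` constructor enforces.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0)
    return RelationshipStructure(list(pedigree.ids), A, "A")


def build_genomic_relationship(scaled: ScaledGenotypes) -> RelationshipStructure:
    """VanRaden genomic relationship G = WW'/N over the genotyped animals."""
    if scaled.n_snps < 1:
        raise ValueError("need at least one SNP to build G")
    W = scaled.values
    G = W @ W.T / scaled.n_snps
    return RelationshipStructure(list(scaled.animal_ids), G, "G")


def blend_genomic(
    G: RelationshipStructure, A22: RelationshipStructure, weight: float = 0.99
) -> RelationshipStructure:
    """Blend G with the pedigree block: weight*G + (1-weight)*A22.

    Restores full rank when the marker count is below the number of genotyped
    animals, so that G can be inverted for the single-step shortcut.
    """
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must be indexed identically for blending")
    return RelationshipStructure(
        list(G.ids), weight * G.values + (1.0 - weight) * A22.values, "G"
    )


def invert(rel: RelationshipStructure) -> RelationshipStructure:
    """Dense inverse, with the kind relabelled accordingly."""
    kind_map = {"A": "A_inverse", "G": "G", "A22": "A22", "H": "H_inverse"}
    try:
        values = np.linalg.inv(rel.values)
    except np.linalg.LinAlgError as exc:
        if rel.kind == "G":
            raise np.linalg.LinAlgError(
                "G is singular; blend it with A22 (blend_genomic) before inversion"
            ) from exc
        raise
    new_kind = kind_map.get(rel.kind, rel.kind)
    values = 0.5 * (values + values.T)
    return RelationshipStructure(list(rel.ids), values, new_kind)  # type: ignore[arg-type]


def _split_ids(A: RelationshipStructure, genotyped_ids) -> tuple[list, list]:
    missing = [g for g in genotyped_ids if g not in A._index]
    if missing:
        raise ValueError(f"genotyped ids absent from A: {missing}")
    gen = set(genotyped_ids)
    non = [a for a in A.ids if a not in gen]
    return non, list(genotyped_ids)


def build_H_direct(
    A: RelationshipStructure, G: RelationshipStructure, genotyped_ids
) -> RelationshipStructure:
    """Combined relationship matrix H over all ids, genotyped block = G.

    ``G`` must be indexed exactly by ``genotyped_ids``; pass a blended G if it
    is to be consistent with :func:`build_H_inverse`.
    """
    if list(G.ids) != list(genotyped_ids):
        raise ValueError("G must be indexed exactly by genotyped_ids")
    non, gen = _split_ids(A, genotyped_ids)
    if not gen:
        return RelationshipStructure(list(A.ids), A.values.copy(), "H")
    i_non = A.indices_of(non)
    i_gen = A.indices_of(gen)
    A11 = A.values[np.ix_(i_non, i_non)]
    A12 = A.values[np.ix_(i_non, i_gen)]
    A22 = A.values[np.ix_(i_gen, i_gen)]
    A22_inv = np.linalg.inv(A22)
    Gv = G.values
    P = A12 @ A22_inv  # maps genotyped to non-genotyped via pedigree
    H = np.empty_like(A.values)
    # assemble in the original id order
    idx = np.concatenate([i_non, i_gen])
    order = np.empty_like(idx)
    order[idx] = np.arange(len(idx))
    H11 = A11 + P @ (Gv - A22) @ P.T
    H12 = P @ Gv
    block = np.block([[H11, H12], [H12.T, Gv]])
    H = block[np.ix_(order, order)]
    return RelationshipStructure(list(A.ids), H, "H")


def build_H_inverse(
    A_inverse: RelationshipStructure,
    G_inverse: RelationshipStructure,
    A22_inverse: RelationshipStructure,
    genotyped_ids,
) -> RelationshipStructure:
    """Single-step shortcut: H^-1 = A^-1 + scatter(G^-1 - A22^-1).

    The correction lands on the genotyped block; with no genotyped animals
    H^-1 = A^-1.
    """
    gen = list(genotyped_ids)
    if list(G_inverse.ids) != gen or list(A22_inverse.ids) != gen:
        raise ValueError("G^-1 and A22^-1 must be indexed exactly by genotyped_ids")
    H_inv = A_inverse.values.copy()
    if gen:
        i_gen = A_inverse.indices_of(gen)
        H_inv[np.ix_(i_gen, i_gen)] += G_inverse.values - A22_inverse.values
    return RelationshipStructure(list(A_inverse.ids), H_inv, "H_inverse")


def single_step_pair(
    pedigree: Pedigree,
    scaled: ScaledGenotypes,
    blend_weight: float = 0.99,
) -> tuple[RelationshipStructure, RelationshipStructure]:
    """Convenience: (H, H_inverse) from a pedigree and scaled genotypes.

    Uses the blended G in both routes so they are mutually consistent.
    """
    A = build_numerator_relationship(pedigree)
    gen = list(scaled.animal_ids)
    G0 = build_genomic_relationship(scaled)
    A22 = A.submatrix(gen)
    A22.kind = "A22"
    Gb = blend_genomic(G0, A22, weight=blend_weight)
    H = build_H_direct(A, Gb, gen)
    H_inv = build_H_inverse(
        invert(A),
        invert(Gb),
        RelationshipStructure(gen, np.linalg.inv(A22.values), "A22"),
        gen,
    )
    return H, H_inv
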