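"""Load design matrices: T (partial coefficients), P (parent pointers), K = T(I-P).

The inbreeding load of an ancestor is an additive genetic effect expressed
in the phenotypes of its inbred descendants.  The row of ``K`` for a
phenotyped animal weights the Mendelian-sampling deviations of the load
effects of the ancestors that generated its inbreeding:  ``T`` holds the
partial inbreeding coefficients F_j(k), ``P`` points each animal to its
parents with entries 0.5, and the product ``T(I-P)`` converts ancestor load
*levels* into the corresponding Mendelian-sampling contributions, keeping
the covariance structure of the loads equal to that of ordinary breeding
values (G x A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, PartialInbreeding

DEFAULT_K_THRESHOLD = 0.01


def build_parent_matrix(ped: Pedigree) -> sp.csr_matrix:
    """Sparse P with one 0.5 entry per known parent slot; zero diagonal."""
    rows, cols = [], []
    for j in range(ped.n):
        for p in (ped.sire[j], ped.dam[j]):
            if p >= 0:
                rows.append(j)
                cols.append(p)
    data = np.full(len(rows), 0.5)
    return sp.csr_matrix((data, (rows, cols)), shape=(ped.n, ped.n))


def build_T(partials: PartialInbreeding) -> sp.csr_matrix:
    n = partials.ped.n
    return sp.csr_matrix(
        (partials.value, (partials.descendant, partials.ancestor)), shape=(n, n)
    )


@dataclass
class LoadDesign:
    """T, P and thresholded K = T(I-P) for one pedigree."""

    T: sp.csr_matrix
    P: sp.csr_matrix
    K: sp.csr_matrix
    threshold: float
    n: int

    def k_frame(self, ped: Pedigree) -> pd.DataFrame:
        coo = self.K.tocoo()
        return pd.DataFrame(
            {
                "descendant": ped.ids[coo.row],
                "ancestor": ped.ids[coo.col],
                "value": coo.data,
            }
        )

    def write_K(self, ped: Pedigree, path, delimiter: str = " ") -> None:
        df = self.k_frame(ped)
        with open(path, "w") as fh:
            fh.write(delimiter.join(["descendant", "ancestor", "value"]) + "\n")
            for r in df.itertuples(index=False):
                fh.write(
                    f"{r.descendant}{delimiter}{r.ancestor}{delimiter}{r.value:.17g}\n"
                )


def build_K(
    partials: PartialInbreeding,
    P: sp.spmatrix | None = None,
    threshold: float = DEFAULT_K_THRESHOLD,
) -> LoadDesign:
    """Assemble K = T(I-P), dropping entries with |K| <= threshold.

    ``T`` is retained unthresholded for diagnostics.  The product is exact
    before thresholding; with all inbreeding-generating ancestors being
    founders (empty P columns for them) K equals T.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ped = partials.ped
    if P is None:
        P = build_parent_matrix(ped)
    if P.shape != (ped.n, ped.n):
        raise ValueError(
            f"parent matrix shape {P.shape} does not match pedigree size {ped.n}"
        )
    T = build_T(partials)
    K = (T @ (sp.identity(ped.n, format="csr") - P.tocsr())).tocsr()
    K.eliminate_zeros()
    if threshold > 0:
        K.data[np.abs(K.data) <= threshold] = 0.0
        K.eliminate_zeros()
    # ordering guard: strictly lower triangular under pedigree order
    coo = K.tocoo()
    if np.any(coo.col >= coo.row):
        raise AssertionError("K is not strictly lower triangular; ordering bug")
    return LoadDesign(T=T, P=P.tocsr(), K=K, threshold=threshold, n=ped.n)
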