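"""Pedigree handling and Mendelian decomposition of inbreeding.

The inbreeding coefficient ``F_j`` of an animal is half the additive
relationship of its parents.  It can be decomposed into *partial inbreeding
coefficients* ``F_j(k)``, one per ancestor ``k``, such that
``sum_k F_j(k) = F_j``.  Each partial coefficient measures the part of the
descendant's autozygosity created by the Mendelian sampling of ancestor
``k`` (every animal, founder or not, is treated as a partial founder whose
sampling term contributes to population variability).

The decomposition is obtained by running the tabular relationship recursion

    A(j, m) = 1/2 (A(s_j, m) + A(d_j, m)),      m earlier than j
    A(j, j) = 1/2 (A(j, s_j) + A(j, d_j)) + phi_jj

with the diagonal Mendelian-sampling matrix ``phi`` zeroed everywhere except
at the single entry ``phi_kk`` of the ancestor of interest; the resulting
partial relationship matrix ``A^(k)`` yields ``F_j(k) = 1/2 A^(k)(s_j, d_j)``.
Summing the partial matrices over all ``k`` reconstructs the ordinary
relationship matrix, hence the closure property of the decomposition.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pedload")

UNKNOWN = 0
_NOPAR = -1  # internal index code for an unknown parent


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Parameters
    ----------
    ids : ndarray of int
        Original animal identifiers, in an order where parents precede
        offspring.
    sire, dam : ndarray of int
        Positional indices of each animal's parents within ``ids``;
        ``-1`` encodes an unknown parent.
    birth_year : ndarray of int, optional
        Birth years when supplied in the input file.
    sex : ndarray of str, optional
        Sex codes when supplied in the input file.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray | None = None
    sex: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not self._index:
            self._index = {int(a): i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")
        # parents must precede offspring
        idx = np.arange(len(self.ids))
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= idx[known]):
                bad = self.ids[known][par[known] >= idx[known]][0]
                raise ValueError(
                    f"pedigree not topologically ordered near animal {bad}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: int) -> int:
        return self._index[int(animal_id)]

    def is_founder(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    def series(self, values: np.ndarray, name: str | None = None) -> pd.Series:
        """Wrap an order-aligned array as a Series indexed by animal id."""
        return pd.Series(np.asarray(values), index=self.ids, name=name)

    def aligned(self, values) -> np.ndarray:
        """Return ``values`` (Series or array) as an order-aligned ndarray."""
        if isinstance(values, pd.Series):
            return values.reindex(self.ids).to_numpy()
        arr = np.asarray(values)
        if arr.shape[0] != self.n:
            raise ValueError("length mismatch with pedigree")
        return arr

    # -- ancestor machinery -------------------------------------------------

    def ancestor_bitsets(self, inclusive: bool = True) -> np.ndarray:
        """Per-animal ancestor sets packed as uint64 bit matrices.

        Row ``j`` has bit ``k`` set when ``k`` is an ancestor of ``j``
        (including ``j`` itself when ``inclusive``).
        """
        n = self.n
        words = (n + 63) // 64
        bits = np.zeros((n, words), dtype=np.uint64)
        for j in range(n):
            if inclusive:
                bits[j, j >> 6] |= np.uint64(1) << np.uint64(j & 63)
            for par in (self.sire[j], self.dam[j]):
                if par >= 0:
                    bits[j] |= bits[par]
                    if not inclusive:
                        bits[j, par >> 6] |= np.uint64(1) << np.uint64(par & 63)
        return bits

    @staticmethod
    def _bit_members(row: np.ndarray) -> np.ndarray:
        """Indices of set bits in one packed row."""
        out = []
        for w, word in enumerate(row):
            word = int(word)
            while word:
                low = word & -word
                out.append(64 * w + low.bit_length() - 1)
                word ^= low
        return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Reading and ordering
# ---------------------------------------------------------------------------

def _toposort(ids, sires, dams, years):
    """Stable topological sort: parents first, ties by (birth_year, input order)."""
    n = len(ids)
    pos = {a: i for i, a in enumerate(ids)}
    children: list[list[int]] = [[] for _ in range(n)]
    npar = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                npar[i] += 1

    def key(i):
        yr = years[i] if years is not None else 0
        return (yr, i)

    heap = [key(i) for i in range(n) if npar[i] == 0]
    heapq.heapify(heap)
    order = []
    remaining = npar.copy()
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            remaining[c] -= 1
            if remaining[c] == 0:
                heapq.heappush(heap, key(c))
    if len(order) < n:
        stuck = [ids[i] for i in range(n) if remaining[i] > 0]
        raise ValueError(f"pedigree cycle detected involving animal {stuck[0]}")
    return order


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a :class:`Pedigree` from a data frame.

    Expected columns in order: animal, sire, dam, then optionally birth year
    and sex.  Unknown parents are coded 0.  Rows may appear in any order;
    a stable topological sort is applied.  Parents that never appear as an
    animal are inserted as founders with a warning.
    """
    df = df.copy()
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError("pedigree needs at least 3 columns (animal sire dam)")
    animals = df.iloc[:, 0].astype(np.int64).to_numpy()
    sires = df.iloc[:, 1].astype(np.int64).to_numpy()
    dams = df.iloc[:, 2].astype(np.int64).to_numpy()
    years = df.iloc[:, 3].astype(np.int64).to_numpy() if ncol >= 4 else None
    sex = df.iloc[:, 4].astype(str).to_numpy() if ncol >= 5 else None

    if np.any(animals <= 0):
        raise ValueError("animal ids must be positive integers")
    seen = set()
    for a in animals:
        if a in seen:
            raise ValueError(f"duplicate animal id {a}")
        seen.add(a)

    # undefined parents become founders
    missing = sorted(
        {int(p) for p in np.concatenate([sires, dams]) if p != UNKNOWN} - seen
    )
    if missing:
        logger.warning(
            "%d parent id(s) never defined as animals; inserted as founders: %s",
            len(missing), missing[:10],
        )
        animals = np.concatenate([animals, missing])
        sires = np.concatenate([sires, np.zeros(len(missing), dtype=np.int64)])
        dams = np.concatenate([dams, np.zeros(len(missing), dtype=np.int64)])
        if years is not None:
            years = np.concatenate([years, np.zeros(len(missing), dtype=np.int64)])
        if sex is not None:
            sex = np.concatenate([sex, np.array(["?"] * len(missing))])

    if np.any(animals[sires != UNKNOWN] == sires[sires != UNKNOWN]) or np.any(
        animals[dams != UNKNOWN] == dams[dams != UNKNOWN]
    ):
        raise ValueError("animal listed as its own parent (cycle)")
    selfed = sires[(sires != UNKNOWN) & (sires == dams)]
    if selfed.size:
        logger.warning("sire equals dam for %d matings (selfing accepted)", selfed.size)

    if sex is not None:
        sexmap = dict(zip(animals, sex))
        as_sire = {int(s) for s in sires if s != UNKNOWN}
        as_dam = {int(d) for d in dams if d != UNKNOWN}
        both = as_sire & as_dam
        conflicts = [a for a in both if a in sexmap]
        conflicts = [a for a in conflicts if sexmap[a] not in ("?",)]
        if conflicts:
            raise ValueError(
                f"animal(s) appear as both sire and dam with sex codes given: "
                f"{sorted(conflicts)[:5]}"
            )

    order = _toposort(list(animals), list(sires), list(dams), years)
    animals = animals[order]
    pos = {int(a): i for i, a in enumerate(animals)}
    sire_idx = np.array(
        [pos[int(s)] if s != UNKNOWN else _NOPAR for s in sires[order]], dtype=np.int64
    )
    dam_idx = np.array(
        [pos[int(d)] if d != UNKNOWN else _NOPAR for d in dams[order]], dtype=np.int64
    )
    return Pedigree(
        ids=animals,
        sire=sire_idx,
        dam=dam_idx,
        birth_year=years[order] if years is not None else None,
        sex=sex[order] if sex is not None else None,
    )


def read_pedigree(path, delimiter: str | None = None) -> Pedigree:
    """Read a pedigree file (columns: animal sire dam [year] [sex]).

    Whitespace- or comma-delimited; 0 codes an unknown parent; a header
    line is auto-detected from a non-numeric first field.
    """
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = "," if "," in first else None  # None -> any whitespace
    tok = first.strip().split(delimiter)[0] if first.strip() else ""
    header = 0 if not tok.lstrip("-").isdigit() else None
    df = pd.read_csv(
        path,
        sep=delimiter if delimiter is not None else r"\s+",
        header=header,
        comment="#",
    )
    return pedigree_from_frame(df)


def pedigree_from_arrays(
    animal: Sequence[int],
    sire: Sequence[int],
    dam: Sequence[int],
    year: Sequence[int] | None = None,
    sex: Sequence[str] | None = None,
) -> Pedigree:
    """Convenience constructor from id-level parallel arrays (0 = unknown)."""
    cols = {"animal": animal, "sire": sire, "dam": dam}
    if year is not None:
        cols["year"] = year
    elif sex is not None:
        cols["year"] = [0] * len(list(animal))
    if sex is not None:
        cols["sex"] = sex
    return pedigree_from_frame(pd.DataFrame(cols))


def write_pedigree(ped: Pedigree, path, delimiter: str = " ") -> None:
    cols = {
        "animal": ped.ids,
        "sire": np.where(ped.sire >= 0, ped.ids[np.maximum(ped.sire, 0)], 0),
        "dam": np.where(ped.dam >= 0, ped.ids[np.maximum(ped.dam, 0)], 0),
    }
    if ped.birth_year is not None:
        cols["year"] = ped.birth_year
    if ped.sex is not None:
        cols["sex"] = ped.sex
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Inbreeding coefficients
# ---------------------------------------------------------------------------

def mendelian_sampling_variance_from_parents(
    f_sire: float | None, f_dam: float | None
) -> float:
    """Mendelian-sampling variance phi_jj given parental inbreeding.

    ``1/4 (1-F_s) + 1/4 (1-F_d)`` with both parents known,
    ``1/2 + 1/4 (1-F_l)`` with one known parent ``l``, and 1 with none.
    """
    if f_sire is None and f_dam is None:
        return 1.0
    if f_sire is None:
        return 0.5 + 0.25 * (1.0 - f_dam)
    if f_dam is None:
        return 0.5 + 0.25 * (1.0 - f_sire)
    return 0.25 * (1.0 - f_sire) + 0.25 * (1.0 - f_dam)


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    phi = np.empty(ped.n)
    for j in range(ped.n):
        s, d = ped.sire[j], ped.dam[j]
        phi[j] = mendelian_sampling_variance_from_parents(
            F[s] if s >= 0 else None, F[d] if d >= 0 else None
        )
    return phi


def mendelian_variance(ped: Pedigree, F) -> pd.Series:
    """Per-animal Mendelian-sampling variance phi_jj (Series by animal id)."""
    Farr = ped.aligned(F)
    return ped.series(_mendelian_variances(ped, Farr), name="phi")


def kinship_matrix(ped: Pedigree, max_n: int = 3000) -> np.ndarray:
    """Dense additive (numerator) relationship matrix A by the tabular method.

    Guarded by ``max_n`` since storage is O(n^2); intended for moderate
    pedigrees and as an oracle for the recursive algorithms.
    """
    n = ped.n
    if n > max_n:
        raise ValueError(f"dense A refused for n={n} > {max_n}")
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[s, :j]
        if d >= 0:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        diag = 1.0
        if s >= 0 and d >= 0:
            diag += 0.5 * A[s, d]
        A[j, j] = diag
    return A


def _inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding by the ancestor-tracing recursion.

    For each animal the row of the Cholesky factor L of A is accumulated
    over touched ancestors only; ``1 + F_j = sum_k L_jk^2 m_k`` with ``m_k``
    the Mendelian-sampling variance of ``k``.
    """
    n = ped.n
    F = np.zeros(n)
    m = np.empty(n)  # Mendelian variance, filled as F of parents is known
    sire, dam = ped.sire, ped.dam
    for j in range(n):
        s, d = sire[j], dam[j]
        m[j] = mendelian_sampling_variance_from_parents(
            F[s] if s >= 0 else None, F[d] if d >= 0 else None
        )
        if s < 0 or d < 0:
            F[j] = 0.0
            continue
        coef: dict[int, float] = {j: 1.0}
        heap = [-j]
        acc = 0.0
        while heap:
            k = -heapq.heappop(heap)
            c = coef.pop(k, 0.0)
            if c == 0.0:
                continue
            acc += c * c * m[k]
            for p in (sire[k], dam[k]):
                if p >= 0:
                    if p not in coef:
                        heapq.heappush(heap, -p)
                        coef[p] = 0.0
                    coef[p] += 0.5 * c
        F[j] = acc - 1.0
    return F


def compute_inbreeding(ped: Pedigree, method: str = "auto") -> pd.Series:
    """Inbreeding coefficients for every animal.

    Parameters
    ----------
    ped : Pedigree
    method : {"auto", "tabular", "recursive"}
        ``tabular`` builds the dense relationship matrix (small pedigrees);
        ``recursive`` uses the per-animal ancestor-tracing algorithm.  Both
        give identical results; ``auto`` picks by pedigree size.
    """
    if method == "auto":
        method = "tabular" if ped.n <= 500 else "recursive"
    if method == "tabular":
        A = kinship_matrix(ped, max_n=max(ped.n, 3000))
        F = np.diag(A) - 1.0
    elif method == "recursive":
        F = _inbreeding_meuwissen_luo(ped)
    else:
        raise ValueError(f"unknown method {method!r}")
    F = np.where(np.abs(F) < 1e-15, 0.0, F)
    return ped.series(F, name="F")


# ---------------------------------------------------------------------------
# Partial inbreeding coefficients
# ---------------------------------------------------------------------------

@dataclass
class PartialInbreeding:
    """Sparse set of partial inbreeding coefficients F_j(k).

    ``descendant``/``ancestor`` hold positional pedigree indices; ``value``
    the strictly positive coefficients.  ``sum_k F_j(k) = F_j``.
    """

    ped: Pedigree
    descendant: np.ndarray
    ancestor: np.ndarray
    value: np.ndarray

    def __len__(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descendant": self.ped.ids[self.descendant],
                "ancestor": self.ped.ids[self.ancestor],
                "partial_f": self.value,
            }
        )

    def totals(self) -> np.ndarray:
        """Sum of partial coefficients per animal, aligned with pedigree order."""
        out = np.zeros(self.ped.n)
        np.add.at(out, self.descendant, self.value)
        return out

    def write(self, path, delimiter: str = " ") -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(delimiter.join(["descendant", "ancestor", "partial_f"]) + "\n")
            for r in df.itertuples(index=False):
                fh.write(
                    f"{r.descendant}{delimiter}{r.ancestor}{delimiter}"
                    f"{r.partial_f:.17g}\n"
                )

    @staticmethod
    def read(path, ped: Pedigree, delimiter: str | None = None) -> "PartialInbreeding":
        df = pd.read_csv(path, sep=delimiter or r"\s+")
        desc = np.array([ped.index_of(a) for a in df["descendant"]], dtype=np.int64)
        anc = np.array([ped.index_of(a) for a in df["ancestor"]], dtype=np.int64)
        return PartialInbreeding(ped, desc, anc, df["partial_f"].to_numpy())


def _candidate_ancestors(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Ancestors appearing on both parental sides of some inbred animal."""
    bits = ped.ancestor_bitsets(inclusive=True)
    words = bits.shape[1]
    mask = np.zeros(words, dtype=np.uint64)
    inbred = np.nonzero(F > 0)[0]
    for j in inbred:
        mask |= bits[ped.sire[j]] & bits[ped.dam[j]]
    return Pedigree._bit_members(mask)


def compute_partial_inbreeding(
    ped: Pedigree, phi=None, F=None, screen: bool = True
) -> PartialInbreeding:
    """Mendelian decomposition of inbreeding over ancestors.

    For each candidate ancestor ``k`` the tabular recursion is run with the
    Mendelian-sampling matrix zeroed except at ``phi_kk``, restricted to the
    sub-pedigree of ``k`` and its descendants (entries outside it are
    provably zero).  ``F_j(k) = 1/2 A^(k)(s_j, d_j)`` is emitted for every
    animal whose parents both descend from ``k``; only strictly positive
    values are stored.

    Parameters
    ----------
    ped : Pedigree
    phi : Series or ndarray, optional
        Mendelian-sampling variances; computed from ``F`` if omitted.
    F : Series or ndarray, optional
        Total inbreeding; computed if omitted.
    screen : bool
        Sweep only candidate ancestors present on both parental sides of
        some inbred animal (sound: others cannot contribute).
    """
    Farr = ped.aligned(F) if F is not None else compute_inbreeding(ped).to_numpy()
    phiarr = (
        ped.aligned(phi) if phi is not None else _mendelian_variances(ped, Farr)
    )
    n = ped.n
    desc_rows: list[np.ndarray] = []
    anc_rows: list[np.ndarray] = []
    val_rows: list[np.ndarray] = []

    if screen:
        candidates = _candidate_ancestors(ped, Farr)
    else:
        candidates = np.arange(n)

    bits = ped.ancestor_bitsets(inclusive=True)
    for k in candidates:
        # members of the sub-pedigree: k and its descendants
        word, bit = k >> 6, np.uint64(1) << np.uint64(k & 63)
        members = np.nonzero((bits[:, word] & bit) != 0)[0]
        if members.size == 1 and Farr[k] == 0 and screen:
            # k has no descendants; as a candidate it must appear through
            # screening only when it does, so this is defensive
            continue
        pos = {int(g): i for i, g in enumerate(members)}
        m = members.size
        Ak = np.zeros((m, m))
        for li, j in enumerate(members):
            s, d = ped.sire[j], ped.dam[j]
            ls = pos.get(int(s), -1) if s >= 0 else -1
            ld = pos.get(int(d), -1) if d >= 0 else -1
            if li > 0:
                row = np.zeros(li)
                if ls >= 0:
                    row += 0.5 * Ak[ls, :li]
                if ld >= 0:
                    row += 0.5 * Ak[ld, :li]
                Ak[li, :li] = row
                Ak[:li, li] = row
            # diagonal: parent-average of the just-computed row entries
            # (plus the single Mendelian-sampling term when j is k itself)
            diag = 0.0
            if ls >= 0:
                diag += 0.5 * Ak[li, ls]
            if ld >= 0:
                diag += 0.5 * Ak[li, ld]
            if j == k:
                diag = phiarr[k]  # k's parents lie outside the sub-pedigree
            Ak[li, li] = diag
        # partial coefficients for members whose two parents are members
        vals = []
        rows = []
        for li, j in enumerate(members):
            if j == k:
                continue
            s, d = ped.sire[j], ped.dam[j]
            if s < 0 or d < 0:
                continue
            ls, ld = pos.get(int(s), -1), pos.get(int(d), -1)
            if ls < 0 or ld < 0:
                continue
            fjk = 0.5 * Ak[ls, ld]
            if fjk > 0.0:
                rows.append(j)
                vals.append(fjk)
        if rows:
            desc_rows.append(np.asarray(rows, dtype=np.int64))
            anc_rows.append(np.full(len(rows), k, dtype=np.int64))
            val_rows.append(np.asarray(vals))

    if desc_rows:
        descendant = np.concatenate(desc_rows)
        ancestor = np.concatenate(anc_rows)
        value = np.concatenate(val_rows)
        order = np.lexsort((ancestor, descendant))
        descendant, ancestor, value = descendant[order], ancestor[order], value[order]
    else:
        descendant = np.empty(0, dtype=np.int64)
        ancestor = np.empty(0, dtype=np.int64)
        value = np.empty(0)
    return PartialInbreeding(ped, descendant, ancestor, value)


# ---------------------------------------------------------------------------
# Pedigree completeness and summaries
# ---------------------------------------------------------------------------

def equivalent_complete_generations(ped: Pedigree) -> pd.Series:
    """Equivalent complete generations per animal.

    Sum over all known-ancestor paths of (1/2)^g, each ancestor counted once
    per path; founders score 0.  Recursion:
    ``ecg_j = sum_{known parents} 1/2 (1 + ecg_parent)``.
    """
    ecg = np.zeros(ped.n)
    for j in range(ped.n):
        acc = 0.0
        for p in (ped.sire[j], ped.dam[j]):
            if p >= 0:
                acc += 0.5 * (1.0 + ecg[p])
        ecg[j] = acc
    return ped.series(ecg, name="ecg")


def summarize_inbreeding(F, partials: PartialInbreeding) -> tuple[dict, pd.DataFrame]:
    """Descriptive statistics for inbreeding and its decomposition.

    Returns a key-value summary (percent inbred, F distribution, counts and
    moments of the partial coefficients, ancestors involved) and a
    per-ancestor table with the number of descendants each ancestor inbreeds.
    """
    ped = partials.ped
    Farr = ped.aligned(F)
    n = ped.n
    inbred = Farr > 0
    n_inbred = int(inbred.sum())
    founder_mask = ped.is_founder()

    anc_unique, anc_counts = np.unique(partials.ancestor, return_counts=True)
    summary = {
        "n_animals": n,
        "pct_inbred": 100.0 * n_inbred / n if n else 0.0,
        "pct_inbred_F_below_0.05": (
            100.0 * float((Farr[inbred] < 0.05).mean()) if n_inbred else 0.0
        ),
        "pct_inbred_F_above_0.1": (
            100.0 * float((Farr[inbred] > 0.1).mean()) if n_inbred else 0.0
        ),
        "mean_F_inbred": float(Farr[inbred].mean()) if n_inbred else 0.0,
        "mean_F_overall": float(Farr.mean()) if n else 0.0,
        "n_partial_coefficients": len(partials),
        "mean_partial_f": float(partials.value.mean()) if len(partials) else 0.0,
        "sd_partial_f": (
            float(partials.value.std(ddof=1)) if len(partials) > 1 else 0.0
        ),
        "max_partial_f": float(partials.value.max()) if len(partials) else 0.0,
        "n_ancestors_involved": int(anc_unique.size),
        "n_founder_ancestors_involved": int(founder_mask[anc_unique].sum()),
    }
    per_ancestor = pd.DataFrame(
        {
            "ancestor": ped.ids[anc_unique],
            "n_descendants_inbred": anc_counts,
            "is_founder": founder_mask[anc_unique],
        }
    )
    return summary, per_ancestor
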