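"""Jukes-Cantor pairwise distance matrices and per-group summary distances.

The observed proportion of differing sites *p* is computed under pairwise
deletion: a column contributes to a pair only when both rows carry an
unambiguous base (A, C, G or T); gaps and IUPAC ambiguity codes are excluded
for that pair. The Jukes-Cantor correction

    d = -(3/4) * ln(1 - 4p/3)

turns *p* into an expected number of substitutions per site under the
one-parameter model. A pair at or beyond the model's domain bound
(p >= 3/4) has no finite distance; such pairs raise
:class:`~protistdiv.errors.SaturationError` rather than being silently
clamped, which would corrupt maximum-distance statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from protistdiv.errors import InputError, SaturationError, UndefinedDistanceError
from protistdiv.seq_regions import GroupAlignment

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "jukes_cantor",
    "distance_matrix",
    "summarize_distances",
    "SaturationError",
    "UndefinedDistanceError",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of Jukes-Cantor distances.

    ``d`` holds substitutions/site (``nan`` marks an undefined pair when the
    matrix was built with ``on_undefined="nan"``); ``comparable_sites`` the
    per-pair count of columns used.
    """

    names: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.d.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise InputError("distance matrix shape does not match name count")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.d)
        if np.any(self.d[finite] < 0):
            raise InputError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.names)

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.names.index(a), self.names.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle pair values in row-major (i<j) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]


def _encode(row: str) -> np.ndarray:
    """Map a row to integer codes; anything outside A/C/G/T (gaps,
    ambiguities) becomes -1 and is excluded by pairwise deletion."""
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Observed proportion of differing sites and the number of sites used.

    Columns where either row has a gap or ambiguity code are excluded
    (pairwise deletion). Raises :class:`UndefinedDistanceError` when no
    comparable site remains.
    """
    if len(a) != len(b):
        raise InputError(f"rows have unequal lengths {len(a)} and {len(b)}")
    ca, cb = _encode(a.upper()), _encode(b.upper())
    both = (ca >= 0) & (cb >= 0)
    sites = int(both.sum())
    if sites == 0:
        raise UndefinedDistanceError("no comparable (ungapped, unambiguous) sites")
    mismatches = int((ca[both] != cb[both]).sum())
    return mismatches / sites, sites


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 0.75; raises :class:`SaturationError` at or beyond
    the bound.
    """
    if p < 0:
        raise InputError(f"proportion p={p} negative")
    if p >= 0.75:
        raise SaturationError(
            f"p={p:.4f} >= 0.75: Jukes-Cantor distance undefined (saturated)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def distance_matrix(
    aln: GroupAlignment, on_undefined: str = "error"
) -> DistanceMatrix:
    """All-pairs Jukes-Cantor distances for one group alignment.

    ``on_undefined`` controls pairs with no comparable sites or saturated
    divergence: ``"error"`` (default) raises naming the offending pair;
    ``"nan"`` records ``nan`` so callers can drop the pair explicitly.
    """
    if on_undefined not in ("error", "nan"):
        raise InputError(f"on_undefined must be 'error' or 'nan', got {on_undefined!r}")
    n = aln.n_seq
    if n < 2:
        raise InputError(f"group {aln.group_id!r}: need >= 2 sequences, got {n}")
    codes = np.stack([_encode(r) for r in aln.rows])
    valid = codes >= 0
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, aln.length)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        s = both.sum(axis=1)
        diff = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s > 0, diff / np.maximum(s, 1), np.nan)
        arg = 1.0 - 4.0 * p / 3.0
        row_d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        if on_undefined == "error" and np.any(~np.isfinite(row_d)):
            j = i + 1 + int(np.flatnonzero(~np.isfinite(row_d))[0])
            if (valid[i] & valid[j]).sum() == 0:
                raise UndefinedDistanceError(
                    f"pair ({aln.names[i]!r}, {aln.names[j]!r}): no comparable sites"
                )
            raise SaturationError(
                f"pair ({aln.names[i]!r}, {aln.names[j]!r}): saturated (p >= 0.75)"
            )
        d[i, i + 1 :] = row_d
        d[i + 1 :, i] = row_d
        sites[i, i + 1 :] = s
        sites[i + 1 :, i] = s
    return DistanceMatrix(names=list(aln.names), d=d, comparable_sites=sites)


def summarize_distances(m: DistanceMatrix) -> tuple[float, float]:
    """Average and maximum over the n(n-1)/2 unordered pair distances.

    The average distance describes the typical divergence between two
    sequences of a group; the maximum is the group's most extreme pair.
    """
    if m.n < 2:
        raise InputError("need >= 2 names to summarize distances")
    vals = m.condensed()
    if np.any(~np.isfinite(vals)):
        raise UndefinedDistanceError("matrix contains undefined pairs")
    return float(vals.mean()), float(vals.max())


def write_matrix_tsv(m: DistanceMatrix, path) -> None:
    """Square matrix TSV with names in the header row and first column."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(m.names) + "\n")
        for i, name in enumerate(m.names):
            fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in m.d[i]) + "\n")


def write_pair_list(m: DistanceMatrix, path) -> None:
    """Three-column pair list: name1, name2, distance (i < j order)."""
    with open(path, "w") as fh:
        for i in range(m.n):
            for j in range(i + 1, m.n):
                fh.write(f"{m.names[i]}\t{m.names[j]}\t{m.d[i, j]:.6f}\n")
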