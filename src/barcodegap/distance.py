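"""Kimura 2-parameter pairwise divergences with pairwise deletion.

The K2P model corrects the raw proportions of transitional (P) and
transversional (Q) differences separately:

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries a gap or any non-ACGT ambiguity code are
excluded per pair (pairwise deletion), so heterogeneous-coverage datasets do
not lose sites globally.  Distances that fall outside the log domain
(saturation) or rest on too few compared sites are reported as sentinels, not
numbers, and are excluded from all downstream flagging.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_OVERLAP = 100


class Undefined(enum.Enum):
    """Sentinels for pairs without a defined K2P distance."""

    SATURATED = "UNDEFINED_SATURATED"
    NO_OVERLAP = "UNDEFINED_NO_OVERLAP"


UNDEFINED_SATURATED = Undefined.SATURATED
UNDEFINED_NO_OVERLAP = Undefined.NO_OVERLAP

# integer codes used in DistanceMatrix.codes
CODE_OK = 0
CODE_SATURATED = 1
CODE_NO_OVERLAP = 2

# A/G are purines, C/T pyrimidines; with this encoding two symbols are a
# transition iff they differ but share the high bit.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"AGCT"):
    _ENCODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode bases as uint8: A=0 G=1 C=2 T=3, anything else 4 (excluded)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion difference proportions over compared sites."""

    P: float
    Q: float
    n_sites: int


def count_pq(a: str, b: str) -> PairCounts:
    """Count transition/transversion proportions between two aligned rows.

    Gap and ambiguity columns are pairwise-deleted.  When no sites remain the
    proportions are reported as NaN with ``n_sites = 0``.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ea, eb = encode(a), encode(b)
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        return PairCounts(math.nan, math.nan, 0)
    diff = valid & (ea != eb)
    ts = diff & ((ea >> 1) == (eb >> 1))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairCounts(n_ts / n, n_tv / n, n)


def k2p(counts: PairCounts, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float | Undefined:
    """K2P distance (substitutions/site) from pair counts, or a sentinel.

    Returns ``UNDEFINED_NO_OVERLAP`` when fewer than ``min_overlap`` sites were
    compared and ``UNDEFINED_SATURATED`` when the log arguments are
    non-positive (the estimator diverges at high divergence).
    """
    if counts.n_sites < min_overlap:
        return Undefined.NO_OVERLAP
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return Undefined.SATURATED
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


class DistanceMatrix:
    """Symmetric K2P matrix with per-pair overlap counts and sentinel codes.

    Attributes
    ----------
    labels : list of accessions (row order)
    species : list of binomials, parallel to labels
    d : (n, n) float array; NaN where a sentinel applies; 0 on the diagonal
    n : (n, n) int array of compared-site counts
    codes : (n, n) uint8 array (0 ok, 1 saturated, 2 insufficient overlap)
    """

    def __init__(self, labels, species, d, n, codes):
        self.labels = list(labels)
        self.species = list(species)
        self.d = np.asarray(d, dtype=float)
        self.n = np.asarray(n, dtype=np.int64)
        self.codes = np.asarray(codes, dtype=np.uint8)
        if len(self.labels) != len(self.species):
            raise ValueError("labels/species length mismatch")
        if self.d.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape does not match labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> float | Undefined:
        """Distance between two accessions, as a float or a sentinel."""
        i, j = self._index[a], self._index[b]
        code = self.codes[i, j]
        if code == CODE_SATURATED:
            return Undefined.SATURATED
        if code == CODE_NO_OVERLAP:
            return Undefined.NO_OVERLAP
        return float(self.d[i, j])

    def is_defined(self, i: int, j: int) -> bool:
        return self.codes[i, j] == CODE_OK

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self._index[lab] for lab in labels])
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            [self.species[i] for i in idx],
            self.d[np.ix_(idx, idx)],
            self.n[np.ix_(idx, idx)],
            self.codes[np.ix_(idx, idx)],
        )

    # -- export ------------------------------------------------------------
    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format: one row per unordered pair with distance and class."""
        rows = []
        nseq = len(self)
        for i in range(nseq):
            for j in range(i + 1, nseq):
                code = self.codes[i, j]
                rows.append(
                    {
                        "acc_i": self.labels[i],
                        "acc_j": self.labels[j],
                        "species_i": self.species[i],
                        "species_j": self.species[j],
                        "d": round(float(self.d[i, j]), 4) if code == CODE_OK else "",
                        "n_sites": int(self.n[i, j]),
                        "class": (
                            "undefined_saturated"
                            if code == CODE_SATURATED
                            else "undefined_no_overlap"
                            if code == CODE_NO_OVERLAP
                            else "intra"
                            if self.species[i] == self.species[j]
                            else "inter"
                        ),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["acc_i", "acc_j", "species_i", "species_j", "d", "n_sites", "class"],
        )

    def to_square_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = []
                for j in range(len(self)):
                    code = self.codes[i, j]
                    if code == CODE_SATURATED:
                        cells.append("NA_saturated")
                    elif code == CODE_NO_OVERLAP:
                        cells.append("NA_no_overlap")
                    else:
                        cells.append(f"{self.d[i, j]:.4f}")
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


def _encode_rows(rows: Sequence[str]) -> np.ndarray:
    return np.vstack([encode(r) for r in rows])


def distance_matrix(alignment, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs K2P over a trimmed alignment (vectorized, pairwise deletion).

    ``alignment`` is a :class:`~barcodegap.anchor_trim.TrimmedAlignment` or any
    object with ``rows`` of ``(accession, species, aligned_bases)``.
    """
    rows = list(alignment.rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    labels = [r[0] for r in rows]
    species = [r[1] for r in rows]
    mat = _encode_rows([r[2] for r in rows])
    nseq = mat.shape[0]
    d = np.zeros((nseq, nseq))
    n = np.full((nseq, nseq), mat.shape[1], dtype=np.int64)
    codes = np.zeros((nseq, nseq), dtype=np.uint8)
    ok_self = mat < 4
    np.fill_diagonal(n, ok_self.sum(axis=1))
    for i in range(nseq - 1):
        a = mat[i]
        rest = mat[i + 1 :]
        valid = (a < 4) & (rest < 4)
        nv = valid.sum(axis=1)
        diff = valid & (a != rest)
        ts = diff & ((a >> 1) == (rest >> 1))
        nts = ts.sum(axis=1)
        ntv = diff.sum(axis=1) - nts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = nts / nv
            Q = ntv / nv
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            dij = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        no_overlap = nv < min_overlap
        saturated = ~no_overlap & ((w1 <= 0) | (w2 <= 0))
        dij = np.where(no_overlap | saturated, np.nan, dij)
        sl = slice(i + 1, nseq)
        d[i, sl] = dij
        d[sl, i] = dij
        n[i, sl] = nv
        n[sl, i] = nv
        code = np.zeros(nv.shape, dtype=np.uint8)
        code[saturated] = CODE_SATURATED
        code[no_overlap] = CODE_NO_OVERLAP
        codes[i, sl] = code
        codes[sl, i] = code
    return DistanceMatrix(labels, species, d, n, codes)
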