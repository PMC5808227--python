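"""Barcode-gap partitioning and the distance-ruler flags.

The screen rests on the empirical gap between conspecific divergence
(generally below 1%) and between-species divergence (generally above 10%)
at this locus.  Three flag categories, all derived from the K2P matrix:

- DEEP_INTRA     — intraspecific divergence above ``t_intra`` (default 1%).
  Emitted at sequence level when one sequence is isolated from every
  conspecific (its *minimum* conspecific distance exceeds the threshold: the
  mislabel/contamination signature), and at species level when the species'
  intra range exceeds the threshold without any isolated sequence (the
  cryptic-complex signature).
- SHALLOW_INTER  — a species pair whose minimum interspecific distance falls
  below ``t_inter`` (default 10%): recent divergence, introgression,
  synonymy or misidentification.
- INVERSION      — a sequence strictly closer to some heterospecific than to
  any conspecific, given that both sides of the ruler are violated (its
  conspecific minimum exceeds ``t_intra`` and its heterospecific minimum
  falls below ``t_inter``); the strongest error signature.

Both thresholds are strict inequalities.  Undefined (sentinel) distances
never trigger flags; they are tallied in the report header.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distance import CODE_OK, CODE_SATURATED, CODE_NO_OVERLAP, DistanceMatrix

DEFAULT_T_INTRA = 0.01
DEFAULT_T_INTER = 0.10


class FlagCategory(enum.Enum):
    DEEP_INTRA = "DEEP_INTRA"
    SHALLOW_INTER = "SHALLOW_INTER"
    INVERSION = "INVERSION"


@dataclass(frozen=True)
class FlagRecord:
    """One flagged sequence (or species / species pair) with evidence."""

    accession: str  # sequence accession, species name, or "A / B" pair
    species: str
    category: FlagCategory
    partner: str  # partner species or accession attaining the extreme
    d_min: float
    d_max: float
    n_evidence_pairs: int
    severity: float  # threshold exceedance; larger = worse

    def __post_init__(self):
        if self.n_evidence_pairs < 1:
            raise ValueError("a flag needs at least one evidence pair")


# ---------------------------------------------------------------------------
# Partition and summaries
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    intra: list[tuple[tuple[str, str], float]]
    inter: list[tuple[tuple[str, str], float]]
    n_excluded_saturated: int = 0
    n_excluded_no_overlap: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_saturated + self.n_excluded_no_overlap


def partition_distances(dm: DistanceMatrix) -> Partition:
    """Assign every defined off-diagonal distance to intra or inter."""
    intra, inter = [], []
    n_sat = n_nov = 0
    n = len(dm)
    for i in range(n):
        for j in range(i + 1, n):
            code = dm.codes[i, j]
            if code == CODE_SATURATED:
                n_sat += 1
                continue
            if code == CODE_NO_OVERLAP:
                n_nov += 1
                continue
            pair = (dm.labels[i], dm.labels[j])
            if dm.species[i] == dm.species[j]:
                intra.append((pair, float(dm.d[i, j])))
            else:
                inter.append((pair, float(dm.d[i, j])))
    return Partition(intra, inter, n_sat, n_nov)


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_seqs: int
    intra_min: float | None
    intra_max: float | None
    intra_mean: float | None
    nearest_heterospecific: tuple[str, float] | None


def species_summaries(dm: DistanceMatrix) -> dict[str, SpeciesSummary]:
    sp = np.asarray(dm.species)
    defined = dm.codes == CODE_OK
    np.fill_diagonal(defined, False)
    out: dict[str, SpeciesSummary] = {}
    for species in sorted(set(dm.species)):
        rows = np.nonzero(sp == species)[0]
        cols = np.nonzero(sp != species)[0]
        intra_mask = np.triu(defined[np.ix_(rows, rows)], 1)
        intra_vals = dm.d[np.ix_(rows, rows)][intra_mask]
        nearest = None
        if cols.size:
            inter_sub = dm.d[np.ix_(rows, cols)]
            inter_mask = defined[np.ix_(rows, cols)]
            if inter_mask.any():
                masked = np.where(inter_mask, inter_sub, np.inf)
                flat = int(np.argmin(masked))
                jj = cols[flat % cols.size]
                nearest = (dm.species[jj], float(masked.min()))
        out[species] = SpeciesSummary(
            species,
            len(rows),
            float(intra_vals.min()) if intra_vals.size else None,
            float(intra_vals.max()) if intra_vals.size else None,
            float(intra_vals.mean()) if intra_vals.size else None,
            nearest,
        )
    return out


# ---------------------------------------------------------------------------
# Flags
# ---------------------------------------------------------------------------

def _defined_offdiag(dm: DistanceMatrix) -> np.ndarray:
    mask = dm.codes == CODE_OK
    np.fill_diagonal(mask, False)
    return mask


def flag_deep_intra(
    dm: DistanceMatrix, t_intra: float = DEFAULT_T_INTRA
) -> list[FlagRecord]:
    """Deep intraspecific divergence: isolated sequences and cryptic complexes.

    Sequence level: minimum defined distance to any conspecific strictly
    exceeds ``t_intra``.  Species level (accession field = species name):
    the species' maximum intraspecific distance exceeds ``t_intra`` but no
    single sequence is isolated.
    """
    if t_intra <= 0:
        raise ValueError("t_intra must be positive")
    sp = np.asarray(dm.species)
    defined = _defined_offdiag(dm)
    same_sp = sp[:, None] == sp[None, :]
    flags: list[FlagRecord] = []
    flagged_species: set[str] = set()
    for i in range(len(dm)):
        mask = defined[i] & same_sp[i]
        if not mask.any():
            continue
        vals = dm.d[i][mask]
        dmin = float(vals.min())
        if dmin > t_intra:
            j = int(np.nonzero(mask)[0][np.argmin(vals)])
            flags.append(
                FlagRecord(
                    dm.labels[i], dm.species[i], FlagCategory.DEEP_INTRA,
                    dm.labels[j], dmin, float(vals.max()), int(mask.sum()),
                    severity=dmin - t_intra,
                )
            )
            flagged_species.add(dm.species[i])
    # species-level: wide intra range, nobody isolated
    for species, summary in species_summaries(dm).items():
        if species in flagged_species or summary.intra_max is None:
            continue
        if summary.intra_max > t_intra:
            rows = np.nonzero(sp == species)[0]
            n_pairs = int(np.triu(defined[np.ix_(rows, rows)], 1).sum())
            flags.append(
                FlagRecord(
                    species, species, FlagCategory.DEEP_INTRA, species,
                    summary.intra_min, summary.intra_max, n_pairs,
                    severity=summary.intra_max - t_intra,
                )
            )
    return flags


def flag_shallow_inter(
    dm: DistanceMatrix, t_inter: float = DEFAULT_T_INTER
) -> list[FlagRecord]:
    """One flag per unordered species pair with min inter distance < t_inter."""
    if t_inter <= 0:
        raise ValueError("t_inter must be positive")
    sp = np.asarray(dm.species)
    defined = _defined_offdiag(dm)
    flags: list[FlagRecord] = []
    species = sorted(set(dm.species))
    for a_idx in range(len(species)):
        for b_idx in range(a_idx + 1, len(species)):
            a, b = species[a_idx], species[b_idx]
            rows = np.nonzero(sp == a)[0]
            cols = np.nonzero(sp == b)[0]
            sub = dm.d[np.ix_(rows, cols)]
            mask = defined[np.ix_(rows, cols)]
            if not mask.any():
                continue
            vals = sub[mask]
            dmin = float(vals.min())
            if dmin < t_inter:
                flat = int(np.argmin(np.where(mask, sub, np.inf)))
                i, j = rows[flat // len(cols)], cols[flat % len(cols)]
                flags.append(
                    FlagRecord(
                        f"{a} / {b}", a, FlagCategory.SHALLOW_INTER,
                        f"{dm.labels[i]} / {dm.labels[j]}",
                        dmin, float(vals.max()), int(mask.sum()),
                        severity=t_inter - dmin,
                    )
                )
    return flags


def flag_inversion(
    dm: DistanceMatrix,
    t_intra: float = DEFAULT_T_INTRA,
    t_inter: float = DEFAULT_T_INTER,
) -> tuple[list[FlagRecord], int]:
    """Sequences strictly closer to a heterospecific than to any conspecific.

    The rule is applied sequentially, mirroring how the ruler is used: a
    sequence is an inversion when its conspecific divergence is itself
    problematic (min conspecific distance > ``t_intra``), its nearest
    heterospecific is problematically close (< ``t_inter``), and that
    heterospecific distance is strictly below the conspecific minimum.
    Conditioning on the ruler keeps ordinary conspecifics of an anomalous
    sequence — whose own divergences are all shallow — out of the flag set.

    Returns the flags and the count of sequences skipped for lack of
    conspecific (or heterospecific) comparisons.
    """
    sp = np.asarray(dm.species)
    defined = _defined_offdiag(dm)
    same_sp = sp[:, None] == sp[None, :]
    flags: list[FlagRecord] = []
    skipped = 0
    for i in range(len(dm)):
        con = defined[i] & same_sp[i]
        het = defined[i] & ~same_sp[i]
        if not con.any() or not het.any():
            skipped += 1
            continue
        con_vals = dm.d[i][con]
        het_vals = dm.d[i][het]
        min_con, min_het = float(con_vals.min()), float(het_vals.min())
        if min_het < min_con and min_con > t_intra and min_het < t_inter:
            j = int(np.nonzero(het)[0][np.argmin(het_vals)])
            flags.append(
                FlagRecord(
                    dm.labels[i], dm.species[i], FlagCategory.INVERSION,
                    dm.labels[j], min_het, min_con, int(con.sum() + het.sum()),
                    severity=min_con - min_het,
                )
            )
    return flags, skipped


# ---------------------------------------------------------------------------
# Histograms (Figure-1-style summaries)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray  # bin edges, half-open [lo, hi)
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "count": self.counts,
            }
        )


def _histogram(values: Sequence[float], bin_width: float) -> Histogram:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return Histogram(np.array([0.0]), np.array([], dtype=int))
    n_bins = max(1, int(math.floor(vals.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((vals / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return Histogram(edges, counts)


def gap_histograms(
    partition: Partition, bin_width: float = 0.005
) -> tuple[Histogram, Histogram]:
    """Fixed-width binned counts of intra- and interspecific distances."""
    return (
        _histogram([d for _, d in partition.intra], bin_width),
        _histogram([d for _, d in partition.inter], bin_width),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

COLUMNS = [
    "accession", "species", "category", "partner",
    "d_min", "d_max", "n_evidence_pairs", "severity",
]


@dataclass
class Report:
    flags: list[FlagRecord]
    n_sequences: int
    n_species: int
    n_intra_pairs: int
    n_inter_pairs: int
    n_excluded_pairs: int
    inversion_skipped: int = 0

    @property
    def n_flag_rows(self) -> int:
        return len(self.flags)

    @property
    def n_flagged_sequences(self) -> int:
        """Distinct flagged accessions (species/pair-level rows excluded)."""
        accs = {
            f.accession
            for f in self.flags
            if f.accession != f.species and " / " not in f.accession
        }
        return len(accs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "accession": f.accession,
                "species": f.species,
                "category": f.category.value,
                "partner": f.partner,
                "d_min": round(f.d_min, 4),
                "d_max": round(f.d_max, 4),
                "n_evidence_pairs": f.n_evidence_pairs,
                "severity": round(f.severity, 4),
            }
            for f in self.flags
        ]
        return pd.DataFrame(rows, columns=COLUMNS)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sequences: {self.n_sequences}\n")
            fh.write(f"# species: {self.n_species}\n")
            fh.write(f"# intra_pairs: {self.n_intra_pairs}\n")
            fh.write(f"# inter_pairs: {self.n_inter_pairs}\n")
            fh.write(f"# excluded_pairs: {self.n_excluded_pairs}\n")
            fh.write(f"# inversion_skipped: {self.inversion_skipped}\n")
            fh.write(f"# flag_rows: {self.n_flag_rows}\n")
            fh.write(f"# flagged_sequences: {self.n_flagged_sequences}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        doc = {
            "summary": {
                "n_sequences": self.n_sequences,
                "n_species": self.n_species,
                "n_intra_pairs": self.n_intra_pairs,
                "n_inter_pairs": self.n_inter_pairs,
                "n_excluded_pairs": self.n_excluded_pairs,
                "inversion_skipped": self.inversion_skipped,
                "n_flag_rows": self.n_flag_rows,
                "n_flagged_sequences": self.n_flagged_sequences,
            },
            "flags": json.loads(self.to_dataframe().to_json(orient="records")),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compile_report(
    flags: Iterable[FlagRecord],
    dm: DistanceMatrix,
    partition: Partition | None = None,
    inversion_skipped: int = 0,
) -> Report:
    """Deduplicate to one row per (accession, category), sorted by severity.

    A sequence carrying several categories keeps one row per category; the
    most severe evidence wins within a pair.
    """
    if partition is None:
        partition = partition_distances(dm)
    best: dict[tuple[str, str], FlagRecord] = {}
    for f in flags:
        key = (f.accession, f.category.value)
        if key not in best or f.severity > best[key].severity:
            best[key] = f
    ordered = sorted(best.values(), key=lambda f: (-f.severity, f.accession))
    return Report(
        ordered,
        n_sequences=len(dm),
        n_species=len(set(dm.species)),
        n_intra_pairs=len(partition.intra),
        n_inter_pairs=len(partition.inter),
        n_excluded_pairs=partition.n_excluded,
        inversion_skipped=inversion_skipped,
    )


def screen(
    dm: DistanceMatrix,
    t_intra: float = DEFAULT_T_INTRA,
    t_inter: float = DEFAULT_T_INTER,
) -> Report:
    """Run all three flaggers and compile the deduplicated report."""
    partition = partition_distances(dm)
    deep = flag_deep_intra(dm, t_intra)
    shallow = flag_shallow_inter(dm, t_inter)
    inv, skipped = flag_inversion(dm, t_intra, t_inter)
    return compile_report(
        deep + shallow + inv, dm, partition, inversion_skipped=skipped
    )
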