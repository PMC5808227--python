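"""Reference-anchored trimming of heterogeneous sequence fragments.

Partial-gene fragments of very different lengths and offsets are mapped one by
one onto a single full-length reference coding sequence by end-gap-free
pairwise alignment; the alignment is then projected into reference
coordinates (insertions relative to the reference are dropped).  A common
analysis window is chosen by trading window length against the number of
fragments that fully cover it, and an equal-length trimmed alignment is
emitted for distance computation.

Because the target locus is protein-coding and indel-sparse, projecting
pairwise anchors gives directly comparable columns without an O(N^2 * L)
multiple alignment; an externally produced MSA can alternatively be ingested
via :meth:`TrimmedAlignment.from_records`.

Coordinates are 0-based half-open internally; reports print 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .seqio import SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringConfig:
    """Nucleotide alignment scores (end gaps free)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_identity: float = 0.50


@dataclass(frozen=True)
class AnchoredFragment:
    """A fragment laid out in reference coordinates."""

    accession: str
    species: str
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    gapped_bases: str  # length == ref_end - ref_start
    identity_to_ref: float

    def __post_init__(self):
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError("invalid reference window")
        if len(self.gapped_bases) != self.ref_end - self.ref_start:
            raise ValueError("gapped_bases length mismatch")


class UnanchorableError(ValueError):
    """Identity to the reference fell below the floor (possible non-homolog)."""

    def __init__(self, accession: str, identity: float):
        super().__init__(f"{accession}: identity {identity:.3f} below anchoring floor")
        self.accession = accession
        self.identity = identity


def _make_aligner(scoring: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # end gaps free on both sequences: fragments are sub-regions of the gene
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def anchor_to_reference(
    record: SeqRecord,
    reference: SeqRecord,
    scoring: ScoringConfig = ScoringConfig(),
) -> AnchoredFragment:
    """Anchor one fragment onto the reference, auto-detecting orientation.

    Both strands are aligned and the higher-scoring orientation kept; the
    result is always reported on the reference (plus) strand.  Raises
    :class:`UnanchorableError` when identity over aligned columns falls below
    ``scoring.min_identity``.
    """
    if not record.bases or not reference.bases:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scoring)
    ref = reference.bases
    query_fwd = record.bases.replace("-", "")
    query_rev = reverse_complement(query_fwd)
    aln_fwd = aligner.align(ref, query_fwd)[0]
    aln_rev = aligner.align(ref, query_rev)[0]
    aln, query = (
        (aln_fwd, query_fwd) if aln_fwd.score >= aln_rev.score else (aln_rev, query_rev)
    )
    target_blocks, query_blocks = (list(map(tuple, b)) for b in aln.aligned)
    if len(target_blocks) == 0:
        raise UnanchorableError(record.accession, 0.0)
    # Free end gaps let the aligner trim mismatching terminal bases into end
    # gaps; fragments are contiguous subsequences of the gene, so extend the
    # terminal blocks diagonally to keep those bases in reference coordinates.
    t0, _ = target_blocks[0]
    q0, _ = query_blocks[0]
    shift = min(q0, t0)
    if shift:
        target_blocks.insert(0, (t0 - shift, t0))
        query_blocks.insert(0, (q0 - shift, q0))
    _, t1 = target_blocks[-1]
    _, q1 = query_blocks[-1]
    shift = min(len(query) - q1, len(ref) - t1)
    if shift:
        target_blocks.append((t1, t1 + shift))
        query_blocks.append((q1, q1 + shift))
    ref_start = int(target_blocks[0][0])
    ref_end = int(target_blocks[-1][1])
    window = ["-"] * (ref_end - ref_start)
    matches = 0
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        for k in range(t1 - t0):
            base = query[q0 + k]
            window[t0 - ref_start + k] = base
            if base == ref[t0 + k]:
                matches += 1
    # identity over the whole fragment, not just aligned columns: a spurious
    # short high-scoring core on a non-homolog must not look like an anchor
    identity = matches / len(query) if query else 0.0
    if identity < scoring.min_identity:
        raise UnanchorableError(record.accession, identity)
    return AnchoredFragment(
        record.accession, record.species, ref_start, ref_end, "".join(window), identity
    )


def anchor_all(
    records: Iterable[SeqRecord],
    reference: SeqRecord,
    scoring: ScoringConfig = ScoringConfig(),
) -> tuple[list[AnchoredFragment], list[tuple[str, str, float]]]:
    """Anchor many records; returns (fragments, report of excluded records).

    Report entries are ``(accession, reason, identity)``.
    """
    fragments: list[AnchoredFragment] = []
    excluded: list[tuple[str, str, float]] = []
    for rec in records:
        try:
            fragments.append(anchor_to_reference(rec, reference, scoring))
        except UnanchorableError as exc:
            excluded.append((rec.accession, "unanchorable", exc.identity))
    return fragments, excluded


# ---------------------------------------------------------------------------
# Window selection
# ---------------------------------------------------------------------------

class NoCommonRegionError(ValueError):
    pass


def select_window(
    fragments: Sequence[AnchoredFragment],
    objective: str = "n_times_length",
    params: dict | None = None,
) -> tuple[int, int]:
    """Choose the analysis window from fragment extents.

    ``n_times_length`` maximizes (fragments fully covering the window) x
    (window length) over all pairs of fragment start/end breakpoints — the
    length-versus-coverage tradeoff.  Ties prefer the longer window, then the
    smaller start.  ``min_coverage_fraction`` returns the longest window fully
    covered by at least ``params['fraction']`` of the fragments.
    """
    if not fragments:
        raise ValueError("no fragments")
    params = params or {}
    starts = np.array([f.ref_start for f in fragments])
    ends = np.array([f.ref_end for f in fragments])
    bps = np.unique(np.concatenate([starts, ends]))
    # counts[i, j] = number of fragments covering [bps[i], bps[j])
    cover_s = starts[:, None] <= bps[None, :]  # (n, B)
    cover_e = ends[:, None] >= bps[None, :]
    counts = cover_s.T.astype(np.int64) @ cover_e.astype(np.int64)  # (B, B)
    lengths = bps[None, :] - bps[:, None]
    valid = lengths > 0
    if objective == "n_times_length":
        eligible = valid & (counts >= 2)
        if not eligible.any():
            raise NoCommonRegionError("no window covered by >= 2 fragments")
        score = np.where(eligible, counts * lengths, -1)
        best = score.max()
        ii, jj = np.nonzero(score == best)
        # ties: longer window first, then smaller start
        order = sorted(zip(ii, jj), key=lambda p: (-(bps[p[1]] - bps[p[0]]), bps[p[0]]))
        i, j = order[0]
        return int(bps[i]), int(bps[j])
    if objective == "min_coverage_fraction":
        fraction = float(params.get("fraction", 0.9))
        need = max(2, int(np.ceil(fraction * len(fragments))))
        eligible = valid & (counts >= need)
        if not eligible.any():
            raise NoCommonRegionError(
                f"no window covered by >= {fraction:.0%} of fragments"
            )
        score = np.where(eligible, lengths, -1)
        best = score.max()
        ii, jj = np.nonzero(score == best)
        order = sorted(zip(ii, jj), key=lambda p: bps[p[0]])
        i, j = order[0]
        return int(bps[i]), int(bps[j])
    raise ValueError(f"unknown objective {objective!r}")


# ---------------------------------------------------------------------------
# Trimmed alignment
# ---------------------------------------------------------------------------

@dataclass
class TrimmedAlignment:
    """Equal-length alignment over a reference window.

    ``rows`` are ``(accession, species, aligned_bases)`` with every row of
    length ``end - start``.
    """

    window: tuple[int, int]
    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        start, end = self.window
        if end <= start:
            raise ValueError("empty window")
        n_sites = end - start
        seen = set()
        for acc, _sp, bases in self.rows:
            if len(bases) != n_sites:
                raise ValueError(f"{acc}: row length {len(bases)} != {n_sites}")
            if acc in seen:
                raise ValueError(f"duplicate accession {acc}")
            seen.add(acc)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return self.window[1] - self.window[0]

    @property
    def accessions(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def species(self) -> list[str]:
        return [r[1] for r in self.rows]

    @classmethod
    def from_records(cls, records: Sequence[SeqRecord]) -> "TrimmedAlignment":
        """Ingest pre-aligned equal-length records (e.g. an external MSA)."""
        if not records:
            raise ValueError("no records")
        n_sites = len(records[0].bases)
        return cls((0, n_sites), [(r.accession, r.species, r.bases) for r in records])

    def to_fasta(self, path) -> None:
        from .seqio import SeqRecord, write_fasta

        write_fasta([SeqRecord(a, s, b) for a, s, b in self.rows], path)

    def subsample(self, indices: Sequence[int]) -> "TrimmedAlignment":
        return TrimmedAlignment(self.window, [self.rows[i] for i in indices])

    def resample_columns(self, column_indices: Sequence[int]) -> "TrimmedAlignment":
        idx = list(column_indices)
        rows = [(a, s, "".join(b[i] for i in idx)) for a, s, b in self.rows]
        return TrimmedAlignment((0, len(idx)), rows)


def build_trimmed_alignment(
    fragments: Sequence[AnchoredFragment],
    window: tuple[int, int],
    min_window_coverage: float = 1.0,
) -> tuple[TrimmedAlignment, list[tuple[str, str, float]]]:
    """Slice fragments over the window, keeping those with enough coverage.

    Coverage is the fraction of the window spanned by the fragment's anchored
    extent; the default 1.0 keeps only fragments spanning the whole window
    (a fixed-length dataset).  Rare internal alignment gaps do not count
    against coverage — they stay in the row and are excluded per pair by the
    distance stage's pairwise deletion.  Returns the alignment and a report
    of excluded fragments as ``(accession, reason, coverage)``.
    """
    start, end = window
    if not 0 < min_window_coverage <= 1:
        raise ValueError("min_window_coverage must be in (0, 1]")
    n_sites = end - start
    rows: list[tuple[str, str, str]] = []
    excluded: list[tuple[str, str, float]] = []
    for frag in fragments:
        lo = max(start, frag.ref_start)
        hi = min(end, frag.ref_end)
        if hi <= lo:
            row = "-" * n_sites
            coverage = 0.0
        else:
            piece = frag.gapped_bases[lo - frag.ref_start : hi - frag.ref_start]
            row = "-" * (lo - start) + piece + "-" * (end - hi)
            coverage = (hi - lo) / n_sites
        if coverage >= min_window_coverage:
            rows.append((frag.accession, frag.species, row))
        else:
            excluded.append((frag.accession, "low_window_coverage", coverage))
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} fragments cover the window; distances/trees undefined"
        )
    return TrimmedAlignment(window, rows), excluded
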