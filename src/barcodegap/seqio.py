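"""Sequence I/O: FASTA reading/writing, species-label parsing and synonym handling.

Records are mitochondrial protein-coding fragments whose FASTA headers carry a
GenBank-style accession followed by a species binomial (the dialect NCBI batch
downloads produce).  Species names are analysed at binomial rank: subspecific
epithets are dropped with a warning, and an optional user-supplied synonym
table maps outdated binomials onto their current canonical names before any
intra/interspecific partitioning happens downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes plus the gap symbol.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

_ACCESSION_RE = re.compile(r"^[A-Za-z0-9_.]+$")


class HeaderParseError(ValueError):
    """A FASTA header did not yield an accession and a species binomial."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class DuplicateAccessionError(ValueError):
    """Two records share the same accession; per-record identity is broken."""


@dataclass(frozen=True)
class SeqRecord:
    """One sequence with its accession, species binomial and raw bases."""

    accession: str
    species: str
    bases: str

    @property
    def source_length(self) -> int:
        """Ungapped length in bp."""
        return len(self.bases) - self.bases.count("-")

    def with_species(self, species: str) -> "SeqRecord":
        return SeqRecord(self.accession, species, self.bases)

    def with_bases(self, bases: str) -> "SeqRecord":
        return SeqRecord(self.accession, self.species, bases)


# ---------------------------------------------------------------------------
# Species names
# ---------------------------------------------------------------------------

def canonical_case(name: str) -> str:
    """Collapse whitespace and case-normalize a binomial (Genus epithet)."""
    words = name.split()
    if not words:
        return ""
    out = [words[0].capitalize()] + [w.lower() for w in words[1:]]
    return " ".join(out)


def parse_binomial(words: Sequence[str]) -> str:
    """Extract a two-word binomial from title words, dropping subspecific epithets.

    Raises :class:`HeaderParseError` when fewer than two words are available.
    """
    if len(words) < 2:
        raise HeaderParseError(f"cannot form a binomial from {words!r}")
    if len(words) > 2 and words[2].islower() and words[2].isalpha():
        logger.warning("dropping subspecific epithet %r from %r", words[2], " ".join(words[:3]))
    return canonical_case(" ".join(words[:2]))


class SynonymTable:
    """Mapping from alias binomials to canonical binomials.

    The mapping is idempotent after construction: chains (a→b, b→c) are
    collapsed and cycles rejected.  Lookups are case-insensitive at binomial
    rank.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        raw = {canonical_case(k): canonical_case(v) for k, v in (mapping or {}).items()}
        self._map: dict[str, str] = {}
        for alias in raw:
            target = raw[alias]
            seen = {alias}
            while target in raw and raw[target] != target:
                if target in seen:
                    raise ValueError(f"synonym cycle involving {alias!r}")
                seen.add(target)
                target = raw[target]
            self._map[alias] = target

    def resolve(self, name: str) -> str:
        name = canonical_case(name)
        return self._map.get(name, name)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return canonical_case(name) in self._map

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """Load a 2-column TSV (alias<TAB>canonical); '#' starts a comment."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                mapping[parts[0].strip()] = parts[1].strip()
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for alias, canon in sorted(self._map.items()):
                fh.write(f"{alias}\t{canon}\n")


def normalize_species(name: str, table: SynonymTable | None = None) -> str:
    """Return the canonical binomial for ``name``.

    Names absent from the table come back unchanged apart from case and
    whitespace normalization.  Non-binomial input (a single word, or extra
    words that are not a droppable subspecific epithet) raises ``ValueError``.
    """
    words = name.split()
    if len(words) < 2:
        raise ValueError(f"not a binomial: {name!r}")
    if len(words) > 2:
        if words[2].islower() and words[2].isalpha():
            logger.warning("dropping subspecific epithet in %r", name)
            words = words[:2]
        else:
            raise ValueError(f"not a binomial: {name!r}")
    canon = canonical_case(" ".join(words))
    return table.resolve(canon) if table is not None else canon


# ---------------------------------------------------------------------------
# FASTA reading / writing
# ---------------------------------------------------------------------------

def _parse_header(title: str, dialect: str, regex: re.Pattern | None) -> tuple[str, str]:
    words = title.split()
    if dialect == "genbank_title":
        # ">AB111222.1 Carassius auratus mitochondrion ..." — accession token,
        # then the first two title words form the binomial.
        if not words:
            raise HeaderParseError("empty header")
        accession = words[0]
        if not _ACCESSION_RE.match(accession):
            raise HeaderParseError(f"bad accession token {accession!r}")
        species = parse_binomial(words[1:4])
        return accession, species
    if dialect == "accession_species":
        # ">ACC|Genus_species" or ">ACC|Genus species"
        head = title.split("|")
        if len(head) != 2:
            raise HeaderParseError(f"expected 'accession|species' in {title!r}")
        accession = head[0].strip()
        species = parse_binomial(head[1].replace("_", " ").split())
        return accession, species
    if dialect == "custom_regex":
        if regex is None:
            raise ValueError("custom_regex dialect requires a compiled regex")
        m = regex.search(title)
        if not m or "accession" not in m.groupdict() or "species" not in m.groupdict():
            raise HeaderParseError(f"regex did not capture accession/species in {title!r}")
        return m.group("accession"), parse_binomial(m.group("species").replace("_", " ").split())
    raise ValueError(f"unknown header dialect {dialect!r}")


def read_fasta(
    path: str | Path,
    header_dialect: str = "genbank_title",
    *,
    regex: str | re.Pattern | None = None,
    synonyms: SynonymTable | None = None,
    return_errors: bool = False,
) -> list[SeqRecord] | tuple[list[SeqRecord], list[HeaderParseError]]:
    """Read a multi-record FASTA into :class:`SeqRecord` objects.

    Bases are upper-cased with ``U`` transliterated to ``T``.  Unparseable
    headers are collected (with their line numbers) and logged rather than
    aborting the read; a duplicate accession is a hard error.
    """
    if isinstance(regex, str):
        regex = re.compile(regex)
    path = Path(path)
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_lines.append(lineno)

    records: list[SeqRecord] = []
    errors: list[HeaderParseError] = []
    seen: set[str] = set()
    with open(path) as fh:
        for idx, (title, seq) in enumerate(SimpleFastaParser(fh)):
            line = header_lines[idx] if idx < len(header_lines) else None
            try:
                accession, species = _parse_header(title, header_dialect, regex)
            except HeaderParseError as exc:
                exc.line = line
                logger.warning("line %s: %s", line, exc)
                errors.append(exc)
                continue
            if accession in seen:
                raise DuplicateAccessionError(
                    f"duplicate accession {accession!r} at line {line}"
                )
            seen.add(accession)
            if synonyms is not None:
                species = synonyms.resolve(species)
            records.append(SeqRecord(accession, species, seq.upper().replace("U", "T")))
    if not records and not errors:
        logger.warning("no records read from %s", path)
    if return_errors:
        return records, errors
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records with ``>accession species`` headers, wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.species}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Rejection:
    record: SeqRecord
    reason: str


def validate_records(
    records: Sequence[SeqRecord], min_length: int = 1
) -> tuple[list[SeqRecord], list[Rejection]]:
    """Partition records into kept / rejected by length and alphabet.

    Rejections are data, not exceptions: the pair of lists is always a
    partition of the input.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[SeqRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        if not set(rec.bases) <= IUPAC_DNA:
            rejected.append(Rejection(rec, "bad_alphabet"))
        elif rec.source_length < min_length:
            rejected.append(Rejection(rec, "too_short"))
        else:
            kept.append(rec)
    return kept, rejected
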