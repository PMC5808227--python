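"""Synthetic barcode datasets with ground truth and injected anomalies.

The generator emulates the statistical structure a barcode-gap screen relies
on: many species, each represented by several conspecific sequences of
shallow divergence, separated from other species by deep divergence.  A
species tree with a birth-process topology is drawn and scaled so the mean
between-species path length equals ``inter_depth``; each species then gets a
star genealogy of tips at depth ``intra_depth / 2``, making the expected
conspecific divergence exactly ``intra_depth``.  Sequences evolve site-
independently under a two-rate (transition alpha / transversion beta,
alpha/beta = kappa) substitution model with exact per-branch substitution
probabilities — no event-by-event simulation.

Terminal species branches are fixed at 45% of ``inter_depth`` so that even
sister species diverge by at least 90% of the nominal depth; the birth
process shapes only the (small) internal structure.  This concentrates
interspecific divergences near ``inter_depth``, mirroring the empirically
deep, well-separated between-species distances the screen assumes, and makes
the intra/inter gap hold for essentially every seed.

Anomalies are injected with mutually exclusive per-sequence labels so that
recovery against ground truth is unambiguous:

- MISLABEL       — species label swapped to a random other species
- INTROGRESSION  — sequence replaced by one evolved from the nearest other
                   species' ancestor, original label kept
- CHIMERA        — back half spliced in from another species
- CRYPTIC        — a conspecific subcluster offset by an extra divergence of
                   10 x ``intra_depth`` (an unrecognized species)
- SYNONYM        — part of a species duplicated under a second binomial,
                   with the alias registered in a generated synonym table
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .njtree import Tree, TreeNode
from .seqio import SeqRecord, SynonymTable

_BASES = "AGCT"  # order matches distance.encode codes 0..3

GENERA = [
    "Simichthys", "Parasimus", "Fictogobius", "Pseudolates", "Modelbarbus",
    "Synthoperca", "Virtucypris", "Aulonotus", "Bencharhynchus", "Mockostoma",
    "Testasalmo", "Probacanthus", "Exemplarius", "Notionella", "Quasidanio",
]

EPITHETS = [
    "alphus", "betus", "gammus", "deltus", "epsilus", "zetus", "etus",
    "thetus", "iotus", "kappus", "lambdus", "mu", "nuus", "xius", "omicrus",
    "pius", "rhous", "sigmus", "tauus", "upsilus", "phius", "chius", "psius",
    "omegus", "primus", "secundus", "tertius", "quartus", "quintus", "sextus",
]


def species_name(i: int) -> str:
    g, e = GENERA[i % len(GENERA)], EPITHETS[(i // len(GENERA)) % len(EPITHETS)]
    if i >= len(GENERA) * len(EPITHETS):
        e = f"{e}{i}"
    return f"{g} {e}"


class Anomaly(enum.Enum):
    NONE = "NONE"
    MISLABEL = "MISLABEL"
    INTROGRESSION = "INTROGRESSION"
    CHIMERA = "CHIMERA"
    CRYPTIC = "CRYPTIC"
    SYNONYM = "SYNONYM"


@dataclass
class TruthEntry:
    true_species: str
    labeled_species: str
    anomaly: Anomaly = Anomaly.NONE
    donor_species: str | None = None

    def __post_init__(self):
        if self.anomaly is Anomaly.NONE and self.true_species != self.labeled_species:
            raise ValueError("NONE anomaly requires true == labeled species")
        if self.anomaly is Anomaly.MISLABEL and self.true_species == self.labeled_species:
            raise ValueError("MISLABEL requires true != labeled species")


class SimTruth:
    """Per-accession ground truth for recovery scoring."""

    def __init__(self, entries: dict[str, TruthEntry] | None = None):
        self.entries: dict[str, TruthEntry] = dict(entries or {})

    def __getitem__(self, accession: str) -> TruthEntry:
        return self.entries[accession]

    def __len__(self) -> int:
        return len(self.entries)

    def accessions_with(self, *anomalies: Anomaly) -> set[str]:
        want = set(anomalies)
        return {a for a, e in self.entries.items() if e.anomaly in want}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\ttrue_species\tlabeled_species\tanomaly\tdonor_species\n")
            for acc in sorted(self.entries):
                e = self.entries[acc]
                fh.write(
                    f"{acc}\t{e.true_species}\t{e.labeled_species}\t"
                    f"{e.anomaly.value}\t{e.donor_species or ''}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "SimTruth":
        entries = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                acc, true_sp, lab_sp, anom, donor = line.rstrip("\n").split("\t")
                entries[acc] = TruthEntry(true_sp, lab_sp, Anomaly(anom), donor or None)
        return cls(entries)


@dataclass(frozen=True)
class AnomalyRates:
    mislabel: float = 0.0
    introgression: float = 0.0
    chimera: float = 0.0
    cryptic_split: float = 0.0
    synonym_pair: float = 0.0

    def total(self) -> float:
        return sum(
            (self.mislabel, self.introgression, self.chimera,
             self.cryptic_split, self.synonym_pair)
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the default barcode-gap scenario."""

    n_species: int = 40
    seqs_per_species: int = 5
    seq_length: int = 918
    intra_depth: float = 0.005  # expected conspecific divergence (subs/site)
    inter_depth: float = 0.15  # expected between-species divergence
    kappa: float = 4.0  # transition/transversion rate ratio
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    anomaly_rates: AnomalyRates = field(default_factory=AnomalyRates)
    fragmentation: tuple[int, int] | None = None  # (min_len, max_len) or None
    seed: int = 0

    def __post_init__(self):
        if self.intra_depth < 0 or self.inter_depth <= 0:
            raise ValueError("depths must be positive (intra may be 0 in the limit)")
        if self.n_species > 1 and self.intra_depth >= self.inter_depth:
            raise ValueError("gap scenario requires intra_depth < inter_depth")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        rates = self.anomaly_rates
        if any(
            r < 0 or r > 1
            for r in (rates.mislabel, rates.introgression, rates.chimera,
                      rates.cryptic_split, rates.synonym_pair)
        ) or rates.total() > 1:
            raise ValueError("anomaly rates must lie in [0,1] and jointly <= 1")


# ---------------------------------------------------------------------------
# Sequence evolution (two-rate model, closed-form branch probabilities)
# ---------------------------------------------------------------------------

def random_sequence(length: int, base_freqs, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=list(base_freqs)).astype(np.uint8)


def evolve(parent: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of length ``d`` expected substitutions/site.

    Rates are normalized so alpha + 2 beta = 1; with codes A=0 G=1 C=2 T=3
    the transition partner of ``x`` is ``x ^ 1`` and the transversion
    partners are ``x ^ 2`` and ``x ^ 3``.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_b = math.exp(-4.0 * beta * d)
    e_ab = math.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e_b + 0.5 * e_ab
    p_ts = 0.25 + 0.25 * e_b - 0.5 * e_ab
    p_tv = 0.25 - 0.25 * e_b  # each of the two transversion targets
    r = rng.random(parent.size)
    child = parent.copy()
    child[(r >= p_same) & (r < p_same + p_ts)] ^= 1
    child[(r >= p_same + p_ts) & (r < p_same + p_ts + p_tv)] ^= 2
    child[r >= p_same + p_ts + p_tv] ^= 3
    return child


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def _yule_topology(names: Sequence[str], rng: np.random.Generator) -> Tree:
    leaves = [TreeNode(name=n) for n in names]
    if len(leaves) == 1:
        return Tree(TreeNode(children=[leaves[0]]))
    root = TreeNode(children=[leaves[0], leaves[1]])
    parent = {id(leaves[0]): root, id(leaves[1]): root}
    tips = [leaves[0], leaves[1]]
    for leaf in leaves[2:]:
        target = tips[rng.integers(len(tips))]
        par = parent[id(target)]
        internal = TreeNode(children=[target, leaf])
        par.children[par.children.index(target)] = internal
        parent[id(internal)] = par
        parent[id(target)] = internal
        parent[id(leaf)] = internal
        tips.append(leaf)
    return Tree(root)


def draw_species_tree(
    n_species: int, inter_depth: float, rng: np.random.Generator
) -> Tree:
    """Birth-process topology scaled so mean tip-pair path = ``inter_depth``.

    Terminal edges are fixed at ``0.45 * inter_depth``; internal edges get
    exponential lengths rescaled to account for the remaining 10% of the mean.
    """
    names = [species_name(i) for i in range(n_species)]
    tree = _yule_topology(names, rng)
    if n_species == 1:
        tree.root.children[0].length = 0.0
        return tree
    stem = 0.45 * inter_depth
    if n_species == 2:
        for c in tree.root.children:
            c.length = inter_depth / 2
        return tree

    def assign(node: TreeNode):
        for c in node.children:
            c.length = stem if c.is_leaf else float(rng.exponential(1.0))
            assign(c)

    assign(tree.root)
    _, paths = tree.path_distance_matrix()
    n = paths.shape[0]
    mean_path = paths[np.triu_indices(n, 1)].mean()
    internal_mean = mean_path - 2 * stem
    target_internal = inter_depth - 2 * stem
    scale = target_internal / internal_mean if internal_mean > 0 else 0.0

    def rescale(node: TreeNode):
        for c in node.children:
            if not c.is_leaf:
                c.length *= scale
            rescale(c)

    rescale(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Clean simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    records: list[SeqRecord]
    truth: SimTruth
    tree: Tree
    reference: SeqRecord
    synonyms: SynonymTable
    ancestors: dict[str, np.ndarray]  # species -> ancestral codes


def _simulate_clean_full(config: SimConfig) -> SimResult:
    rng = np.random.default_rng([config.seed % (2**31), 11])
    # tips sit at intra_depth/2 below their species root, so the species-tree
    # paths target inter_depth - intra_depth to make the expected tip-to-tip
    # divergence between species equal inter_depth
    path_depth = max(config.inter_depth - config.intra_depth, config.inter_depth / 2)
    tree = draw_species_tree(config.n_species, path_depth, rng)
    root_codes = random_sequence(config.seq_length, config.base_freqs, rng)

    ancestors: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, codes: np.ndarray):
        for c in node.children:
            child_codes = evolve(codes, c.length, config.kappa, rng)
            if c.is_leaf:
                ancestors[c.name] = child_codes
            else:
                descend(c, child_codes)

    descend(tree.root, root_codes)

    records: list[SeqRecord] = []
    truth = SimTruth()
    counter = 1
    for i in range(config.n_species):
        sp = species_name(i)
        anc = ancestors[sp]
        for _ in range(config.seqs_per_species):
            codes = evolve(anc, config.intra_depth / 2, config.kappa, rng)
            acc = f"SIM{counter:06d}.1"
            counter += 1
            records.append(SeqRecord(acc, sp, decode(codes)))
            truth.entries[acc] = TruthEntry(sp, sp)
    reference = SeqRecord("SIMREF001.1", species_name(0), decode(root_codes))
    return SimResult(records, truth, tree, reference, SynonymTable(), ancestors)


def simulate_clean(config: SimConfig) -> tuple[list[SeqRecord], SimTruth, Tree]:
    """Anomaly-free dataset: records, ground truth, and the true species tree."""
    res = _simulate_clean_full(config)
    return res.records, res.truth, res.tree


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

def inject_anomalies(
    records: Sequence[SeqRecord],
    truth: SimTruth,
    config: SimConfig,
    *,
    ancestors: dict[str, np.ndarray] | None = None,
    tree: Tree | None = None,
) -> tuple[list[SeqRecord], SimTruth, SynonymTable]:
    """Apply the configured anomaly mix; assignments are disjoint per sequence.

    Counts per category are ``round(rate * n_records)``.  Returns modified
    records, updated truth, and a synonym table holding any generated aliases.
    """
    from .distance import encode as encode_bases

    rng = np.random.default_rng([config.seed % (2**31), 23])
    records = list(records)
    truth = SimTruth({a: replace(e) for a, e in truth.entries.items()})
    n = len(records)
    rates = config.anomaly_rates
    counts = {
        Anomaly.MISLABEL: round(rates.mislabel * n),
        Anomaly.INTROGRESSION: round(rates.introgression * n),
        Anomaly.CHIMERA: round(rates.chimera * n),
        Anomaly.CRYPTIC: round(rates.cryptic_split * n),
        Anomaly.SYNONYM: round(rates.synonym_pair * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("anomaly rates require more anomalies than sequences")

    species_list = sorted({r.species for r in records})
    by_species: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_species.setdefault(rec.species, []).append(idx)

    if ancestors is None:
        # fall back: use one member per species as a stand-in ancestor
        ancestors = {
            sp: encode_bases(records[idxs[0]].bases) for sp, idxs in by_species.items()
        }

    # nearest heterospecific by true-tree path; falls back to random choice
    nearest: dict[str, str] = {}
    if tree is not None and len(species_list) > 1:
        names, paths = tree.path_distance_matrix()
        for i, sp in enumerate(names):
            order = np.argsort(paths[i])
            for j in order:
                if names[j] != sp:
                    nearest[sp] = names[j]
                    break

    used: set[int] = set()
    synonyms: dict[str, str] = {}
    # An anomalous sequence "bridges" (species its bases came from, species it
    # is labeled as).  At most one anomaly per bridge: two anomalies sharing a
    # bridge would be each other's nearest "conspecifics" and neither could be
    # recovered from the distance matrix, making the truth labels ambiguous.
    bridges: set[tuple[str, str]] = set()

    def pick_free(k: int) -> list[int]:
        free = [i for i in range(n) if i not in used]
        if len(free) < k:
            raise ValueError("anomaly rates require more anomalies than sequences")
        chosen = rng.choice(len(free), size=k, replace=False)
        return [free[c] for c in chosen]

    def other_species(sp: str) -> str:
        choices = [s for s in species_list if s != sp]
        if not choices:
            raise ValueError("anomaly injection needs >= 2 species")
        return choices[rng.integers(len(choices))]

    # -- per-sequence anomalies -------------------------------------------
    for idx in pick_free(counts[Anomaly.MISLABEL]):
        used.add(idx)
        rec = records[idx]
        new_sp = other_species(rec.species)
        for _ in range(100):
            if (rec.species, new_sp) not in bridges:
                break
            new_sp = other_species(rec.species)
        bridges.add((rec.species, new_sp))
        records[idx] = rec.with_species(new_sp)
        truth.entries[rec.accession] = TruthEntry(
            rec.species, new_sp, Anomaly.MISLABEL
        )

    for idx in pick_free(counts[Anomaly.INTROGRESSION]):
        used.add(idx)
        rec = records[idx]
        donor = nearest.get(rec.species) or other_species(rec.species)
        for _ in range(100):
            if (donor, rec.species) not in bridges:
                break
            donor = other_species(rec.species)
        bridges.add((donor, rec.species))
        codes = evolve(ancestors[donor], config.intra_depth / 2, config.kappa, rng)
        records[idx] = rec.with_bases(decode(codes))
        truth.entries[rec.accession] = TruthEntry(
            rec.species, rec.species, Anomaly.INTROGRESSION, donor_species=donor
        )

    for idx in pick_free(counts[Anomaly.CHIMERA]):
        used.add(idx)
        rec = records[idx]
        donor = other_species(rec.species)
        half = len(rec.bases) // 2
        donor_codes = evolve(ancestors[donor], config.intra_depth / 2, config.kappa, rng)
        spliced = rec.bases[:half] + decode(donor_codes)[half : len(rec.bases)]
        records[idx] = rec.with_bases(spliced)
        truth.entries[rec.accession] = TruthEntry(
            rec.species, rec.species, Anomaly.CHIMERA, donor_species=donor
        )

    # -- species-level anomalies ------------------------------------------
    def pick_species_members(budget: int, min_size: int) -> list[int]:
        for sp in species_list:
            idxs = [i for i in by_species[sp] if i not in used]
            if len(idxs) == len(by_species[sp]) and len(idxs) >= min_size + 1:
                take = min(budget, max(min_size, len(idxs) // 2))
                take = min(take, len(idxs) - 1)  # keep part of the species intact
                chosen = list(rng.choice(idxs, size=take, replace=False))
                return chosen
        raise ValueError("no untouched species left for a species-level anomaly")

    remaining = counts[Anomaly.CRYPTIC]
    while remaining > 0:
        members = pick_species_members(remaining, min_size=2)
        sp = records[members[0]].species
        offset_anc = evolve(
            ancestors[sp], 10 * config.intra_depth, config.kappa, rng
        )
        for idx in members:
            used.add(idx)
            rec = records[idx]
            codes = evolve(offset_anc, config.intra_depth / 2, config.kappa, rng)
            records[idx] = rec.with_bases(decode(codes))
            truth.entries[rec.accession] = TruthEntry(sp, sp, Anomaly.CRYPTIC)
        remaining -= len(members)

    remaining = counts[Anomaly.SYNONYM]
    while remaining > 0:
        members = pick_species_members(remaining, min_size=1)
        sp = records[members[0]].species
        genus, epithet = sp.split()
        alias = f"{genus} {epithet}oides"
        synonyms[alias] = sp
        for idx in members:
            used.add(idx)
            rec = records[idx]
            records[idx] = rec.with_species(alias)
            truth.entries[rec.accession] = TruthEntry(sp, alias, Anomaly.SYNONYM)
        remaining -= len(members)

    return records, truth, SynonymTable(synonyms)


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragmentize(
    records: Sequence[SeqRecord], config: SimConfig
) -> list[SeqRecord]:
    """Truncate each record to a sampled (offset, length) window of the gene."""
    if config.fragmentation is None:
        return list(records)
    min_len, max_len = config.fragmentation
    if min_len < 1:
        raise ValueError("fragment length must be >= 1")
    rng = np.random.default_rng([config.seed % (2**31), 37])
    out = []
    for rec in records:
        L = len(rec.bases)
        length = int(rng.integers(min_len, min(max_len, L) + 1))
        offset = int(rng.integers(0, L - length + 1))
        out.append(rec.with_bases(rec.bases[offset : offset + length]))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimResult:
    """Full generator: clean data, anomaly injection, fragmentation."""
    res = _simulate_clean_full(config)
    records, truth, synonyms = inject_anomalies(
        res.records, res.truth, config, ancestors=res.ancestors, tree=res.tree
    )
    records = fragmentize(records, config)
    return SimResult(records, truth, res.tree, res.reference, synonyms, res.ancestors)


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, reference, truth TSV, synonym TSV and the true tree."""
    from . import njtree
    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "records.fasta",
        "reference": outdir / "reference.fasta",
        "truth": outdir / "truth.tsv",
        "synonyms": outdir / "synonyms.tsv",
        "tree": outdir / "true_tree.nwk",
    }
    write_fasta(result.records, paths["fasta"])
    write_fasta([result.reference], paths["reference"])
    result.truth.to_tsv(paths["truth"])
    result.synonyms.to_tsv(paths["synonyms"])
    njtree.write_newick(result.tree, paths["tree"])
    return paths
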