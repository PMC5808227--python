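"""Entropy-based index of substitution saturation (Iss) and its test.

A saturated alignment has lost phylogenetic signal: repeated substitutions
drive per-site base composition toward randomness.  The index compares the
observed mean per-site Shannon entropy with the entropy expected at full
substitution saturation (H_FSS), obtained from columns of i.i.d. draws from
the base composition:

    Iss = mean_site H_obs / H_FSS(n_otu)

Iss is evaluated on random subsamples of NumOTU rows (4/8/16/32 by default)
and compared against a critical value Iss.c below which signal is considered
retained; a t statistic with DF = n_sites - 1 and a two-sided p value are
reported per NumOTU, for both symmetric- and asymmetric-topology critical
values.

Iss.c is pluggable: either user-supplied constants (the bundled
:data:`DEFAULT_ISS_C` table carries reference values for alignments of
roughly a thousand sites) or the built-in simulation calibration
:func:`calibrate_iss_c`, which locates the Iss at which neighbor-joining
stops recovering the true topology reliably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anchor_trim import TrimmedAlignment
from .distance import encode

SYMMETRIC = "symmetric"
ASYMMETRIC = "asymmetric"


# ---------------------------------------------------------------------------
# Entropy primitives
# ---------------------------------------------------------------------------

def site_entropy(column: Sequence[str] | str) -> float:
    """Shannon entropy (bits) of one alignment column over A/C/G/T.

    Gaps and ambiguity codes are excluded; an empty column (after exclusion)
    raises ``ValueError`` — callers skip and report such sites.
    """
    codes = encode("".join(column))
    codes = codes[codes < 4]
    if codes.size == 0:
        raise ValueError("column empty after excluding gaps/ambiguities")
    counts = np.bincount(codes, minlength=4)
    p = counts[counts > 0] / codes.size
    return float(-(p * np.log2(p)).sum())


def _matrix(alignment: TrimmedAlignment) -> np.ndarray:
    return np.vstack([encode(r[2]) for r in alignment.rows])


def per_site_entropy(alignment: TrimmedAlignment) -> tuple[np.ndarray, int]:
    """Entropy per column (NaN where no usable bases) and the skipped count."""
    mat = _matrix(alignment)
    counts = np.stack([(mat == c).sum(axis=0) for c in range(4)])  # (4, L)
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / tot
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        H = -(p * logp).sum(axis=0)
    H = np.where(tot > 0, H, np.nan)
    return H, int((tot == 0).sum())


def _entropy_of_counts(counts: np.ndarray) -> np.ndarray:
    """Row-wise entropy of count vectors (bits)."""
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / tot
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


def h_fss(
    n_otu: int,
    base_freqs: Sequence[float],
    n_draws: int = 20000,
    seed: int | None = 0,
) -> float:
    """Expected column entropy at full saturation for ``n_otu`` sequences.

    Exact multinomial enumeration for ``n_otu <= 8``; Monte Carlo otherwise.
    Degenerate compositions (one base frequency of 1) give 0.
    """
    if n_otu < 2:
        raise ValueError("n_otu must be >= 2")
    f = np.asarray(base_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    if (f >= 1.0 - 1e-12).any():
        return 0.0
    if n_otu <= 8:
        total = 0.0
        logf = np.log(np.where(f > 0, f, 1.0))
        for na in range(n_otu + 1):
            for nc in range(n_otu - na + 1):
                for ng in range(n_otu - na - nc + 1):
                    nt = n_otu - na - nc - ng
                    counts = np.array([na, nc, ng, nt])
                    if ((counts > 0) & (f == 0)).any():
                        continue
                    logcoef = (
                        math.lgamma(n_otu + 1)
                        - sum(math.lgamma(c + 1) for c in counts)
                    )
                    prob = math.exp(logcoef + float((counts * logf).sum()))
                    total += prob * float(_entropy_of_counts(counts))
        return total
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_otu, f, size=n_draws)
    return float(_entropy_of_counts(draws).mean())


def observed_base_freqs(alignment: TrimmedAlignment) -> np.ndarray:
    mat = _matrix(alignment)
    counts = np.bincount(mat[mat < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("alignment has no usable bases")
    return counts / counts.sum()


def iss(
    alignment: TrimmedAlignment,
    base_freqs: Sequence[float] | None = None,
    seed: int | None = 0,
) -> float:
    """Observed mean site entropy over the full-saturation expectation."""
    if alignment.n_rows < 2:
        raise ValueError("need >= 2 rows")
    if base_freqs is None:
        base_freqs = observed_base_freqs(alignment)
    H, _skipped = per_site_entropy(alignment)
    if np.isnan(H).all():
        raise ValueError("no usable sites")
    hf = h_fss(alignment.n_rows, base_freqs, seed=seed)
    if hf == 0.0:
        return math.nan
    return float(np.nanmean(H)) / hf


# ---------------------------------------------------------------------------
# Critical values
# ---------------------------------------------------------------------------

class IssCTable:
    """Critical Iss values keyed by (NumOTU, topology)."""

    def __init__(self, values: dict[int, tuple[float, float]]):
        # values: num_otu -> (symmetric, asymmetric)
        self._values = dict(values)

    def get(self, num_otu: int, topology: str) -> float:
        if num_otu not in self._values:
            raise KeyError(
                f"no Iss.c value for NumOTU={num_otu}; supply one or calibrate"
            )
        sym, asym = self._values[num_otu]
        if topology == SYMMETRIC:
            return sym
        if topology == ASYMMETRIC:
            return asym
        raise ValueError(f"unknown topology {topology!r}")

    @classmethod
    def from_tsv(cls, path) -> "IssCTable":
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line or line.lower().startswith("numotu"):
                    continue
                num, sym, asym = line.split("\t")
                values[int(num)] = (float(sym), float(asym))
        return cls(values)


#: Reference critical values for ~10^3-site nucleotide alignments at the
#: standard subsample sizes; replace via a user table or calibrate_iss_c.
DEFAULT_ISS_C = IssCTable(
    {
        4: (0.817, 0.785),
        8: (0.784, 0.677),
        16: (0.766, 0.565),
        32: (0.742, 0.431),
    }
)


# ---------------------------------------------------------------------------
# The test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationResult:
    num_otu: int
    iss: float
    iss_c_sym: float
    t_sym: float
    df: int
    p_sym: float
    iss_c_asym: float
    t_asym: float
    p_asym: float
    replicates: int


def _t_and_p(iss_value: float, iss_c: float, se: float, df: int) -> tuple[float, float]:
    if se == 0.0:
        if iss_value == iss_c:
            return 0.0, 1.0
        return (math.inf if iss_c > iss_value else -math.inf), 0.0
    t = (iss_c - iss_value) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p


def iss_test(
    alignment: TrimmedAlignment,
    num_otu_grid: Sequence[int] = (4, 8, 16, 32),
    n_subsamples: int = 32,
    iss_c_provider: IssCTable | None = None,
    seed: int | None = 0,
) -> list[SaturationResult]:
    """Saturation test on NumOTU-subsampled alignments.

    For each NumOTU, ``n_subsamples`` random row subsets are drawn and the
    per-site entropies averaged; Iss is the mean relative to H_FSS at that
    NumOTU, its standard error is sd(per-site H) / (H_FSS * sqrt(n_sites)),
    and T = (Iss.c - Iss) / SE with DF = n_sites - 1.
    """
    provider = iss_c_provider or DEFAULT_ISS_C
    rng = np.random.default_rng(seed)
    freqs = observed_base_freqs(alignment)
    n_rows, n_sites = alignment.n_rows, alignment.n_sites
    results = []
    for num_otu in num_otu_grid:
        if num_otu > n_rows:
            raise ValueError(f"NumOTU={num_otu} exceeds {n_rows} rows")
        iss_c_sym = provider.get(num_otu, SYMMETRIC)
        iss_c_asym = provider.get(num_otu, ASYMMETRIC)
        hf = h_fss(num_otu, freqs, seed=seed)
        acc = np.zeros(n_sites)
        cnt = np.zeros(n_sites)
        for _ in range(n_subsamples):
            rows = rng.choice(n_rows, size=num_otu, replace=False)
            H, _ = per_site_entropy(alignment.subsample(rows))
            usable = ~np.isnan(H)
            acc[usable] += H[usable]
            cnt[usable] += 1
        with np.errstate(invalid="ignore"):
            Hbar = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        usable = ~np.isnan(Hbar)
        n_usable = int(usable.sum())
        if n_usable == 0 or hf == 0.0:
            raise ValueError("no usable sites for the saturation test")
        iss_value = float(np.nanmean(Hbar)) / hf
        sd = float(np.nanstd(Hbar, ddof=1)) if n_usable > 1 else 0.0
        se = sd / (hf * math.sqrt(n_usable))
        df = n_sites - 1
        t_sym, p_sym = _t_and_p(iss_value, iss_c_sym, se, df)
        t_asym, p_asym = _t_and_p(iss_value, iss_c_asym, se, df)
        results.append(
            SaturationResult(
                num_otu, iss_value, iss_c_sym, t_sym, df, p_sym,
                iss_c_asym, t_asym, p_asym, n_subsamples,
            )
        )
    return results


def results_table(results: Sequence[SaturationResult]) -> pd.DataFrame:
    """TSV-ready frame: NumOTU, Iss, Iss.c/T/DF/P for both topologies."""
    return pd.DataFrame(
        [
            {
                "NumOTU": r.num_otu,
                "Iss": round(r.iss, 3),
                "Iss.c_sym": round(r.iss_c_sym, 3),
                "T_sym": round(r.t_sym, 3),
                "DF": r.df,
                "P_sym": round(r.p_sym, 3),
                "Iss.c_asym": round(r.iss_c_asym, 3),
                "T_asym": round(r.t_asym, 3),
                "P_asym": round(r.p_asym, 3),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Calibration of Iss.c by simulation
# ---------------------------------------------------------------------------

def _balanced_topology(n: int) -> "TreeNode":
    from .njtree import TreeNode

    def build(labels):
        if len(labels) == 1:
            return TreeNode(name=labels[0])
        mid = len(labels) // 2
        return TreeNode(children=[build(labels[:mid]), build(labels[mid:])])

    return build([f"T{i+1}" for i in range(n)])


def _caterpillar_topology(n: int) -> "TreeNode":
    from .njtree import TreeNode

    node = TreeNode(children=[TreeNode(name="T1"), TreeNode(name="T2")])
    for i in range(2, n):
        node = TreeNode(children=[node, TreeNode(name=f"T{i+1}")])
    return node


class CalibrationError(RuntimeError):
    pass


def calibrate_iss_c(
    num_otu: int,
    topology: str = SYMMETRIC,
    depth_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0),
    reps: int = 24,
    seed: int | None = 0,
    seq_length: int = 600,
    kappa: float = 4.0,
    recovery_threshold: float = 0.95,
) -> float:
    """Simulated critical Iss: the Iss at which NJ recovery drops to 95%.

    Alignments are evolved on a fixed symmetric (balanced) or asymmetric
    (caterpillar) topology with every edge set to each grid depth; per depth
    the mean Iss and the fraction of replicates whose NJ tree matches the
    true topology are recorded.  Recovery is monotone-smoothed along the
    depth grid and the crossing at ``recovery_threshold`` is located by
    linear interpolation on Iss.
    """
    from .distance import distance_matrix
    from .njtree import SentinelDistanceError, Tree, nj
    from .simdata import decode, evolve, random_sequence

    if topology == SYMMETRIC:
        root = _balanced_topology(num_otu)
    elif topology == ASYMMETRIC:
        root = _caterpillar_topology(num_otu)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    uniform = np.full(4, 0.25)
    hf = h_fss(num_otu, uniform, seed=seed)
    true_splits = Tree(root).bipartitions()

    mean_iss = []
    recovery = []
    for depth in depth_grid:

        def set_lengths(node):
            for c in node.children:
                c.length = depth
                set_lengths(c)

        set_lengths(root)
        iss_vals = []
        recovered = 0
        for _ in range(reps):
            seqs: dict[str, str] = {}

            def descend(node, codes):
                for c in node.children:
                    child = evolve(codes, c.length, kappa, rng)
                    if c.is_leaf:
                        seqs[c.name] = decode(child)
                    else:
                        descend(c, child)

            descend(root, random_sequence(seq_length, uniform, rng))
            aln = TrimmedAlignment(
                (0, seq_length), [(name, name, s) for name, s in sorted(seqs.items())]
            )
            H, _ = per_site_entropy(aln)
            iss_vals.append(float(np.nanmean(H)) / hf)
            try:
                est = nj(distance_matrix(aln, min_overlap=10))
                if est.bipartitions() == true_splits:
                    recovered += 1
            except SentinelDistanceError:
                pass
        mean_iss.append(float(np.mean(iss_vals)))
        recovery.append(recovered / reps)

    # enforce non-increasing recovery along increasing depth before crossing
    rec = np.minimum.accumulate(np.asarray(recovery))
    iss_arr = np.asarray(mean_iss)
    if rec[0] < recovery_threshold:
        raise CalibrationError(
            "recovery below threshold at the shallowest depth; widen the grid downward"
        )
    below = np.nonzero(rec < recovery_threshold)[0]
    if below.size == 0:
        raise CalibrationError(
            "recovery never crosses the threshold; widen the grid upward"
        )
    k = int(below[0])
    r0, r1 = rec[k - 1], rec[k]
    w = (r0 - recovery_threshold) / (r0 - r1) if r0 != r1 else 0.5
    return float(iss_arr[k - 1] + w * (iss_arr[k] - iss_arr[k - 1]))
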