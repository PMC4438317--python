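"""Tetranucleotide-frequency genome binning with coverage refinement.

Long contigs (>= 3 kb by default) are profiled by canonical tetranucleotide
frequencies (136 reverse-complement-pooled classes), clustered by Ward-linkage
hierarchical agglomeration on Euclidean distances, with the bin count chosen
by silhouette maximization (non-metric MDS stress reported as an ordination
diagnostic). Bins are then refined by robust coverage statistics
(median ± 3×MAD) and optional taxonomy labels, simple internal-repeat
(chimera) flagging, core-gene completeness, and read-mapping relative
abundance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import median_abs_deviation
from sklearn.manifold import smacof
from sklearn.metrics import silhouette_score

from . import sequtils
from .containers import ContigSet

__all__ = [
    "ContigTooShortError", "TNFProfile", "BinAssignment", "OrdinationResult",
    "tnf_profile", "tnf_profiles", "cluster_contigs", "select_bin_count",
    "nmds", "refine_bins", "flag_chimeras", "estimate_completeness",
    "relative_abundance",
]


class ContigTooShortError(ValueError):
    """Raised when a contig is below the TNF length cutoff (skip signal)."""


def _build_canonical_map() -> tuple[np.ndarray, list[str]]:
    """Map each of the 256 tetranucleotides to one of 136 canonical classes
    (each 4-mer pooled with its reverse complement)."""
    comp = [3, 2, 1, 0]  # A<->T, C<->G on 0..3 codes
    class_of: dict[int, int] = {}
    names: list[str] = []
    mapping = np.empty(256, dtype=np.int64)
    for idx in range(256):
        digits = [(idx >> 6) & 3, (idx >> 4) & 3, (idx >> 2) & 3, idx & 3]
        rc = 0
        for d in reversed(digits):  # reverse order, complemented
            rc = rc * 4 + comp[d]
        canon = min(idx, rc)
        if canon not in class_of:
            class_of[canon] = len(names)
            names.append("".join("ACGT"[d] for d in (
                (canon >> 6) & 3, (canon >> 4) & 3, (canon >> 2) & 3, canon & 3)))
        mapping[idx] = class_of[canon]
    return mapping, names


_TNF_MAP, TNF_CLASS_NAMES = _build_canonical_map()
N_TNF_CLASSES = len(TNF_CLASS_NAMES)  # 136


@dataclass(frozen=True)
class TNFProfile:
    """Canonical tetranucleotide frequency vector of one contig."""

    contig_id: str
    vector: np.ndarray  # length 136, sums to 1


@dataclass
class BinAssignment:
    """Contig -> bin mapping (bin ids dense from 1) plus unbinned leftovers."""

    assignments: dict[str, int]
    n_bins: int
    unbinned: list[str] = field(default_factory=list)

    def members(self, bin_id: int) -> list[str]:
        return [c for c, b in self.assignments.items() if b == bin_id]

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[i] for i in ids])

    def summarize(
        self,
        contigs: ContigSet,
        completeness: Optional[dict[int, float]] = None,
    ) -> pd.DataFrame:
        """Per-bin summary: contig count, total bases, mean GC, mean coverage."""
        rows = []
        by_id = {c.id: c for c in contigs}
        for b in range(1, self.n_bins + 1):
            mem = [by_id[i] for i in self.members(b) if i in by_id]
            if not mem:
                continue
            covs = [c.coverage for c in mem if c.coverage is not None]
            rows.append({
                "bin": b,
                "n_contigs": len(mem),
                "total_bases": sum(c.length for c in mem),
                "gc_percent": 100.0 * float(np.mean(
                    [sequtils.gc_fraction(c.seq) for c in mem])),
                "mean_coverage": float(np.mean(covs)) if covs else np.nan,
                "completeness": (completeness or {}).get(b, np.nan),
            })
        return pd.DataFrame(rows)


@dataclass
class OrdinationResult:
    """2-D (or d-D) NMDS coordinates with Kruskal stress-1."""

    coords: np.ndarray
    stress: float


# ---------------------------------------------------------------------------
# TNF
# ---------------------------------------------------------------------------

def tnf_profile(seq: str, min_len: int = 3000, contig_id: str = "") -> TNFProfile:
    """Canonical TNF of one contig; contigs under ``min_len`` are rejected.

    All length-4 ACGT windows are counted, pooled with reverse complements
    into 136 classes, and normalized to frequencies.
    """
    if len(seq) < min_len:
        raise ContigTooShortError(
            f"contig length {len(seq)} < min_len {min_len}")
    codes = sequtils.encode(seq)
    valid = codes < 4
    idx4 = (codes[:-3].astype(np.int64) * 64 + codes[1:-2] * 16
            + codes[2:-1] * 4 + codes[3:])
    wvalid = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    counts = np.bincount(idx4[wvalid], minlength=256)
    prof = np.zeros(N_TNF_CLASSES)
    np.add.at(prof, _TNF_MAP, counts)
    total = prof.sum()
    if total == 0:
        raise ContigTooShortError("contig has no valid tetranucleotide window")
    return TNFProfile(contig_id=contig_id, vector=prof / total)


def tnf_profiles(contigs: ContigSet, min_len: int = 3000) -> tuple[list[str], np.ndarray]:
    """Profiles for all contigs >= min_len; returns (ids, matrix), shorter
    contigs silently skipped."""
    ids, rows = [], []
    for c in contigs:
        try:
            p = tnf_profile(c.seq, min_len=min_len, contig_id=c.id)
        except ContigTooShortError:
            continue
        ids.append(c.id)
        rows.append(p.vector)
    return ids, (np.vstack(rows) if rows else np.empty((0, N_TNF_CLASSES)))


# ---------------------------------------------------------------------------
# clustering / ordination
# ---------------------------------------------------------------------------

def _dense_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids densely from 1 in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in seen:
            seen[v] = len(seen) + 1
        out[i] = seen[v]
    return out


def cluster_contigs(ids: Sequence[str], profiles: np.ndarray, n_bins: int) -> BinAssignment:
    """Ward/Euclidean agglomerative clustering of TNF profiles cut at
    ``n_bins`` clusters."""
    n = len(ids)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError("n_bins cannot exceed the number of profiles")
    if n == 0:
        return BinAssignment({}, 0)
    if n_bins == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(profiles, method="ward")
        labels = _dense_labels(fcluster(Z, t=n_bins, criterion="maxclust"))
    return BinAssignment(dict(zip(ids, (int(b) for b in labels))),
                         int(labels.max()))


def nmds(
    dist: np.ndarray,
    dims: int = 2,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorization with isotonic regression on
    dissimilarity ranks; returns coordinates and Kruskal stress-1."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    coords, stress = smacof(
        D,
        metric=False,
        n_components=dims,
        init=init,
        n_init=1 if init is not None else 4,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    return OrdinationResult(coords=coords, stress=float(stress))


def select_bin_count(
    ids: Sequence[str],
    profiles: np.ndarray,
    k_min: int = 2,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the bin count by mean silhouette width over Ward tree cuts.

    Returns (chosen k, diagnostics frame with one row per k: silhouette and
    the 2-D NMDS stress of the TNF distance matrix, a k-independent
    ordination diagnostic). Ties go to the smaller k.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 profiles to select a bin count")
    if k_max is None:
        k_max = min(20, n - 1)
    if not 2 <= k_min < k_max <= n - 1:
        raise ValueError("require 2 <= k_min < k_max <= n-1")
    Z = linkage(profiles, method="ward")
    stress = nmds(squareform(pdist(profiles)), dims=2, seed=seed).stress
    rows = []
    for k in range(k_min, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            sil = np.nan
        else:
            sil = float(silhouette_score(profiles, labels))
        rows.append({"k": k, "silhouette": sil, "nmds_stress": stress})
    diag = pd.DataFrame(rows)
    chosen = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return chosen, diag


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def refine_bins(
    assignment: BinAssignment,
    ids: Sequence[str],
    profiles: np.ndarray,
    coverages: dict[str, float],
    taxonomy: Optional[dict[str, str]] = None,
    mad_factor: float = 3.0,
) -> BinAssignment:
    """Move coverage/taxonomy-divergent contigs to the best compatible bin.

    A contig is divergent if its coverage deviates from its bin's median by
    more than ``mad_factor`` x MAD, or its taxonomy label conflicts with the
    bin's majority label. Divergent contigs are reassigned to the
    nearest-bin-mean-TNF bin among bins with compatible coverage and
    taxonomy. A coverage-only flag moves a contig only when some compatible
    bin is a strictly better TNF match than its current bin (a composition-
    consistent coverage outlier stays put); a taxonomy conflict forces a
    move, to unbinned if no bin qualifies. Bin statistics are computed on
    the input assignment, so the result is order-independent.
    """
    taxonomy = taxonomy or {}
    prof_of = {i: profiles[j] for j, i in enumerate(ids)}
    bins = sorted({b for b in assignment.assignments.values()})
    stats: dict[int, dict] = {}
    for b in bins:
        mem = assignment.members(b)
        covs = np.array([coverages[m] for m in mem], dtype=float)
        labels = [taxonomy.get(m) for m in mem if taxonomy.get(m) is not None]
        majority = None
        if labels:
            vals, cnts = np.unique(labels, return_counts=True)
            majority = sorted(vals[cnts == cnts.max()])[0]
        mean_prof = (
            np.mean([prof_of[m] for m in mem if m in prof_of], axis=0)
            if any(m in prof_of for m in mem) else None
        )
        stats[b] = {
            "median": float(np.median(covs)),
            "mad": float(median_abs_deviation(covs)),
            "majority": majority,
            "mean_prof": mean_prof,
        }

    def cov_ok(b: int, cov: float) -> bool:
        return abs(cov - stats[b]["median"]) <= mad_factor * stats[b]["mad"]

    def tax_ok(b: int, label: Optional[str]) -> bool:
        return (label is None or stats[b]["majority"] is None
                or label == stats[b]["majority"])

    new = dict(assignment.assignments)
    unbinned = list(assignment.unbinned)
    for cid in assignment.assignments:  # insertion order: deterministic
        b = assignment.assignments[cid]
        cov = coverages[cid]
        label = taxonomy.get(cid)
        tax_conflict = not tax_ok(b, label)
        if cov_ok(b, cov) and not tax_conflict:
            continue
        candidates = [
            b2 for b2 in bins
            if b2 != b and cov_ok(b2, cov) and tax_ok(b2, label)
            and stats[b2]["mean_prof"] is not None
        ]
        best, best_d = None, np.inf
        if candidates and cid in prof_of:
            for b2 in candidates:
                d = float(np.linalg.norm(prof_of[cid] - stats[b2]["mean_prof"]))
                if d < best_d:
                    best, best_d = b2, d
        if tax_conflict:
            if best is not None:
                new[cid] = best
            else:
                del new[cid]
                unbinned.append(cid)
        else:  # coverage-only flag: move only to a strictly better TNF fit
            d_own = (
                float(np.linalg.norm(prof_of[cid] - stats[b]["mean_prof"]))
                if cid in prof_of and stats[b]["mean_prof"] is not None
                else np.inf
            )
            if best is not None and best_d < d_own:
                new[cid] = best
    return BinAssignment(new, assignment.n_bins, unbinned)


# ---------------------------------------------------------------------------
# chimera flagging / completeness / abundance
# ---------------------------------------------------------------------------

def flag_chimeras(
    contigs: ContigSet,
    window: int = 500,
    min_identity: float = 0.98,
) -> list[tuple[str, tuple[int, int]]]:
    """Flag contigs containing an internal duplicated block.

    Non-overlapping ``window``-bp windows of each contig are compared
    pairwise (both orientations); a pair at >= ``min_identity`` flags the
    contig with the span covering both copies. A simplified stand-in for
    self-alignment chimera screening: most real chimeras arise at repeats.
    """
    max_ed = int((1.0 - min_identity) * window)
    flags: list[tuple[str, tuple[int, int]]] = []
    for c in contigs:
        wins = [c.seq[i:i + window]
                for i in range(0, c.length - window + 1, window)]
        found = None
        for i in range(len(wins)):
            for j in range(i + 1, len(wins)):
                for cand in (wins[j], sequtils.revcomp(wins[j])):
                    ed = edlib.align(wins[i], cand, mode="NW", task="distance",
                                     k=max_ed)["editDistance"]
                    if ed >= 0:
                        found = (i * window, j * window + window)
                        break
                if found:
                    break
            if found:
                break
        if found:
            flags.append((c.id, found))
    return flags


def estimate_completeness(bin_genes, core_gene_set) -> float:
    """Fraction of a core-gene set present in the bin (set semantics)."""
    core = set(core_gene_set)
    if not core:
        raise ValueError("core gene set must be non-empty")
    return len(set(bin_genes) & core) / len(core)


def relative_abundance(
    mapping: pd.DataFrame,
    assignment: BinAssignment,
) -> pd.Series:
    """Per-bin read fractions from a read -> contig mapping table.

    ``mapping`` needs columns ``read_id`` and ``reference`` (None/NaN for
    unmapped). Reads on unbinned contigs count toward ``unmapped`` so that
    bin fractions + unmapped sum to 1.
    """
    total = len(mapping)
    if total == 0:
        raise ValueError("empty mapping table")
    counts = {b: 0 for b in range(1, assignment.n_bins + 1)}
    unmapped = 0
    contig_bin = assignment.assignments
    for ref in mapping["reference"]:
        b = contig_bin.get(ref) if isinstance(ref, str) else None
        if b is None:
            unmapped += 1
        else:
            counts[b] += 1
    frac = {f"bin{b}": c / total for b, c in counts.items()}
    frac["unmapped"] = unmapped / total
    return pd.Series(frac)
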