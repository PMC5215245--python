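"""Cross-pipeline comparison of rank-level abundance profiles.

Builds a pipelines x taxa relative-abundance matrix (unclassified reads
excluded, rows renormalized), clusters pipelines by average-linkage
(UPGMA) on Euclidean distances, ordinates them by PCoA on Bray-Curtis
dissimilarities, and compares pipeline groups with a Mann-Whitney-Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .evaluate import UNCLASSIFIED_KEY, AbundanceProfile
from .exceptions import InputError

#: Combined sample size up to which the rank-sum test uses exact null
#: enumeration (tie-free data only).
EXACT_RANKSUM_MAX_N = 12


def build_profile_matrix(profiles: dict[str, AbundanceProfile]) -> pd.DataFrame:
    """Pipelines x taxa relative-abundance matrix.

    Drops the unclassified pool from every profile and renormalizes each
    row to sum to 1; columns are the union of taxa over all pipelines,
    with absent taxa at 0.  A profile with no classified reads cannot form
    a row.
    """
    if not profiles:
        raise InputError("no profiles given")
    ranks = {p.rank for p in profiles.values()}
    if len(ranks) != 1:
        raise InputError(f"profiles are at mixed ranks: {sorted(ranks)}")
    rows = {}
    for name, profile in profiles.items():
        counts = profile.classified_counts()
        total = sum(counts.values())
        if total == 0:
            raise InputError(f"profile {name!r} is entirely unclassified")
        rows[name] = {k: v / total for k, v in counts.items()}
    taxa = sorted({t for r in rows.values() for t in r}, key=str)
    mat = pd.DataFrame(
        [[rows[name].get(t, 0.0) for t in taxa] for name in sorted(rows)],
        index=sorted(rows),
        columns=taxa,
    )
    return mat


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix; branch lengths are parent-minus-child
    merge heights (leaves at height 0)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    parts = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        heights[node] = float(h)
        la = f"{parts[a]}:{h - heights[a]:.10g}"
        lb = f"{parts[b]}:{h - heights[b]:.10g}"
        parts[node] = f"({la},{lb})"
    return parts[n + len(Z) - 1] + ";"


def euclidean_upgma(matrix: pd.DataFrame) -> str:
    """UPGMA dendrogram of pipelines on Euclidean distances, as newick.

    Rows are sorted by label before clustering so the result is invariant
    to input row order (deterministic tie-break).
    """
    if len(matrix) < 2:
        raise InputError("clustering needs at least 2 pipelines")
    mat = matrix.sort_index()
    Z = linkage(pdist(mat.to_numpy(), metric="euclidean"), method="average")
    return _linkage_to_newick(Z, list(mat.index))


def bray_curtis_matrix(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between pipeline rows.

    d(u, v) = 1 - 2 * sum(min(u_i, v_i)) / (sum(u) + sum(v)), in [0, 1]
    for non-negative rows.
    """
    if (matrix.to_numpy() < 0).any():
        raise InputError("Bray-Curtis requires non-negative abundances")
    dm = squareform(pdist(matrix.to_numpy(), metric="braycurtis"))
    return DistanceMatrix(dm, ids=list(matrix.index))


@dataclass
class PCoAResult:
    """Classical-scaling ordination kept to positive-eigenvalue axes."""

    coordinates: pd.DataFrame          # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray            # positive eigenvalues, descending
    proportion_explained: np.ndarray   # fraction of positive-eigenvalue variance
    negative_eigenvalue_magnitude: float  # |sum of dropped negative eigenvalues|


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Principal Coordinates Analysis of a distance matrix.

    Negative eigenvalues (non-Euclidean distortion) are dropped, not
    corrected; their summed magnitude is reported so users can judge how
    Euclidean the input was.
    """
    if dist.shape[0] < 2:
        raise InputError("PCoA needs at least 2 items")
    res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    tol = 1e-10 * max(1.0, float(np.abs(eig).max()))
    pos = eig > tol
    neg_mag = float(-eig[eig < -tol].sum()) if (eig < -tol).any() else 0.0
    eigvals = eig[pos]
    coords = res.samples.to_numpy()[:, pos]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    total = eigvals.sum() if eigvals.size else 1.0
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals / total,
        negative_eigenvalue_magnitude=neg_mag,
    )


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test between two value groups.

    Uses exact null enumeration when the combined sample size is at most
    12 and the data are tie-free; otherwise the tie-corrected,
    continuity-corrected normal approximation.  Returns (U statistic of
    group_a, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_RANKSUM_MAX_N and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def top_n_taxa(profile: AbundanceProfile, n: int) -> AbundanceProfile:
    """Keep the n most abundant classified taxa, pool the rest into "other".

    The unclassified pool stays its own key; ties at the cutoff break by
    taxon id; total counts are conserved.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    classified = profile.classified_counts()
    order = sorted(classified, key=lambda t: (-classified[t], str(t)))
    kept = order[:n]
    out = {t: classified[t] for t in kept}
    out["other"] = sum(classified[t] for t in order[n:])
    if UNCLASSIFIED_KEY in profile.counts:
        out[UNCLASSIFIED_KEY] = profile.counts[UNCLASSIFIED_KEY]
    result = AbundanceProfile(out, profile.rank)
    # AbundanceProfile drops zero counts; reinstate an explicit empty
    # "other" bucket so pooling is always visible in exports.
    if "other" not in result.counts:
        result.counts["other"] = 0
    return result
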