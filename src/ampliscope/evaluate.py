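"""Scoring one pipeline's taxonomic assignments against ground truth.

Confusion semantics at a fixed rank (family or genus): a read is a true
positive when its predicted rank-level taxon equals the rank-level taxon of
the genome it was simulated from; a false positive when the prediction
differs; a false negative when the pipeline discarded it or called it
unclassified (including calls coarser than the evaluated rank).  A
singleton rule mirrors common pipeline guidelines: taxa supported by a
single read are removed from the final results and their reads recounted
as false negatives.

Richness (Chao1 + signed error percent), diversity (Shannon, inverse
Simpson) and partition-agreement metrics (NMI, AMI, 1-NID) operate on
rank-level abundance profiles / read partitions, after an optional
taxonomic-merging step that pools OTUs assigned to the same taxon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha
from sklearn.metrics import adjusted_mutual_info_score, normalized_mutual_info_score

from .exceptions import DataError, InputError
from .taxonomy import CLASSIFIED, DISCARDED, UNCLASSIFIED, TaxonomyTree, normalize_assignments

logger = logging.getLogger(__name__)

#: Profile key pooling all reads/OTUs without a rank-level call.
UNCLASSIFIED_KEY = "unclassified"


@dataclass(frozen=True)
class ConfusionCounts:
    """Read-level confusion counts at one rank; TP+FP+FN = n_reads."""

    tp: int
    fp: int
    fn: int
    rank: str

    @property
    def n_reads(self) -> int:
        return self.tp + self.fp + self.fn


@dataclass
class AbundanceProfile:
    """Taxon -> read count at a fixed rank.

    Keys are taxids plus the special :data:`UNCLASSIFIED_KEY`; richness and
    diversity computations always exclude the unclassified pool.
    """

    counts: dict = field(default_factory=dict)
    rank: str = "family"

    def __post_init__(self):
        self.counts = {k: int(v) for k, v in self.counts.items() if v > 0}
        if any(v < 0 for v in self.counts.values()):
            raise InputError("negative abundance")

    def total(self, include_unclassified: bool = True) -> int:
        return sum(
            v for k, v in self.counts.items()
            if include_unclassified or k != UNCLASSIFIED_KEY
        )

    def classified_counts(self) -> dict:
        return {k: v for k, v in self.counts.items() if k != UNCLASSIFIED_KEY}

    @property
    def observed_richness(self) -> int:
        return len(self.classified_counts())


# -- assignment-table plumbing --------------------------------------------


def _truth_rank_taxa(truth: pd.DataFrame, tree: TaxonomyTree, rank: str) -> pd.Series:
    """Project truth taxids onto *rank*; truth must always resolve."""
    mapping = {}
    for t in truth["taxid"].unique():
        anc = tree.ancestor_at_rank(int(t), rank)
        if anc is None:
            raise DataError(f"ground-truth taxid {t} has no ancestor at rank {rank!r}")
        mapping[t] = anc
    return truth["taxid"].map(mapping)


def align_to_truth(truth: pd.DataFrame, pred: pd.DataFrame) -> pd.DataFrame:
    """Reindex a prediction table onto the truth read set.

    Reads absent from the prediction are injected as discarded; reads
    unknown to the truth are an error.
    """
    if pred["read_id"].duplicated().any():
        raise InputError("duplicate read_id in assignment table")
    unknown = set(pred["read_id"]) - set(truth["read_id"])
    if unknown:
        raise InputError(f"{len(unknown)} predicted read_ids missing from truth (e.g. {sorted(unknown)[:3]})")
    merged = truth[["read_id"]].merge(pred, on="read_id", how="left")
    missing = merged["status"].isna()
    merged.loc[missing, "status"] = DISCARDED
    return merged


def drop_singleton_taxa(pred_norm: pd.DataFrame) -> pd.DataFrame:
    """Remove taxa supported by exactly one classified read.

    Their reads become unclassified (counted as false negatives downstream),
    matching the guideline of discarding taxonomic singletons from final
    results.
    """
    out = pred_norm.copy()
    classified = out["status"] == CLASSIFIED
    counts = out.loc[classified, "taxid"].value_counts()
    singles = set(counts[counts == 1].index)
    if singles:
        hit = classified & out["taxid"].isin(singles)
        out.loc[hit, "status"] = UNCLASSIFIED
        out.loc[hit, "taxid"] = pd.NA
    return out


def confusion_at_rank(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    tree: TaxonomyTree,
    rank: str,
    drop_singletons: bool = False,
) -> ConfusionCounts:
    """Count TP/FP/FN for one pipeline at one rank.

    *pred* may carry assignments at any rank (or names); it is normalized
    to *rank* first.  With *drop_singletons*, single-read taxa are removed
    before counting and their reads scored as false negatives.
    """
    truth_rank = _truth_rank_taxa(truth, tree, rank)
    pred_norm = normalize_assignments(tree, align_to_truth(truth, pred), rank)
    if drop_singletons:
        pred_norm = drop_singleton_taxa(pred_norm)
    # align_to_truth guarantees row order == truth row order
    classified = (pred_norm["status"] == CLASSIFIED).to_numpy()
    pred_taxa = pred_norm["taxid"].to_numpy()
    truth_taxa = truth_rank.to_numpy()
    idx = np.flatnonzero(classified)
    correct = np.asarray(pred_taxa[idx] == truth_taxa[idx], dtype=bool)
    tp = int(correct.sum())
    fp = int(classified.sum()) - tp
    fn = len(truth) - tp - fp
    return ConfusionCounts(tp, fp, fn, rank)


def f_measure(counts: ConfusionCounts) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R).

    Zero denominators (including TP = 0) yield 0 by convention.
    """
    if counts.n_reads <= 0:
        raise InputError("confusion counts cover no reads")
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


# -- profiles --------------------------------------------------------------


def profile_from_assignments(pred_norm: pd.DataFrame, rank: str) -> AbundanceProfile:
    """Rank-level abundance profile of a normalized assignment table.

    Unclassified reads pool under :data:`UNCLASSIFIED_KEY`; discarded reads
    do not contribute (they never reach a pipeline's final table).
    """
    counts: dict = {}
    classified = pred_norm[pred_norm["status"] == CLASSIFIED]
    for taxid, n in classified["taxid"].value_counts().items():
        counts[taxid] = int(n)
    n_uncl = int((pred_norm["status"] == UNCLASSIFIED).sum())
    if n_uncl:
        counts[UNCLASSIFIED_KEY] = n_uncl
    return AbundanceProfile(counts, rank)


def truth_profile(truth: pd.DataFrame, tree: TaxonomyTree, rank: str) -> AbundanceProfile:
    taxa = _truth_rank_taxa(truth, tree, rank)
    return AbundanceProfile(dict(taxa.value_counts()), rank)


def merge_otus(otus: pd.DataFrame, tree: TaxonomyTree, rank: str) -> AbundanceProfile:
    """Taxonomic merging: pool all OTUs assigned to the same rank-level taxon.

    *otus* columns: ``otu_id``, ``size``, ``taxid`` (taxid may be NA, a
    name, or the string "unclassified" for unassigned OTUs, which pool
    under the unclassified key).
    """
    counts: dict = {}
    for row in otus.itertuples():
        size = int(row.size)
        if size < 1:
            raise InputError(f"OTU {row.otu_id} has size {size}")
        taxon = row.taxid
        key: object = UNCLASSIFIED_KEY
        if not (pd.isna(taxon) or str(taxon).lower() in ("unclassified", "na")):
            if isinstance(taxon, str) and not taxon.lstrip("-").isdigit():
                taxid = tree.resolve_name(taxon)
            else:
                taxid = int(taxon)
            anc = tree.ancestor_at_rank(taxid, rank)
            key = anc if anc is not None else UNCLASSIFIED_KEY
        counts[key] = counts.get(key, 0) + size
    return AbundanceProfile(counts, rank)


# -- richness & diversity --------------------------------------------------


def chao1(profile: AbundanceProfile, bias_corrected: bool = True) -> float:
    """Abundance-based richness estimate from singleton/doubleton counts.

    Default is the bias-corrected form S_obs + f1(f1-1)/(2(f2+1)); the
    classic f1^2/(2 f2) form is available behind the flag.  The
    unclassified pool never counts as a taxon.
    """
    counts = list(profile.classified_counts().values())
    if not counts:
        raise InputError("Chao1 of an empty profile is undefined")
    return float(_alpha.chao1(np.asarray(counts, dtype=int), bias_corrected=bias_corrected))


def chao1_error_percent(estimate: float, truth_richness: float) -> float:
    """Signed relative deviation of estimated from true richness, x100."""
    if truth_richness <= 0:
        raise InputError("truth richness must be positive")
    return (estimate - truth_richness) / truth_richness * 100.0


def diversity_indices(profile: AbundanceProfile) -> tuple[float, float]:
    """(Shannon with natural log, inverse Simpson) of the classified pool."""
    counts = np.asarray(list(profile.classified_counts().values()), dtype=float)
    if counts.size == 0:
        raise InputError("diversity of an empty profile is undefined")
    shannon = float(_alpha.shannon(counts.astype(int), base=math.e))
    inv_simpson = float(_alpha.enspie(counts.astype(int)))
    return shannon, inv_simpson


# -- partition agreement ---------------------------------------------------


def partition_agreement(truth_labels, pred_labels) -> tuple[float, float, float]:
    """(NMI, AMI, 1-NID) between two read partitions.

    Both NMI and NID are normalized by max(H_U, H_V), under which
    1 - NID = I/max(H_U, H_V) = NMI; both are reported for interface
    compatibility.  AMI subtracts the permutation-model expectation of I
    and is clamped at 0.  Degenerate cases: both partitions a single
    shared cluster -> all 1; a single cluster on one side only -> all 0.
    """
    u = list(truth_labels)
    v = list(pred_labels)
    if len(u) != len(v):
        raise InputError(f"label vectors differ in length ({len(u)} vs {len(v)})")
    if len(u) < 2:
        raise InputError("partition agreement needs at least 2 items")
    ku, kv = len(set(u)), len(set(v))
    if ku == 1 and kv == 1:
        return 1.0, 1.0, 1.0
    if ku == 1 or kv == 1:
        logger.info("one-sided single-cluster partition; agreement defined as 0")
        return 0.0, 0.0, 0.0
    # encode labels to ints for sklearn
    eu = pd.factorize(pd.Series(u))[0]
    ev = pd.factorize(pd.Series(v))[0]
    nmi = float(normalized_mutual_info_score(eu, ev, average_method="max"))
    ami = float(adjusted_mutual_info_score(eu, ev, average_method="max"))
    return nmi, max(0.0, ami), nmi


def partition_labels(
    truth: pd.DataFrame,
    pred_norm: pd.DataFrame,
    tree: TaxonomyTree,
    rank: str,
) -> tuple[list, list]:
    """Per-read (truth, predicted) rank-level partitions.

    Discarded reads are excluded from both partitions; unclassified reads
    form one dedicated cluster on the predicted side, so heavy unclassified
    rates penalize agreement.
    """
    truth_rank = _truth_rank_taxa(truth, tree, rank).to_numpy()
    status = pred_norm["status"].to_numpy()
    taxa = pred_norm["taxid"].to_numpy()
    keep = status != DISCARDED
    u = list(truth_rank[keep])
    v = [
        taxa[i] if status[i] == CLASSIFIED else UNCLASSIFIED_KEY
        for i in np.flatnonzero(keep)
    ]
    return u, v


# -- one-call report -------------------------------------------------------

METRICS = (
    "precision", "recall", "f_measure",
    "chao1", "chao1_error_percent", "shannon", "inverse_simpson",
    "nmi", "ami", "one_minus_nid",
)


def evaluate_pipeline(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    tree: TaxonomyTree,
    ranks: tuple[str, ...] = ("family", "genus"),
    drop_singletons: bool = True,
    chao1_bias_corrected: bool = True,
    strict_names: bool = False,
    dataset: str = "dataset",
    pipeline: str = "pipeline",
) -> pd.DataFrame:
    """Full metric battery for one pipeline, as a tidy table.

    Columns: dataset, pipeline, rank, metric, value.  The ground-truth
    richness used for the Chao1 error is the number of distinct rank-level
    taxa among the dataset's truth reads (equals the design richness
    whenever every designed taxon amplified).
    """
    rows = []
    aligned = align_to_truth(truth, pred)
    for rank in ranks:
        pred_norm = normalize_assignments(tree, aligned, rank, strict=strict_names)
        if drop_singletons:
            pred_norm = drop_singleton_taxa(pred_norm)
        cc = confusion_at_rank(truth, pred_norm, tree, rank, drop_singletons=False)
        p, r, f = f_measure(cc)
        values = {"precision": p, "recall": r, "f_measure": f}

        profile = profile_from_assignments(pred_norm, rank)
        t_profile = truth_profile(truth, tree, rank)
        if profile.observed_richness:
            est = chao1(profile, bias_corrected=chao1_bias_corrected)
            values["chao1"] = est
            values["chao1_error_percent"] = chao1_error_percent(est, t_profile.observed_richness)
            values["shannon"], values["inverse_simpson"] = diversity_indices(profile)
        else:
            logger.warning("pipeline %s has no classified reads at rank %s", pipeline, rank)
            for m in ("chao1", "chao1_error_percent", "shannon", "inverse_simpson"):
                values[m] = float("nan")

        u, v = partition_labels(truth, pred_norm, tree, rank)
        if len(u) >= 2:
            values["nmi"], values["ami"], values["one_minus_nid"] = partition_agreement(u, v)
        else:
            values["nmi"] = values["ami"] = values["one_minus_nid"] = float("nan")

        for metric in METRICS:
            rows.append((dataset, pipeline, rank, metric, values[metric]))
    return pd.DataFrame(rows, columns=["dataset", "pipeline", "rank", "metric", "value"])
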