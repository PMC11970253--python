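"""Two-stage hierarchical subtyping of non-diabetic samples.

Stage 1 clusters sample embeddings with average-linkage hierarchical
clustering on 1 - cosine distance into three groups named Normal / Pre_I
/ Pre_II by increasing fraction of clinically IGR members. Stage 2
re-clusters Pre_I into two and Pre_II into three sub-groups, named a/b(/c)
by ascending mean glucose of their members, producing the fixed six-label
taxonomy. New samples are assigned to the subtype with the highest mean
cosine similarity to its reference members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .types import DayProfile, SampleEmbedding

__all__ = [
    "TAXONOMY",
    "ReferenceSample",
    "SubtypeReference",
    "SubtypeAssignment",
    "fit_reference",
    "assign_subtype",
    "median_profile",
]

log = logging.getLogger(__name__)

TAXONOMY = ("Normal", "Pre_Ia", "Pre_Ib", "Pre_IIa", "Pre_IIb", "Pre_IIc")


@dataclass
class ReferenceSample:
    embedding: SampleEmbedding
    clinical_label: str                    # "NGT" or "IGR"
    days: list[DayProfile] = field(default_factory=list)

    @property
    def mean_glucose(self) -> float:
        if not self.days:
            return float("nan")
        vals = np.concatenate([d.values[d.present_mask] for d in self.days])
        return float(vals.mean()) if vals.size else float("nan")


@dataclass
class SubtypeReference:
    samples: list[ReferenceSample]
    partition: dict[str, list[int]]        # subtype -> indices into samples
    linkage_method: str
    median_profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def members(self, subtype: str) -> list[ReferenceSample]:
        return [self.samples[i] for i in self.partition[subtype]]

    def subtype_of(self, index: int) -> str:
        for t, idx in self.partition.items():
            if index in idx:
                return t
        raise KeyError(index)


@dataclass
class SubtypeAssignment:
    subject_id: str
    subtype: str
    scores: dict[str, float]

    def __post_init__(self):
        best = max(self.scores.values())
        if not np.isclose(self.scores[self.subtype], best):
            raise ValueError("assigned subtype must attain the maximal score")


def _cosine_linkage(vectors: np.ndarray, method: str) -> np.ndarray:
    d = pdist(vectors, metric="cosine")  # 1 - cosine similarity
    if np.allclose(d, 0.0, atol=1e-12):
        raise ValueError("all embeddings identical: cosine clustering is degenerate")
    return linkage(d, method=method)


def _cut(vectors: np.ndarray, n_clusters: int, method: str) -> np.ndarray:
    z = _cosine_linkage(vectors, method)
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    if len(np.unique(labels)) != n_clusters:
        raise ValueError(
            f"hierarchical cut produced {len(np.unique(labels))} clusters, wanted {n_clusters}"
        )
    return labels


def fit_reference(
    samples: list[ReferenceSample],
    linkage_method: str = "average",
) -> SubtypeReference:
    """Fit the six-subtype reference from labeled NGT/IGR sample embeddings."""
    if len(samples) < 6:
        raise ValueError("need at least 6 samples to fit six subtypes")
    vectors = np.stack([s.embedding.vector for s in samples])

    stage1 = _cut(vectors, 3, linkage_method)
    clusters = {}
    for c in np.unique(stage1):
        idx = np.flatnonzero(stage1 == c)
        igr_frac = np.mean([samples[i].clinical_label == "IGR" for i in idx])
        clusters[c] = (igr_frac, idx)
    by_igr = sorted(clusters.values(), key=lambda t: (t[0], t[1][0]))
    stage1_named = {"Normal": by_igr[0][1], "Pre_I": by_igr[1][1], "Pre_II": by_igr[2][1]}

    partition: dict[str, list[int]] = {"Normal": list(map(int, stage1_named["Normal"]))}
    for parent, n_sub, names in (
        ("Pre_I", 2, ("Pre_Ia", "Pre_Ib")),
        ("Pre_II", 3, ("Pre_IIa", "Pre_IIb", "Pre_IIc")),
    ):
        idx = stage1_named[parent]
        if len(idx) < n_sub:
            raise ValueError(
                f"cluster {parent} has {len(idx)} member(s); cannot split into {n_sub}"
            )
        sub = _cut(vectors[idx], n_sub, linkage_method)
        groups = [idx[np.flatnonzero(sub == c)] for c in np.unique(sub)]
        # deterministic a/b/c naming by ascending mean glucose (fall back to
        # embedding-norm order when day profiles were not provided)
        def sort_key(g):
            mg = np.nanmean([samples[i].mean_glucose for i in g])
            return mg if np.isfinite(mg) else float(np.linalg.norm(vectors[g].mean(axis=0)))

        groups.sort(key=sort_key)
        for name, g in zip(names, groups):
            partition[name] = list(map(int, g))

    ref = SubtypeReference(samples, partition, linkage_method)
    for t in TAXONOMY:
        if not ref.partition[t]:
            raise ValueError(f"subtype {t} is empty after fitting")
        try:
            ref.median_profiles[t] = median_profile(ref, t)
        except ValueError:
            pass  # no day profiles attached; median profile optional
    return ref


def assign_subtype(
    sample: SampleEmbedding,
    ref: SubtypeReference,
    use_abs: bool = True,
) -> SubtypeAssignment:
    """argmax over subtypes of the mean cosine similarity to reference members.

    ``use_abs`` applies the absolute value to the summed similarity before
    normalizing (as the assignment rule is printed); disable to rank by the
    signed mean.
    """
    v = np.asarray(sample.vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-norm sample embedding")
    scores = {}
    for t in TAXONOMY:
        members = ref.members(t)
        sims = []
        for m in members:
            u = m.embedding.vector
            nu = np.linalg.norm(u)
            if nu == 0:
                raise ValueError("zero-norm reference embedding")
            sims.append(float(v @ u / (norm * nu)))
        total = float(np.sum(sims))
        scores[t] = (abs(total) if use_abs else total) / len(members)
    best = max(scores.values())
    winners = [t for t in TAXONOMY if np.isclose(scores[t], best)]
    if len(winners) > 1:
        log.warning("subtype tie for %s among %s; keeping %s",
                    sample.subject_id, winners, winners[0])
    return SubtypeAssignment(sample.subject_id, winners[0], scores)


def median_profile(ref: SubtypeReference, subtype: str) -> np.ndarray:
    """Slot-wise median glucose over all member days (present slots only)."""
    members = ref.members(subtype)
    if not members:
        raise ValueError(f"subtype {subtype} is empty")
    days = [d for m in members for d in m.days]
    if not days:
        raise ValueError(f"subtype {subtype} has no day profiles")
    stacked = np.stack([d.values for d in days])
    with np.errstate(all="ignore"):
        return np.nanmedian(stacked, axis=0)
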