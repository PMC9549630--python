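"""Hierarchical clustering of a QPP ensemble and cross-group matching.

QPPs detected from different seeds often converge onto the same underlying
pattern (possibly time-shifted).  Average-linkage hierarchical clustering on
the distance 1 - similarity groups them; "robust" clusters must be large
(>= 20 members), recur in the series (> 10 occurrences of the cluster's
pattern) and be present in most subjects.  Each cluster is summarised by its
highest-occurrence member, the representative QPP (rQPP).  Anti-correlated
patterns are deliberately NOT folded together: a network-activation pattern
and its mirror image are distinct brain states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .detect import QPP, pattern_similarity
from .preprocess import Bounds

logger = logging.getLogger(__name__)


@dataclass
class QPPCluster:
    member_ids: list[int]          # indices into the ensemble
    size: int
    n_occurrences: int             # occurrence count of the representative QPP
    subject_coverage: float        # fraction of members occurring in >=80% of subjects
    robust: bool
    representative_id: int


@dataclass
class ClusterMatch:
    cluster_a: int
    cluster_b: int
    spatial_corr: float
    best_shift: int
    matched: bool                  # strictly > match threshold


def qpp_similarity(qpp_a: QPP | np.ndarray, qpp_b: QPP | np.ndarray,
                   max_shift: int) -> tuple[float, int]:
    """Max-over-shift space-time correlation between two QPP patterns."""
    a = qpp_a.pattern if isinstance(qpp_a, QPP) else qpp_a
    b = qpp_b.pattern if isinstance(qpp_b, QPP) else qpp_b
    return pattern_similarity(a, b, max_shift)


def _member_subject_fraction(qpp: QPP, subject_bounds: list[Bounds]) -> float:
    """Fraction of subjects in whose frame range this QPP occurs >= once."""
    if not subject_bounds:
        return 0.0
    occ = np.asarray(qpp.occurrences)
    hit = sum(1 for _, start, end in subject_bounds
              if np.any((occ >= start) & (occ < end)))
    return hit / len(subject_bounds)


def cluster_qpps(ensemble: list[QPP], subject_bounds: list[Bounds],
                 linkage_cut: float = 0.3, max_shift: int | None = None,
                 min_size: int = 20, min_occurrences: int = 10,
                 subject_frac: float = 0.8, member_frac: float = 0.5,
                 include_unconverged: bool = False) -> list[QPPCluster]:
    """Average-linkage clustering on 1 - similarity, cut at ``linkage_cut``.

    Robustness requires: size >= ``min_size``, representative occurrence count
    strictly > ``min_occurrences``, and more than ``member_frac`` of the
    members each occurring at least once in at least ``subject_frac`` of the
    subjects.  Unconverged ensemble members are excluded by default.

    Clusters are returned sorted by representative occurrence count
    (descending).
    """
    ids = [i for i, q in enumerate(ensemble)
           if include_unconverged or q.converged]
    if len(ids) < 2:
        raise ValueError("need at least 2 usable (converged) QPPs to cluster")
    if max_shift is None:
        max_shift = ensemble[ids[0]].window_w // 2

    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim, _ = qpp_similarity(ensemble[ids[i]], ensemble[ids[j]],
                                    max_shift)
            dist[i, j] = dist[j, i] = max(0.0, 1.0 - sim)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=linkage_cut, criterion="distance")

    clusters = []
    for c in np.unique(assignment):
        members = [ids[k] for k in np.flatnonzero(assignment == c)]
        rep = select_representative(members, ensemble)
        n_occ = ensemble[rep].n_occurrences
        fracs = [_member_subject_fraction(ensemble[m], subject_bounds)
                 for m in members]
        coverage = float(np.mean([f >= subject_frac for f in fracs]))
        robust = (len(members) >= min_size and n_occ > min_occurrences
                  and coverage > member_frac)
        clusters.append(QPPCluster(
            member_ids=sorted(members), size=len(members),
            n_occurrences=n_occ, subject_coverage=coverage, robust=robust,
            representative_id=rep))
    clusters.sort(key=lambda cl: (-cl.n_occurrences, cl.member_ids[0]))
    return clusters


def select_representative(member_ids: list[int] | QPPCluster,
                          ensemble: list[QPP]) -> int:
    """Member with the most STC-threshold occurrences; ties break to the
    lowest seed frame."""
    members = (member_ids.member_ids if isinstance(member_ids, QPPCluster)
               else list(member_ids))
    if not members:
        raise ValueError("cluster has no members")
    return min(members, key=lambda m: (-ensemble[m].n_occurrences,
                                       ensemble[m].seed_frame))


def match_clusters_across_groups(rqpps_a: list[QPP], rqpps_b: list[QPP],
                                 max_shift: int | None = None,
                                 threshold: float = 0.70) -> list[ClusterMatch]:
    """Greedy one-to-one matching of representative QPPs across two groups.

    All pairs are scored with :func:`qpp_similarity`; pairs are then fixed in
    descending similarity order.  A pair counts as matched only if its
    correlation strictly exceeds ``threshold`` (0.70).
    """
    if not rqpps_a or not rqpps_b:
        return []
    if max_shift is None:
        max_shift = rqpps_a[0].window_w // 2
    scored = []
    for i, qa in enumerate(rqpps_a):
        for j, qb in enumerate(rqpps_b):
            sim, shift = qpp_similarity(qa, qb, max_shift)
            scored.append((sim, i, j, shift))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for sim, i, j, shift in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(ClusterMatch(cluster_a=i, cluster_b=j,
                                    spatial_corr=float(sim), best_shift=shift,
                                    matched=bool(sim > threshold)))
    matches.sort(key=lambda m: (m.cluster_a, m.cluster_b))
    return matches


def cluster_report(clusters: list[QPPCluster]) -> "pandas.DataFrame":
    """Tabular cluster summary (size, occurrences, coverage, robust, rep)."""
    import pandas as pd

    return pd.DataFrame([{
        "cluster": i, "size": c.size, "occurrences": c.n_occurrences,
        "subject_coverage": round(c.subject_coverage, 4),
        "robust": bool(c.robust), "representative_id": c.representative_id,
    } for i, c in enumerate(clusters)])
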