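"""Genome binning of long contigs and marker-gene completeness scoring.

Contigs above a length cutoff (default 10 kb) are clustered by
average-linkage hierarchical clustering on the composite feature distance
(tetranucleotide frequency + log-coverage + GC). The cut is
an explicit bin count k, or "auto" = the k in [2, 10] with the largest
silhouette. Bin quality is scored against user-supplied marker-gene lists
(31 single-copy and 107 essential genes by convention); completeness is
strictly essential_found/107 with duplicates counted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .contig import Contig
from .errors import InsufficientInputError
from .seqprofile import DEFAULT_FEATURE_WEIGHTS, feature_distance_matrix, gc_content

N_SINGLE_COPY = 31
N_ESSENTIAL = 107


def default_single_copy_ids() -> list[str]:
    """Placeholder ids standing in for the 31 bacterial single-copy genes."""
    return [f"SCG_{i:03d}" for i in range(1, N_SINGLE_COPY + 1)]


def default_essential_ids() -> list[str]:
    """Placeholder ids standing in for the 107 essential genes."""
    return [f"ESS_{i:03d}" for i in range(1, N_ESSENTIAL + 1)]


@dataclass
class BinAssignment:
    assignments: dict[str, str]                  # contig id -> bin id
    summary: pd.DataFrame                        # per-bin total bp, mean gc/cov
    unbinned: list[str] = field(default_factory=list)  # below min_length

    @property
    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, b in self.assignments.items():
            out.setdefault(b, []).append(cid)
        return out


@dataclass
class MarkerReport:
    single_copy_found: int
    essential_found: int
    completeness: float
    duplicated_markers: int


def bin_contigs(contigs: Sequence[Contig], min_length: int = 10_000,
                k: int | str = "auto",
                weights: tuple[float, float, float] = DEFAULT_FEATURE_WEIGHTS,
                ) -> BinAssignment:
    """Cluster contigs >= min_length into k bins (k="auto": best silhouette)."""
    eligible = [c for c in contigs if c.length >= min_length]
    unbinned = [c.id for c in contigs if c.length < min_length]
    if len(eligible) < 2:
        raise InsufficientInputError(
            f"need >= 2 contigs of length >= {min_length}, got {len(eligible)}")
    dist = feature_distance_matrix(eligible, weights)
    z = linkage(squareform(dist, checks=False), method="average")
    if k == "auto":
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(10, len(eligible) - 1) + 1):
            labels = fcluster(z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            s = silhouette_score(dist, labels, metric="precomputed")
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    labels = fcluster(z, t=int(k), criterion="maxclust")
    assignments = {c.id: f"bin_{lab}" for c, lab in zip(eligible, labels)}
    rows = []
    for b in sorted(set(assignments.values()), key=lambda s: int(s.split("_")[1])):
        members = [c for c in eligible if assignments[c.id] == b]
        rows.append({
            "bin": b,
            "n_contigs": len(members),
            "total_bp": sum(c.length for c in members),
            "mean_gc": float(np.mean([gc_content(c) for c in members])),
            "mean_coverage": float(np.mean([c.coverage for c in members])),
        })
    return BinAssignment(assignments, pd.DataFrame(rows), unbinned)


def score_completeness(bin_annotations: Mapping[str, Sequence[str]] | pd.DataFrame,
                       single_copy_list: Sequence[str] | None = None,
                       essential_list: Sequence[str] | None = None,
                       ) -> MarkerReport:
    """Count distinct marker genes present in a bin's annotations.

    `bin_annotations` maps contig id -> marker ids found (or a DataFrame
    with columns contig_id, marker_id). Duplicates count once toward
    completeness and are tallied in duplicated_markers; ids absent from
    both lists raise a warning and are ignored.
    """
    single = list(single_copy_list) if single_copy_list else default_single_copy_ids()
    essential = list(essential_list) if essential_list else default_essential_ids()
    if isinstance(bin_annotations, pd.DataFrame):
        markers = [str(m) for m in bin_annotations["marker_id"]]
    else:
        markers = [str(m) for v in bin_annotations.values() for m in v]
    single_set, essential_set = set(single), set(essential)
    counts: dict[str, int] = {}
    for m in markers:
        if m not in single_set and m not in essential_set:
            warnings.warn(f"unknown marker id {m!r} ignored", stacklevel=2)
            continue
        counts[m] = counts.get(m, 0) + 1
    sc_found = len(set(counts) & single_set)
    ess_found = len(set(counts) & essential_set)
    dup = sum(1 for c in counts.values() if c > 1)
    return MarkerReport(
        single_copy_found=sc_found,
        essential_found=ess_found,
        completeness=ess_found / len(essential),
        duplicated_markers=dup)


def assignment_to_frame(assignment: BinAssignment) -> pd.DataFrame:
    rows = [{"contig_id": cid, "bin": b}
            for cid, b in sorted(assignment.assignments.items())]
    rows += [{"contig_id": cid, "bin": "unbinned"}
             for cid in sorted(assignment.unbinned)]
    return pd.DataFrame(rows)
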