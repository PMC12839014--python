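"""Library screening, hit filtering, diversity clustering, hit picking.

A screening library is standardized with the same protocol as the
training data, scored in batches by the selected model, and filtered by
probability score (inclusive comparator, default PS >= 0.8).  The
surviving hits are clustered for structural diversity by agglomerative
average-linkage clustering on the Tanimoto distance d = 1 - T between
path fingerprints, cutting the dendrogram at distance 0.30; one
representative per cluster — the commercially available member with
the highest PS — is selected for purchase.

The agglomerator is written out explicitly (rather than delegating to a
library routine) so that exact-tie merges are deterministic and
independent of input order: among equally distant pairs, the pair with
the lowest indices merges first.  Average linkage is monotone, so
merging until the closest pair exceeds the cutoff is equivalent to
cutting the full dendrogram at that height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cdk9screen import features, models
from cdk9screen.standardize import RawCompound, StandardizationError, strip_to_parent

DEFAULT_PS_MIN = 0.8
DEFAULT_CUT = 0.30


def standardize_library(library: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize a library frame (compound_id, smiles[, available]).

    Returns (standardized, rejects); unparseable entries are logged with
    a reason code, never dropped silently and never fatal.
    """
    rows, rejects = [], []
    for row in library.itertuples(index=False):
        try:
            std = strip_to_parent(RawCompound(str(row.compound_id), row.smiles))
        except StandardizationError as err:
            rejects.append((str(row.compound_id), err.reason))
            continue
        rows.append(
            (
                std.compound_id,
                std.parent_smiles,
                std.std_key,
                bool(getattr(row, "available", True)),
            )
        )
    standardized = pd.DataFrame(
        rows, columns=["compound_id", "parent_smiles", "std_key", "available"]
    )
    reject_log = pd.DataFrame(rejects, columns=["compound_id", "reason"])
    return standardized, reject_log


def score_library(
    model: models.TrainedModel,
    library: pd.DataFrame,
    scaler: features.ScalerModel | None = None,
    batch_size: int = 1000,
) -> pd.DataFrame:
    """Score a standardized library with the trained model, in batches.

    The representation comes from the model spec; output rows follow
    input order and gain a ``ps`` column.  Batching is purely a memory
    measure — results are identical for any batch size.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out = library.reset_index(drop=True).copy()
    ps = np.empty(len(out), dtype=np.float64)
    kind = model.spec.representation
    smiles = out["parent_smiles"].tolist()
    for start in range(0, len(out), batch_size):
        chunk = smiles[start : start + batch_size]
        X = features.featurize_matrix(chunk, kind, scaler)
        ps[start : start + len(chunk)] = models.predict_ps(model, X)
    out["ps"] = ps
    return out


def filter_hits(
    scored: pd.DataFrame, ps_min: float = DEFAULT_PS_MIN, inclusive: bool = True
) -> pd.DataFrame:
    """Retain high-scoring compounds, sorted by PS descending.

    The screening comparator is inclusive (ps >= ps_min) by default;
    set ``inclusive=False`` for the strict form used by the
    model-evaluation thresholds.
    """
    keep = scored["ps"] >= ps_min if inclusive else scored["ps"] > ps_min
    hits = scored[keep].copy()
    return hits.sort_values(
        ["ps", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Average-linkage agglomerative clustering with deterministic tie-breaks
# ---------------------------------------------------------------------------

def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - T over rows of a binary fingerprint matrix."""
    fps = np.asarray(fps, dtype=np.float64)
    sim = models.tanimoto_kernel_matrix(fps, fps)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage_labels(dist: np.ndarray, cut: float) -> np.ndarray:
    """Cluster labels from average-linkage agglomeration cut at ``cut``.

    Clusters merge while the smallest average inter-cluster distance is
    <= cut; exact ties merge the lowest-index pair first.  Labels are
    renumbered 0..k-1 in order of each cluster's first member.
    """
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    D = dist.copy()
    np.fill_diagonal(D, np.inf)
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    while alive.sum() > 1:
        sub = np.where(alive)[0]
        block = D[np.ix_(sub, sub)]
        flat = np.argmin(block)  # first occurrence = lowest-index pair
        i_s, j_s = divmod(flat, block.shape[1])
        if block[i_s, j_s] > cut:
            break
        i, j = sorted((sub[i_s], sub[j_s]))
        # Lance-Williams update for average linkage
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * D[i] + nj * D[j]) / (ni + nj)
        D[i], D[:, i] = new_row, new_row
        D[i, i] = np.inf
        sizes[i] = ni + nj
        members[i].extend(members[j])
        alive[j] = False
        D[j], D[:, j] = np.inf, np.inf
    labels = np.empty(n, dtype=int)
    next_label = 0
    for i in sorted(np.where(alive)[0], key=lambda i: min(members[i])):
        for m in members[i]:
            labels[m] = next_label
        next_label += 1
    return labels


@dataclass
class ClusterAssignment:
    """Cluster membership of the hit list at one distance cutoff."""

    labels: np.ndarray
    cut: float
    n_clusters: int


def cluster_hits(hits: pd.DataFrame, cut: float = DEFAULT_CUT) -> ClusterAssignment:
    """Diversity clustering of hits on path-fingerprint Tanimoto distance."""
    if len(hits) == 0:
        return ClusterAssignment(np.zeros(0, dtype=int), cut, 0)
    fps = features.featurize_matrix(hits["parent_smiles"].tolist(), "path_fp")
    labels = average_linkage_labels(tanimoto_distance_matrix(fps), cut)
    return ClusterAssignment(labels, cut, int(labels.max()) + 1)


def select_representatives(
    assignment: ClusterAssignment, hits: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """One representative per cluster: highest-PS available member.

    Ties break by lexicographic compound_id.  Clusters with no available
    member contribute no representative; they are reported in the
    returned log lines (mirroring compounds dropping out of a purchase
    list when vendors cannot supply them).
    """
    hits = hits.reset_index(drop=True).copy()
    if len(hits) != len(assignment.labels):
        raise ValueError("assignment does not match hits")
    hits["cluster"] = assignment.labels
    rows, log = [], []
    for cluster_id, group in hits.groupby("cluster", sort=True):
        avail = group[group["available"]]
        if avail.empty:
            log.append(
                f"cluster {cluster_id}: no available member "
                f"({len(group)} compounds skipped)"
            )
            continue
        best = avail.sort_values(
            ["ps", "compound_id"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        rows.append(
            {
                "compound_id": best["compound_id"],
                "parent_smiles": best["parent_smiles"],
                "ps": float(best["ps"]),
                "cluster": int(cluster_id),
                "cluster_size": int(len(group)),
            }
        )
    reps = pd.DataFrame(
        rows, columns=["compound_id", "parent_smiles", "ps", "cluster", "cluster_size"]
    )
    reps = reps.sort_values(
        ["ps", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return reps, log
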