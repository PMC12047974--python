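"""Network-level differentiation metrics in two-dimensional gradient space.

For each subject, with each parcel placed at (gradient-1 score, gradient-2 score):

* network mean — arithmetic mean gradient score per network, per gradient;
* gradient range — max minus min score across parcels, per gradient;
* within-network dispersion — mean Euclidean distance from a network's central
  point (the coordinate-wise median of its member parcels) to all of its members;
* between-network dispersion — Euclidean distance between the central points of
  each unordered pair of networks.

A 7-network scheme yields 7 within- and 21 between-network dispersion scores per
subject. Low within-dispersion means a tight, undifferentiated network; low
between-dispersion means blurred segregation between two networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .scheme import ParcelScheme


@dataclass(frozen=True)
class DifferentiationMetrics:
    network_mean: pd.DataFrame  # networks x gradients
    range_: pd.Series  # per gradient
    centroids: pd.DataFrame  # networks x (g1, g2)
    within_dispersion: pd.Series  # per network
    between_dispersion: pd.Series  # per unordered network pair, index "A|B"


def network_means(scores: np.ndarray, scheme: ParcelScheme) -> pd.DataFrame:
    """Mean gradient score per network per gradient (networks x gradients)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != scheme.n_parcels:
        raise ValueError("scores do not match scheme parcel count")
    out = {}
    for net in scheme.networks:
        idx = scheme.network_indices(net)
        out[net] = scores[idx].mean(axis=0)
    return pd.DataFrame(
        out, index=[f"g{i + 1}" for i in range(scores.shape[1])]
    ).T


def gradient_range(scores_1d: np.ndarray) -> float:
    """Max minus min gradient score; a global differentiation index."""
    v = np.asarray(scores_1d, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need >= 2 parcels for a range")
    return float(v.max() - v.min())


def dispersion_metrics(
    g1: np.ndarray, g2: np.ndarray, scheme: ParcelScheme
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centroids, within- and between-network dispersion in the (g1, g2) plane.

    The central point of a network is the coordinate-wise (marginal) median of
    its member parcels; within-dispersion averages the Euclidean distance from
    that point to every member (members coinciding with it contribute 0);
    between-dispersion is the distance between central points of network pairs.
    """
    pts = np.column_stack([np.asarray(g1, float).ravel(), np.asarray(g2, float).ravel()])
    if pts.shape[0] != scheme.n_parcels:
        raise ValueError("gradient scores do not match scheme parcel count")
    nets = scheme.networks
    cent = {}
    within = {}
    for net in nets:
        idx = scheme.network_indices(net)
        if idx.size < 2:
            raise ValueError(f"network {net!r} has < 2 parcels")
        member = pts[idx]
        c = np.median(member, axis=0)
        cent[net] = c
        within[net] = float(np.linalg.norm(member - c, axis=1).mean())
    centroids = pd.DataFrame(cent, index=["g1", "g2"]).T
    between = {
        f"{a}|{b}": float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
        for a, b in combinations(nets, 2)
    }
    return centroids, pd.Series(within, name="within_dispersion"), pd.Series(
        between, name="between_dispersion"
    )


def subject_metrics(scores: np.ndarray, scheme: ParcelScheme) -> DifferentiationMetrics:
    """All differentiation metrics for one subject's (aligned) gradient scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need at least two gradients (columns)")
    nm = network_means(scores[:, :2], scheme)
    rng = pd.Series(
        {f"g{c + 1}": gradient_range(scores[:, c]) for c in range(2)}, name="range"
    )
    centroids, within, between = dispersion_metrics(scores[:, 0], scores[:, 1], scheme)
    return DifferentiationMetrics(nm, rng, centroids, within, between)


def metrics_table(
    subject_scores: dict[str, np.ndarray], scheme: ParcelScheme
) -> pd.DataFrame:
    """Wide per-subject metric table over a cohort.

    Columns: ``nm_g{1,2}_<net>`` network means, ``range_g{1,2}``, ``wd_<net>``
    within-network dispersion, ``bd_<netA>|<netB>`` between-network dispersion.
    """
    rows = {}
    for sid, scores in subject_scores.items():
        m = subject_metrics(scores, scheme)
        row: dict[str, float] = {}
        for net in m.network_mean.index:
            row[f"nm_g1_{net}"] = m.network_mean.loc[net, "g1"]
            row[f"nm_g2_{net}"] = m.network_mean.loc[net, "g2"]
        row["range_g1"] = m.range_["g1"]
        row["range_g2"] = m.range_["g2"]
        for net, v in m.within_dispersion.items():
            row[f"wd_{net}"] = v
        for pair, v in m.between_dispersion.items():
            row[f"bd_{pair}"] = v
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


METRIC_FAMILIES = ("network_mean_g1", "network_mean_g2", "range", "within_dispersion",
                   "between_dispersion")


def metric_family(column: str) -> str:
    """FDR family of a metrics_table column."""
    if column.startswith("nm_g1_"):
        return "network_mean_g1"
    if column.startswith("nm_g2_"):
        return "network_mean_g2"
    if column.startswith("range_"):
        return "range"
    if column.startswith("wd_"):
        return "within_dispersion"
    if column.startswith("bd_"):
        return "between_dispersion"
    raise ValueError(f"not a metric column: {column!r}")
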