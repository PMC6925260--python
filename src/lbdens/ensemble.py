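"""Well-bottom clustering and Boltzmann-weighted ensemble averages.

Frames harvested from the bottom of each free-energy well are k-means
clustered; each significant cluster contributes an observable value x_i
(in a full MD workflow, computed from a 1 us cMD run started at the
cluster representative) weighted by its fraction w_i of the well's frames:

    weighted average = w_1 x_1 + w_2 x_2 + ... + w_n x_n

Per-well averages are then combined across wells with Boltzmann
populations pi_i = exp(-E_i / kB T) / sum_j exp(-E_j / kB T), E_i being the
well energy relative to the lowest well, giving the ensemble's single
"Boltzmann average" value of the observable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from lbdens.constants import KB_KCAL_MOL_K, DEFAULT_TEMPERATURE_K

__all__ = [
    "ClusterSet",
    "WellSummary",
    "cluster_well_frames",
    "weighted_average",
    "well_populations",
    "boltzmann_average",
]


@dataclass
class ClusterSet:
    """k-means clusters of one well's frames.

    ``fractions`` are relative to *all* frames handed in (the well total),
    so after dropping clusters below ``min_fraction`` they sum to <= 1.
    """

    fractions: dict[int, float]
    representatives: dict[int, int]  # cluster id -> frame id nearest centroid
    labels: np.ndarray  # per-input-frame cluster id (before thresholding)
    k: int
    min_fraction: float
    dropped: tuple[int, ...] = field(default_factory=tuple)


@dataclass
class WellSummary:
    """One well's relative energy, observable average and population."""

    energy: float  # kcal/mol relative to the lowest well
    average: float  # weighted-average observable for this well
    population: float  # Boltzmann fraction, sums to 1 over wells


def cluster_well_frames(
    frame_ids: Sequence[int],
    coordinates: np.ndarray,
    k: int = 5,
    min_fraction: float = 0.05,
    seed: int = 0,
) -> ClusterSet:
    """k-means cluster well-bottom frames (default 5 clusters, drop <5%).

    ``coordinates`` is an (n_frames, n_features) array — Cartesian
    coordinates flattened per frame, or the CV pairs when coordinates are
    unavailable.  The representative of each cluster is the member frame
    nearest (squared-Euclidean) its centroid.  Fixed ``seed`` gives
    deterministic output; 10 seeded restarts guard against bad initial
    centroids.
    """
    frame_ids = np.asarray(frame_ids)
    coordinates = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coordinates.shape[0] != frame_ids.size:
        raise ValueError("frame_ids and coordinates length mismatch")
    n = frame_ids.size
    if n < k:
        warnings.warn(f"only {n} frames available; reducing k from {k} to {n}")
        k = n
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(coordinates)
    fractions: dict[int, float] = {}
    reps: dict[int, int] = {}
    dropped: list[int] = []
    for cid in range(k):
        members = np.flatnonzero(labels == cid)
        frac = members.size / n
        d2 = ((coordinates[members] - km.cluster_centers_[cid]) ** 2).sum(axis=1)
        rep = int(frame_ids[members[np.argmin(d2)]])
        if frac < min_fraction:
            dropped.append(cid)
        else:
            fractions[cid] = frac
            reps[cid] = rep
    return ClusterSet(
        fractions=fractions,
        representatives=reps,
        labels=labels,
        k=k,
        min_fraction=min_fraction,
        dropped=tuple(dropped),
    )


def weighted_average(
    clusters: ClusterSet,
    values: Mapping[int, float],
    renormalize: bool = True,
) -> float:
    """Cluster-fraction weighted average of an observable for one well.

    With ``renormalize`` (default) the surviving-cluster fractions are
    rescaled to sum to 1 so the result is a convex combination of the
    cluster values; without it the literal sum of w_i x_i over surviving
    clusters is returned.
    """
    missing = [cid for cid in clusters.fractions if cid not in values]
    if missing:
        raise ValueError(f"missing observable values for clusters {missing}")
    if not clusters.fractions:
        raise ValueError("no surviving clusters")
    total = sum(clusters.fractions.values())
    acc = sum(w * values[cid] for cid, w in clusters.fractions.items())
    return acc / total if renormalize else acc


def well_populations(
    energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE_K,
    literal_sign: bool = False,
) -> np.ndarray:
    """Boltzmann populations of wells from relative energies (kcal/mol).

    pi_i = exp(-E_i / kB T) / sum_j exp(-E_j / kB T), so the lowest-energy
    well (E = 0 by construction) is the most populated.  ``literal_sign``
    flips to the +E_i exponent for audit purposes only.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("no well energies supplied")
    if (e < 0).any():
        raise ValueError("well energies must be >= 0 (relative to lowest well)")
    if not math.isclose(e.min(), 0.0, abs_tol=1e-9):
        raise ValueError("lowest well must have energy exactly 0")
    kt = KB_KCAL_MOL_K * temperature
    sign = 1.0 if literal_sign else -1.0
    x = np.exp(sign * e / kt)
    return x / x.sum()


def boltzmann_average(summaries: Sequence[WellSummary]) -> float:
    """Population-weighted combination of per-well averages."""
    if not summaries:
        raise ValueError("no well summaries supplied")
    total = sum(s.population for s in summaries)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"well populations sum to {total}, expected 1")
    return sum(s.population * s.average for s in summaries)
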