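"""Reweighting of biased (aMD) ensembles and 2D free-energy landscapes.

An accelerated-MD run samples a flattened potential V + dV where the boost
dV >= 0 is largest in deep wells.  Each saved frame carries its boost
energy, so the unbiased Boltzmann distribution can be recovered by giving
frame i a weight proportional to exp(dV_i / kB T) (or a series / cumulant
approximation of it when the exponential is too noisy).  Binning reweighted
frames over the two RMSD collective variables and taking -kB T ln p yields
the potential of mean force (PMF) displayed as an energy landscape; its
local minima are the wells whose members feed the ensemble-averaging stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from lbdens.constants import KB_KCAL_MOL_K, DEFAULT_TEMPERATURE_K

__all__ = [
    "TrajectoryEnsemble",
    "LandscapeGrid",
    "Well",
    "reweight_frames",
    "build_pmf",
    "find_wells",
    "extract_well_frames",
]


@dataclass
class TrajectoryEnsemble:
    """Per-frame collective variables and boost energies of a biased run.

    Parameters
    ----------
    cv1, cv2 : arrays, angstrom
        The two collective variables (RMSD to the active and to the
        inactive reference conformation in the original application).
    dv : array, kcal/mol
        Boost energy of each frame; all zero for an unbiased (cMD) run.
    temperature : float, kelvin
    frame_ids : array of int, optional
        Defaults to 0..n-1.
    """

    cv1: np.ndarray
    cv2: np.ndarray
    dv: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cv1 = np.asarray(self.cv1, dtype=float)
        self.cv2 = np.asarray(self.cv2, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.cv1.size == 0:
            raise ValueError("ensemble must contain at least one frame")
        if not (self.cv1.shape == self.cv2.shape == self.dv.shape):
            raise ValueError("cv1, cv2 and dv must have identical shapes")
        if not (np.isfinite(self.cv1).all() and np.isfinite(self.cv2).all()):
            raise ValueError("collective variables must be finite")
        if (self.dv < 0).any() or not np.isfinite(self.dv).all():
            raise ValueError("boost energies dV must be finite and >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.cv1.size)
        else:
            self.frame_ids = np.asarray(self.frame_ids)
            if self.frame_ids.shape != self.cv1.shape:
                raise ValueError("frame_ids length mismatch")

    def __len__(self) -> int:
        return int(self.cv1.size)

    @property
    def beta(self) -> float:
        """1/(kB T) in mol/kcal."""
        return 1.0 / (KB_KCAL_MOL_K * self.temperature)


@dataclass
class LandscapeGrid:
    """Binned, reweighted free-energy surface.

    ``prob`` sums to 1 over occupied bins; ``pmf`` is -kB T ln p shifted so
    the occupied minimum is exactly 0; unoccupied bins are NaN, never 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    prob: np.ndarray
    pmf: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.prob > 0

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class Well:
    """A local PMF minimum, with energy relative to the global minimum."""

    center: tuple[float, float]  # (cv1, cv2) bin centers, angstrom
    index: tuple[int, int]  # bin indices on the grid
    energy: float  # kcal/mol, >= 0; exactly one well per landscape has 0


# estimators accepted by reweight_frames
_ESTIMATORS = ("exponential", "maclaurin", "cumulant2")

# exp() overflow guard: beta*dV beyond this loses all small-weight frames
_MAX_EXP_ARG = 700.0


def reweight_frames(
    ensemble: TrajectoryEnsemble,
    estimator: str = "cumulant2",
    order: int = 10,
    bin_width: float = 0.1,
) -> np.ndarray:
    """Per-frame weights that undo the aMD boost, normalized to sum to 1.

    ``exponential`` gives the exact w_i proportional to exp(beta dV_i);
    ``maclaurin`` truncates that exponential to the given series order
    (variance-reduced, slightly biased); ``cumulant2`` assigns each frame
    the second-order cumulant-corrected weight of its CV bin,
    exp(<beta dV>_b + var(beta dV)_b / 2) / N, so that histogramming these
    weights on the same grid reproduces the per-bin cumulant PMF.

    Raises
    ------
    OverflowError
        When the exponential estimator would overflow; use ``cumulant2``.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}, got {estimator!r}")
    bdv = ensemble.beta * ensemble.dv
    if estimator == "exponential":
        if bdv.max() - bdv.min() > _MAX_EXP_ARG:
            raise OverflowError(
                "beta*dV range too large for exponential reweighting; "
                "use estimator='cumulant2'"
            )
        w = np.exp(bdv - bdv.max())
    elif estimator == "maclaurin":
        if order < 1:
            raise ValueError("maclaurin order must be >= 1")
        w = np.zeros_like(bdv)
        term = np.ones_like(bdv)
        w += term
        for k in range(1, order + 1):
            term = term * bdv / k
            w += term
    else:  # cumulant2, per CV bin
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        ix = np.floor(ensemble.cv1 / bin_width).astype(np.int64)
        iy = np.floor(ensemble.cv2 / bin_width).astype(np.int64)
        keys = ix * (iy.max() - iy.min() + 1 + 1) + iy  # unique per bin
        _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=bdv)
        sq_sums = np.bincount(inverse, weights=bdv**2)
        mean = sums / counts
        var = np.maximum(sq_sums / counts - mean**2, 0.0)
        log_w_bin = mean + 0.5 * var
        w = np.exp(log_w_bin[inverse] - log_w_bin.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise OverflowError("reweighting produced non-finite weights")
    return w / total


def build_pmf(
    ensemble: TrajectoryEnsemble,
    weights: np.ndarray | None = None,
    bin_width: float = 0.1,
) -> LandscapeGrid:
    """Weighted 2D histogram of the CVs converted to a PMF.

    PMF(bin) = -kB T ln p(bin), shifted so the occupied minimum is 0.
    Unoccupied bins are NaN (flagged, not zero energy).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = len(ensemble)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != ensemble.cv1.shape:
            raise ValueError("weights length mismatch")
        if not math.isclose(weights.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError("weights must be normalized to sum to 1")

    def _edges(v: np.ndarray) -> np.ndarray:
        lo = math.floor(v.min() / bin_width) * bin_width
        hi = math.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        nbins = int(round((hi - lo) / bin_width))
        return lo + bin_width * np.arange(nbins + 1)

    x_edges = _edges(ensemble.cv1)
    y_edges = _edges(ensemble.cv2)
    prob, _, _ = np.histogram2d(
        ensemble.cv1, ensemble.cv2, bins=(x_edges, y_edges), weights=weights
    )
    prob /= prob.sum()
    occ = prob > 0
    if occ.sum() == 1:
        warnings.warn("all frames fall in a single bin: degenerate landscape")
    kt = KB_KCAL_MOL_K * ensemble.temperature
    pmf = np.full_like(prob, np.nan)
    pmf[occ] = -kt * np.log(prob[occ])
    pmf[occ] -= np.nanmin(pmf[occ])
    return LandscapeGrid(x_edges, y_edges, prob, pmf, ensemble.temperature)


def _neighbors(i: int, j: int, shape: tuple[int, int]):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                yield ni, nj


def find_wells(
    grid: LandscapeGrid,
    max_energy: float = 3.0,
    min_separation: float = 0.0,
) -> list[Well]:
    """Local PMF minima below ``max_energy``, ordered by energy.

    A bin is a candidate when it is occupied and no occupied 8-neighbor has
    a strictly lower PMF.  Plateaus (connected candidates with equal PMF)
    are collapsed to their lowest flat-index bin.  Candidates whose centers
    are closer than ``min_separation`` (angstrom, Euclidean) are merged
    keeping the deeper; ties keep the lower flat index.  Returns an empty
    list (not an error) when nothing lies below ``max_energy``.
    """
    occ = grid.occupied
    if not occ.any():
        raise ValueError("grid has no occupied bins")
    pmf = grid.pmf
    shape = pmf.shape
    candidates: list[tuple[int, int]] = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not occ[i, j]:
                continue
            if all(
                not occ[ni, nj] or pmf[ni, nj] >= pmf[i, j]
                for ni, nj in _neighbors(i, j, shape)
            ):
                candidates.append((i, j))
    # collapse equal-energy plateaus to the lowest flat index
    cand_set = set(candidates)
    kept: list[tuple[int, int]] = []
    for i, j in candidates:
        comp = {(i, j)}
        stack = [(i, j)]
        while stack:
            ci, cj = stack.pop()
            for ni, nj in _neighbors(ci, cj, shape):
                if (ni, nj) in cand_set and (ni, nj) not in comp and pmf[
                    ni, nj
                ] == pmf[i, j]:
                    comp.add((ni, nj))
                    stack.append((ni, nj))
        if (i, j) == min(comp, key=lambda t: t[0] * shape[1] + t[1]):
            kept.append((i, j))

    xc, yc = grid.x_centers, grid.y_centers
    wells = [
        Well(center=(float(xc[i]), float(yc[j])), index=(i, j), energy=float(pmf[i, j]))
        for i, j in kept
        if pmf[i, j] <= max_energy
    ]
    wells.sort(key=lambda w: (w.energy, w.index[0] * shape[1] + w.index[1]))
    # merge nearby minima, keeping the deeper (list already energy-ordered)
    merged: list[Well] = []
    for w in wells:
        if all(
            math.hypot(w.center[0] - m.center[0], w.center[1] - m.center[1])
            >= min_separation
            for m in merged
        ):
            merged.append(w)
    return merged


def extract_well_frames(
    ensemble: TrajectoryEnsemble,
    well: Well,
    half_width: float = 0.1,
) -> np.ndarray:
    """Frame ids inside the closed square of half-side ``half_width`` (A).

    The default 0.1 A half-width reproduces the 0.2 x 0.2 A RMSD square
    centered on the well bottom used to harvest structures for clustering.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    cx, cy = well.center
    mask = (np.abs(ensemble.cv1 - cx) <= half_width) & (
        np.abs(ensemble.cv2 - cy) <= half_width
    )
    if not mask.any():
        raise ValueError(
            f"no frames within {half_width} A of well at {well.center}; "
            "well unusable for clustering"
        )
    return ensemble.frame_ids[mask]
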