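"""Structural observables on coordinate trajectories.

Prevalences of hydrogen bonds and salt bridges, backbone-dihedral helicity
profiles and helix extension, and segment RMSD series — the per-trajectory
quantities that feed the well/Boltzmann averaging stage.  Trajectories are
:class:`mdtraj.Trajectory` objects (multi-model PDB in, constant topology);
all distances in the public interface are in angstroms and residue numbers
are 1-based inclusive, matching PPARgamma2 isoform numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import mdtraj as md
import numpy as np

__all__ = [
    "BondCriteria",
    "ObservableSeries",
    "parse_selector",
    "hbond_prevalence",
    "saltbridge_prevalence",
    "helicity_profile",
    "helix_extension",
    "rmsd_series",
]

NM_PER_ANGSTROM = 0.1

# alpha-helical backbone dihedral window, degrees
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
MIN_HELIX_RUN = 3

# side-chain nitrogen / oxygen atom names recognized for salt bridges
_BASIC_N = {"NZ", "NH1", "NH2", "NE", "ND1", "NE2"}
_ACIDIC_O = {"OE1", "OE2", "OD1", "OD2"}


@dataclass(frozen=True)
class BondCriteria:
    """Hydrogen-bond geometry cutoffs.

    The ideal criterion (donor–acceptor heavy-atom distance <= 3.5 A and
    donor–H–acceptor angle >= 135 deg) is a field convention; the relaxed
    criterion loosens it by the stated margins (+0.4 A, -20 deg).
    """

    max_distance: float = 3.5  # angstrom, donor-acceptor
    min_angle: float = 135.0  # degrees at the hydrogen
    relaxed_distance_margin: float = 0.4
    relaxed_angle_margin: float = 20.0

    def cutoffs(self, mode: str) -> tuple[float, float]:
        if mode == "ideal":
            return self.max_distance, self.min_angle
        if mode == "relaxed":
            return (
                self.max_distance + self.relaxed_distance_margin,
                self.min_angle - self.relaxed_angle_margin,
            )
        raise ValueError(f"mode must be 'ideal' or 'relaxed', got {mode!r}")


@dataclass
class ObservableSeries:
    """Per-frame scalar observable with units and provenance."""

    values: np.ndarray
    units: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def parse_selector(sel: str) -> tuple[int, list[str]]:
    """Parse ``'K347:NZ'`` / ``'E499:OE1/OE2'`` into (resid, atom names).

    The leading one-letter residue code is optional and not checked against
    the topology; the number is the 1-based residue id.
    """
    try:
        res_part, atom_part = sel.split(":")
    except ValueError as exc:
        raise ValueError(f"selector {sel!r} must look like 'K347:NZ'") from exc
    digits = "".join(c for c in res_part if c.isdigit())
    if not digits:
        raise ValueError(f"selector {sel!r} has no residue number")
    return int(digits), [a.strip() for a in atom_part.split("/") if a.strip()]


def _resolve(traj: md.Trajectory, resid: int, names: list[str]) -> list[int]:
    idx = [
        a.index
        for a in traj.topology.atoms
        if a.residue.resSeq == resid and a.name in names
    ]
    if not idx:
        raise ValueError(f"no atoms named {names} in residue {resid}")
    return idx


def _bonded_hydrogens(traj: md.Trajectory, donor_index: int) -> list[int]:
    """Hydrogens of the donor's residue within covalent range in frame 0."""
    donor = traj.topology.atom(donor_index)
    hyds = [
        a.index
        for a in donor.residue.atoms
        if a.element is not None and a.element.symbol == "H"
    ]
    if not hyds:
        return []
    d = md.compute_distances(
        traj[0], [[donor_index, h] for h in hyds], periodic=False
    )[0]
    return [h for h, dist in zip(hyds, d) if dist / NM_PER_ANGSTROM < 1.3]


def hbond_prevalence(
    traj: md.Trajectory,
    donor: str,
    acceptor: str,
    criteria: BondCriteria = BondCriteria(),
    mode: str = "ideal",
) -> float:
    """Fraction of frames in which any donor–acceptor pair is H-bonded.

    ``donor`` / ``acceptor`` are ``'K347:NZ'``-style selectors; the donor
    atoms must carry at least one covalently bound hydrogen.  A pair counts
    as bonded when the heavy-atom distance and the donor–H–acceptor angle
    (maximized over the donor's hydrogens) both satisfy the criterion.
    """
    d_res, d_names = parse_selector(donor)
    a_res, a_names = parse_selector(acceptor)
    d_idx = _resolve(traj, d_res, d_names)
    a_idx = _resolve(traj, a_res, a_names)
    max_dist, min_angle = criteria.cutoffs(mode)

    bonded = np.zeros(traj.n_frames, dtype=bool)
    for di in d_idx:
        hyds = _bonded_hydrogens(traj, di)
        if not hyds:
            raise ValueError(
                f"donor atom {traj.topology.atom(di)} has no bound hydrogen"
            )
        for ai in a_idx:
            dist = (
                md.compute_distances(traj, [[di, ai]], periodic=False)[:, 0]
                / NM_PER_ANGSTROM
            )
            ang_ok = np.zeros(traj.n_frames, dtype=bool)
            for h in hyds:
                ang = np.degrees(
                    md.compute_angles(traj, [[di, h, ai]], periodic=False)[:, 0]
                )
                ang_ok |= ang >= min_angle
            bonded |= (dist <= max_dist) & ang_ok
    return float(bonded.mean())


def saltbridge_prevalence(
    traj: md.Trajectory,
    basic_resid: int,
    acidic_resid: int,
    cutoff: float = 4.0,
) -> float:
    """Fraction of frames with any side-chain N–O pair within ``cutoff`` A."""
    n_idx = [
        a.index
        for a in traj.topology.atoms
        if a.residue.resSeq == basic_resid and a.name in _BASIC_N
    ]
    o_idx = [
        a.index
        for a in traj.topology.atoms
        if a.residue.resSeq == acidic_resid and a.name in _ACIDIC_O
    ]
    if not n_idx:
        raise ValueError(f"residue {basic_resid} has no basic side-chain N atoms")
    if not o_idx:
        raise ValueError(f"residue {acidic_resid} has no acidic side-chain O atoms")
    pairs = [[ni, oi] for ni in n_idx for oi in o_idx]
    d = md.compute_distances(traj, pairs, periodic=False) / NM_PER_ANGSTROM
    return float((d.min(axis=1) <= cutoff).mean())


def _helical_mask(traj: md.Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(frames x residues) helicity matrix and the residue ids it covers.

    A residue is helical in a frame when its (phi, psi) lie in the
    alpha-helical window and it belongs to a run of >= MIN_HELIX_RUN
    consecutive window-satisfying residues.  Chain-terminal residues lack
    one dihedral and are never assigned helical.
    """
    phi_idx, phi = md.compute_phi(traj, periodic=False)
    psi_idx, psi = md.compute_psi(traj, periodic=False)
    top = traj.topology
    # map dihedral quartets to the residue owning the central CA
    phi_res = {top.atom(q[2]).residue.resSeq: i for i, q in enumerate(phi_idx)}
    psi_res = {top.atom(q[1]).residue.resSeq: i for i, q in enumerate(psi_idx)}
    resids = np.array(sorted(set(phi_res) & set(psi_res)))
    n_frames = traj.n_frames
    in_window = np.zeros((n_frames, resids.size), dtype=bool)
    for j, r in enumerate(resids):
        ph = np.degrees(phi[:, phi_res[r]])
        ps = np.degrees(psi[:, psi_res[r]])
        in_window[:, j] = (
            (ph >= HELIX_PHI[0])
            & (ph <= HELIX_PHI[1])
            & (ps >= HELIX_PSI[0])
            & (ps <= HELIX_PSI[1])
        )
    helical = np.zeros_like(in_window)
    for f in range(n_frames):
        row = in_window[f]
        j = 0
        while j < row.size:
            if row[j]:
                k = j
                while k < row.size and row[k] and (
                    k == j or resids[k] == resids[k - 1] + 1
                ):
                    k += 1
                if k - j >= MIN_HELIX_RUN:
                    helical[f, j:k] = True
                j = k
            else:
                j += 1
    return helical, resids


def helicity_profile(
    traj: md.Trajectory,
    residue_range: tuple[int, int] | None = None,
) -> dict[int, float]:
    """Per-residue helical fraction over frames (1-based inclusive range)."""
    helical, resids = _helical_mask(traj)
    frac = helical.mean(axis=0)
    out = {int(r): float(f) for r, f in zip(resids, frac)}
    if residue_range is not None:
        lo, hi = residue_range
        if hi - lo + 1 < 4:
            raise ValueError("residue range must span at least 4 residues")
        out = {r: v for r, v in out.items() if lo <= r <= hi}
    return out


def helix_extension(traj: md.Trajectory, reference_terminus: int) -> float:
    """Mean N-terminal helix extension (residues) past a reference terminus.

    For each frame, counts how many residues immediately N-terminal to
    ``reference_terminus`` (terminus-1, terminus-2, ...) are contiguously
    helical; the mean over frames is returned.
    """
    helical, resids = _helical_mask(traj)
    pos = {int(r): j for j, r in enumerate(resids)}
    ext = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        count = 0
        r = reference_terminus - 1
        while r in pos and helical[f, pos[r]]:
            count += 1
            r -= 1
        ext[f] = count
    return float(ext.mean())


_BACKBONE = ("N", "CA", "C", "O")


def _backbone_indices(traj: md.Trajectory, residue_range: tuple[int, int]) -> list[int]:
    lo, hi = residue_range
    idx = [
        a.index
        for a in traj.topology.atoms
        if lo <= a.residue.resSeq <= hi and a.name in _BACKBONE
    ]
    if not idx:
        raise ValueError(f"no backbone atoms in residue range {residue_range}")
    return idx


def rmsd_series(
    traj: md.Trajectory,
    reference: md.Trajectory,
    residue_range: tuple[int, int],
    fit_range: tuple[int, int] | None = None,
) -> ObservableSeries:
    """Backbone RMSD (A) per frame after superposition on ``fit_range``.

    Each frame is least-squares superposed onto the reference using the
    backbone atoms of ``fit_range`` (defaults to ``residue_range``), then
    the RMSD is evaluated over the backbone atoms of ``residue_range`` —
    e.g. helix 12 RMSD to the active and inactive chains of the reference
    crystal structure, or the 322–329 charge-clamp segment.
    """
    if fit_range is None:
        fit_range = residue_range
    fit_idx = _backbone_indices(traj, fit_range)
    calc_idx = _backbone_indices(traj, residue_range)
    ref_fit_idx = _backbone_indices(reference, fit_range)
    ref_calc_idx = _backbone_indices(reference, residue_range)
    if len(fit_idx) != len(ref_fit_idx) or len(calc_idx) != len(ref_calc_idx):
        raise ValueError("trajectory/reference atom mismatch over requested ranges")
    moved = traj.slice(range(traj.n_frames), copy=True)
    moved.superpose(
        reference, frame=0, atom_indices=fit_idx, ref_atom_indices=ref_fit_idx
    )
    diff = moved.xyz[:, calc_idx, :] - reference.xyz[0, ref_calc_idx, :]
    rmsd_nm = np.sqrt((diff**2).sum(axis=2).mean(axis=1))
    return ObservableSeries(
        values=rmsd_nm / NM_PER_ANGSTROM,
        units="angstrom",
        provenance={
            "definition": f"backbone RMSD over residues {residue_range}, "
            f"fit on {fit_range}",
        },
    )
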