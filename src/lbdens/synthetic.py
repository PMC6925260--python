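"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of input the analysis consumes —
boosted-ensemble CV tables, idealized peptide trajectories with scheduled
hydrogen bonds and helicity, Lorentzian peak mixtures, two-state
saturation-transfer profiles, quadratic-binding titrations with planted
outliers, and residue-level deuterium-uptake truths observed through
overlapping peptides — so every downstream stage can be tested closed-loop
without any deposited data.  Noise is additive Gaussian everywhere and
every source of randomness takes an explicit integer seed; a fixed seed
gives bit-identical output.

None of this simulates real force-field dynamics: trajectories are ideal
geometric constructions whose observables equal their schedules exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mdtraj as md
import numpy as np

from lbdens.constants import KB_KCAL_MOL_K, DEFAULT_TEMPERATURE_K
from lbdens.binding import AnisotropyTitration, quadratic_binding
from lbdens.hdx import HDXPeptideSet, effective_residues
from lbdens.landscape import TrajectoryEnsemble
from lbdens.nmr import CESTProfile, Spectrum1D, cest_intensity, phased_lorentzian
import pandas as pd

__all__ = [
    "WellSpec",
    "BoostSpec",
    "LandscapeSpec",
    "BondSchedule",
    "ResidueUptakeTruth",
    "gen_amd_ensemble",
    "gen_mini_protein_trajectory",
    "gen_spectrum",
    "gen_cest_profile",
    "gen_titration",
    "gen_hdx_dataset",
]


# ---------------------------------------------------------------------------
# free-energy landscapes and boosted ensembles


@dataclass(frozen=True)
class WellSpec:
    """One Gaussian well of the latent 2D surface."""

    center: tuple[float, float]  # angstrom in CV space
    depth: float  # kcal/mol relative to the deepest well (>= 0)
    width: tuple[float, float] = (0.3, 0.3)  # Gaussian sd per axis, angstrom


@dataclass(frozen=True)
class BoostSpec:
    """aMD-style boost: dV(E) = (Eb - E)^2 / (alpha + Eb - E) below Eb.

    ``e_threshold`` (Eb) is measured from the surface minimum.  The default
    (Eb = 8, alpha = 4.8 kcal/mol) caps the boost at 5 kcal/mol, keeping
    exponential reweighting well-conditioned.
    """

    e_threshold: float = 8.0
    alpha: float = 4.8

    def boost(self, energy: np.ndarray) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        gap = np.maximum(self.e_threshold - e, 0.0)
        return gap * gap / (self.alpha + gap)

    @property
    def max_boost(self) -> float:
        return float(self.boost(np.array(0.0)))


@dataclass
class LandscapeSpec:
    """Latent multi-well surface that an ensemble is drawn from.

    The unbiased density is a Gaussian mixture with component weights
    proportional to exp(-depth / kB T), so two equal-width wells have the
    direct Boltzmann occupancy ratio exp(-(d2-d1) / kB T).
    """

    wells: list[WellSpec]
    temperature: float = DEFAULT_TEMPERATURE_K
    boost: BoostSpec | None = None

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("at least one well required")
        for w in self.wells:
            if w.width[0] <= 0 or w.width[1] <= 0:
                raise ValueError("well widths must be positive")
            if w.depth < 0:
                raise ValueError("well depths must be >= 0")
        if not any(w.depth == 0 for w in self.wells):
            raise ValueError("at least one well must sit at reference depth 0")

    @property
    def kt(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    def component_weights(self) -> np.ndarray:
        w = np.exp(-np.array([wl.depth for wl in self.wells]) / self.kt)
        return w / w.sum()

    def density(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unbiased mixture density at points (x, y)."""
        weights = self.component_weights()
        p = np.zeros_like(np.asarray(x, dtype=float))
        for wl, cw in zip(self.wells, weights):
            sx, sy = wl.width
            p = p + cw * np.exp(
                -0.5 * ((x - wl.center[0]) / sx) ** 2
                - 0.5 * ((y - wl.center[1]) / sy) ** 2
            ) / (2 * math.pi * sx * sy)
        return p

    def energy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """-kT ln density, shifted so the global minimum is ~0."""
        p = self.density(x, y)
        pmax = self.density(
            np.array([w.center[0] for w in self.wells]),
            np.array([w.center[1] for w in self.wells]),
        ).max()
        return -self.kt * np.log(np.maximum(p, 1e-300) / pmax)


def gen_amd_ensemble(
    spec: LandscapeSpec, n_frames: int, seed: int
) -> TrajectoryEnsemble:
    """Sample frames from the (optionally boosted) landscape density.

    Without a boost the frames are exact draws from the Gaussian-mixture
    density and dV = 0.  With a boost the biased density p * exp(-dV/kT)
    is sampled by inverse-CDF on a fine grid (0.02 A cells, uniform jitter
    within a cell) and each frame records the exact dV at its own point,
    so reweighting recovers the unbiased surface.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.boost is None:
        weights = spec.component_weights()
        comp = rng.choice(len(spec.wells), size=n_frames, p=weights)
        cv1 = np.empty(n_frames)
        cv2 = np.empty(n_frames)
        for i, wl in enumerate(spec.wells):
            m = comp == i
            cv1[m] = rng.normal(wl.center[0], wl.width[0], m.sum())
            cv2[m] = rng.normal(wl.center[1], wl.width[1], m.sum())
        dv = np.zeros(n_frames)
        return TrajectoryEnsemble(cv1, cv2, dv, temperature=spec.temperature)

    cell = 0.02
    pad = 5.0
    xs = [w.center[0] for w in spec.wells]
    ys = [w.center[1] for w in spec.wells]
    wmax = max(max(w.width) for w in spec.wells)
    gx = np.arange(min(xs) - pad * wmax, max(xs) + pad * wmax + cell, cell)
    gy = np.arange(min(ys) - pad * wmax, max(ys) + pad * wmax + cell, cell)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    energy = spec.energy(X, Y)
    dv_grid = spec.boost.boost(energy)
    biased = spec.density(X, Y) * np.exp(-dv_grid / spec.kt)
    p = (biased / biased.sum()).ravel()
    idx = rng.choice(p.size, size=n_frames, p=p)
    ix, iy = np.unravel_index(idx, X.shape)
    cv1 = gx[ix] + rng.uniform(-0.5, 0.5, n_frames) * cell
    cv2 = gy[iy] + rng.uniform(-0.5, 0.5, n_frames) * cell
    dv = spec.boost.boost(spec.energy(cv1, cv2))
    return TrajectoryEnsemble(cv1, cv2, dv, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# idealized peptide trajectories


@dataclass
class BondSchedule:
    """Intended bonded state per frame for donor/acceptor residue pairs.

    ``pairs`` maps (donor_resid, acceptor_resid) in 1-based numbering;
    ``states`` holds one boolean array (length n_frames) per pair.
    """

    pairs: list[tuple[int, int]]
    states: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.states):
            raise ValueError("one state sequence required per pair")
        self.states = [np.asarray(s, dtype=bool) for s in self.states]
        lengths = {s.size for s in self.states}
        if len(lengths) > 1:
            raise ValueError("state sequences must share one length")
        donors = [p[0] for p in self.pairs]
        accs = [p[1] for p in self.pairs]
        if len(set(donors + accs)) < len(donors) + len(accs):
            raise ValueError("donor/acceptor residues must be distinct across pairs")

    @property
    def n_frames(self) -> int:
        return int(self.states[0].size) if self.states else 0


# ideal backbone internal coordinates (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-135.0, 135.0)

# scheduled-bond geometry: unambiguously inside the ideal criterion when
# bonded (2.9 A, 165 deg) and outside the relaxed one when not (6.0 A)
_BOND_DIST, _BOND_ANGLE, _UNBOND_DIST = 2.9, 165.0, 6.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF atom placement from three predecessors (angles in degrees)."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_frame(n_res: int, phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O/H coordinates for one frame from dihedrals.

    phi[i] applies for i >= 1, psi[i] for i <= n_res - 2 (0-based).
    """
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        if i < n_res - 1:
            # carbonyl O trans to the next amide N
            O[i] = _place(N[i + 1], CA[i], C[i], 1.231, 120.8, 180.0)
        else:
            O[i] = _place(N[i], CA[i], C[i], 1.231, 120.8, 0.0)
    H = np.zeros((n_res, 3))
    for i in range(1, n_res):
        u = C[i - 1] - O[i - 1]
        H[i] = N[i] + 1.01 * u / np.linalg.norm(u)
    # N-terminal amide H: arbitrary in-plane direction
    u = N[0] - CA[0]
    H[0] = N[0] + 1.01 * u / np.linalg.norm(u)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def gen_mini_protein_trajectory(
    n_residues: int,
    schedule: BondSchedule | None = None,
    helix_truth: list[tuple[int, int] | None] | None = None,
    n_frames: int | None = None,
    seed: int = 0,
) -> md.Trajectory:
    """Idealized multi-model peptide with scheduled bonds and helicity.

    ``helix_truth`` gives per frame the 1-based inclusive residue span
    built with ideal alpha-helical dihedrals (phi = -57, psi = -47); all
    other residues are extended strand.  For every scheduled pair the
    donor residue is a lysine-like residue with a free NZ-HZ1 group and
    the acceptor carries an OE1; in bonded frames OE1 sits 2.9 A from NZ
    at a 165 deg NZ-HZ1-OE1 angle (inside the ideal criterion), and in
    non-bonded frames 6.0 A away (outside even the relaxed criterion).
    """
    if n_residues < 6:
        raise ValueError("need at least 6 residues")
    if schedule is not None and schedule.pairs:
        nf = schedule.n_frames
        if n_frames is not None and n_frames != nf:
            raise ValueError("schedule length does not match n_frames")
    elif helix_truth is not None:
        nf = len(helix_truth)
    elif n_frames is not None:
        nf = n_frames
    else:
        raise ValueError("frame count undetermined: pass n_frames")
    if helix_truth is not None and len(helix_truth) != nf:
        raise ValueError("helix_truth length does not match trajectory length")

    donors = {p[0] for p in schedule.pairs} if schedule else set()
    acceptors = {p[1] for p in schedule.pairs} if schedule else set()

    top = md.Topology()
    chain = top.add_chain()
    elem = md.element
    atom_index: dict[tuple[int, str], int] = {}
    for r in range(1, n_residues + 1):
        resname = "LYS" if r in donors else ("GLU" if r in acceptors else "ALA")
        res = top.add_residue(resname, chain, resSeq=r)
        for name, el in (
            ("N", elem.nitrogen),
            ("H", elem.hydrogen),
            ("CA", elem.carbon),
            ("C", elem.carbon),
            ("O", elem.oxygen),
        ):
            a = top.add_atom(name, el, res)
            atom_index[(r, name)] = a.index
        if r in donors:
            a = top.add_atom("NZ", elem.nitrogen, res)
            atom_index[(r, "NZ")] = a.index
            a = top.add_atom("HZ1", elem.hydrogen, res)
            atom_index[(r, "HZ1")] = a.index
        if r in acceptors:
            a = top.add_atom("OE1", elem.oxygen, res)
            atom_index[(r, "OE1")] = a.index

    n_atoms = top.n_atoms
    xyz = np.zeros((nf, n_atoms, 3))
    for f in range(nf):
        phi = np.full(n_residues, STRAND_PHI_PSI[0])
        psi = np.full(n_residues, STRAND_PHI_PSI[1])
        if helix_truth is not None and helix_truth[f] is not None:
            lo, hi = helix_truth[f]
            phi[lo - 1 : hi] = HELIX_PHI_PSI[0]
            psi[lo - 1 : hi] = HELIX_PHI_PSI[1]
        bb = _backbone_frame(n_residues, phi, psi)
        for r in range(1, n_residues + 1):
            for name in ("N", "H", "CA", "C", "O"):
                xyz[f, atom_index[(r, name)]] = bb[name][r - 1]
        if schedule:
            for (d_res, a_res), states in zip(schedule.pairs, schedule.states):
                ca = bb["CA"][d_res - 1]
                mid = 0.5 * (bb["N"][d_res - 1] + bb["C"][d_res - 1])
                u = ca - mid
                u /= np.linalg.norm(u)
                nz = ca + 3.0 * u
                hz = nz + 1.01 * u
                xyz[f, atom_index[(d_res, "NZ")]] = nz
                xyz[f, atom_index[(d_res, "HZ1")]] = hz
                if states[f]:
                    # direction 15 deg off the NZ->HZ1 axis, at the distance
                    # that puts the acceptor 2.9 A from NZ
                    ref = bb["N"][d_res - 1] - ca
                    w = np.cross(u, ref)
                    w /= np.linalg.norm(w)
                    theta = math.radians(180.0 - _BOND_ANGLE)
                    dvec = math.cos(theta) * u + math.sin(theta) * w
                    cos_t = float(np.dot(u, dvec))
                    rr = -1.01 * cos_t + math.sqrt(
                        (1.01 * cos_t) ** 2 - 1.01**2 + _BOND_DIST**2
                    )
                    oe = hz + rr * dvec
                else:
                    oe = nz + _UNBOND_DIST * u
                xyz[f, atom_index[(a_res, "OE1")]] = oe
    # mdtraj stores nm
    return md.Trajectory(xyz * 0.1, top)


# ---------------------------------------------------------------------------
# spectra, CEST, titrations, HDX


def gen_spectrum(
    peaks: list[tuple[float, float, float, float]],
    noise_sd: float,
    npoints: int,
    sweep: tuple[float, float],
    base_freq_mhz: float,
    seed: int,
    total_area: float = 1.0,
    phase_bound: float = math.pi / 50.0,
) -> Spectrum1D:
    """Sum of phased Lorentzians on a uniform (descending) ppm axis + noise.

    ``peaks``: (shift ppm, FWHM Hz, area fraction, phase rad); fractions
    must sum to 1 (when any peaks are given) and phases respect the bound.
    The noiseless integral over the axis equals ``total_area`` up to the
    truncated Lorentzian tails.
    """
    if npoints < 64:
        raise ValueError("npoints must be >= 64")
    lo, hi = min(sweep), max(sweep)
    if hi <= lo:
        raise ValueError("sweep width must be nonzero")
    if peaks:
        fracs = [p[2] for p in peaks]
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValueError("area fractions must sum to 1")
        for shift, width, _, phase in peaks:
            if width <= 0:
                raise ValueError("peak widths must be positive")
            if abs(phase) > phase_bound + 1e-12:
                raise ValueError(f"|phase| exceeds the bound {phase_bound}")
    rng = np.random.default_rng(seed)
    ppm = np.linspace(hi, lo, npoints)
    y = np.zeros(npoints)
    for shift, width, frac, phase in peaks:
        y += total_area * frac * phased_lorentzian(
            ppm, shift, width, phase, base_freq_mhz
        )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, npoints)
    return Spectrum1D(ppm, y, base_freq_mhz)


def gen_cest_profile(
    kex: float,
    pops: tuple[float, float],
    shifts_hz: tuple[float, float],
    R1: float,
    R2: tuple[float, float],
    sat_offsets_hz: list[float],
    sat_times_s: list[float],
    seed: int,
    w1_hz: float = 25.0,
    noise_sd: float = 0.0,
) -> CESTProfile:
    """Two-state saturation-transfer profile over offset x time conditions.

    Intensities come from the closed-form Bloch–McConnell solution used by
    the fitting stage, normalized to the unsaturated major-state signal;
    optional Gaussian noise is added on top.
    """
    if kex < 0:
        raise ValueError("kex must be >= 0")
    if not math.isclose(sum(pops), 1.0, abs_tol=1e-9):
        raise ValueError("populations must sum to 1")
    if R1 < 0 or min(R2) < 0:
        raise ValueError("relaxation rates must be >= 0")
    rng = np.random.default_rng(seed)
    offs, times = [], []
    for off in sat_offsets_hz:
        for tt in sat_times_s:
            offs.append(off)
            times.append(tt)
    inten = np.array(
        [
            cest_intensity(kex, pops, shifts_hz, R1, R2, o, tt, w1_hz)
            for o, tt in zip(offs, times)
        ]
    )
    if noise_sd > 0:
        inten = inten + rng.normal(0.0, noise_sd, inten.size)
    return CESTProfile(
        np.array(offs), np.array(times), inten, tuple(pops), tuple(shifts_hz),
        tuple(R2), w1_hz,
    )


def gen_titration(
    Kd_nM: float,
    Ab: float,
    Af: float,
    Lst_nM: float,
    Rt_series_nM: list[float],
    noise_sd: float,
    outlier_frac: float,
    seed: int,
) -> tuple[AnisotropyTitration, np.ndarray]:
    """Quadratic-binding titration with optional planted outliers.

    Returns the titration and the ground-truth outlier mask.  Planted
    outliers are displaced by 10x the noise SD (or 0.05 anisotropy units
    for a noiseless series), alternating in sign.
    """
    if Kd_nM <= 0:
        raise ValueError("Kd must be positive")
    if Lst_nM <= 0:
        raise ValueError("probe concentration must be positive")
    if Ab == Af:
        raise ValueError("bound and free anisotropies must differ")
    rt = np.asarray(Rt_series_nM, dtype=float)
    if rt.size == 0:
        raise ValueError("empty titration series")
    rng = np.random.default_rng(seed)
    a = quadratic_binding(rt, Kd_nM, Ab, Af, Lst_nM)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, rt.size)
    flags = np.zeros(rt.size, dtype=bool)
    n_out = int(round(outlier_frac * rt.size))
    if n_out > 0:
        shift = 10.0 * noise_sd if noise_sd > 0 else 0.05
        which = rng.choice(rt.size, size=n_out, replace=False)
        signs = np.where(np.arange(n_out) % 2 == 0, 1.0, -1.0)
        a[which] += signs * shift
        flags[which] = True
    return AnisotropyTitration(rt, a, Lst_nM), flags


@dataclass
class ResidueUptakeTruth:
    """True fractional deuterium uptake per residue and timepoint."""

    timepoints_s: np.ndarray
    uptake: dict[int, np.ndarray]  # residue -> fraction (0-1) per timepoint

    def __post_init__(self) -> None:
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        for r, vals in self.uptake.items():
            vals = np.asarray(vals, dtype=float)
            self.uptake[r] = vals
            if vals.shape != self.timepoints_s.shape:
                raise ValueError(f"residue {r}: uptake/timepoint length mismatch")
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"residue {r}: uptake outside [0, 1]")
            if (np.diff(vals) < -1e-12).any():
                raise ValueError(f"residue {r}: uptake must be nondecreasing in time")


def gen_hdx_dataset(
    truth: ResidueUptakeTruth,
    peptide_map: list[tuple[int, int, str]],
    noise_sd: float,
    recovery: float = 0.70,
    d_content: float = 0.80,
    n_replicates: int = 3,
    seed: int = 0,
) -> HDXPeptideSet:
    """Observed peptide %D from a residue-level truth.

    Each peptide reads the mean truth over its exchange-competent residues
    (excluding its first two residues and prolines) scaled by
    recovery * d_content, expressed in percent, plus replicate noise.
    """
    if not (0 < recovery <= 1) or not (0 < d_content <= 1):
        raise ValueError("recovery and d_content must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for start, end, sequence in peptide_map:
        if len(sequence) != end - start + 1:
            raise ValueError(f"peptide {sequence}: sequence/range length mismatch")
        competent = effective_residues(sequence, start)
        if not competent:
            raise ValueError(f"peptide {sequence} has no competent residues")
        missing = [r for r in competent if r not in truth.uptake]
        if missing:
            raise ValueError(f"peptide {sequence} outside truth range: {missing}")
        base = np.mean([truth.uptake[r] for r in competent], axis=0)
        observed = 100.0 * base * recovery * d_content
        for rep in range(1, n_replicates + 1):
            noisy = observed + (
                rng.normal(0.0, noise_sd, observed.size) if noise_sd > 0 else 0.0
            )
            for tp, val in zip(truth.timepoints_s, noisy):
                rows.append(
                    {
                        "sequence": sequence,
                        "start": start,
                        "end": end,
                        "timepoint_s": float(tp),
                        "replicate": rep,
                        "percentD": float(val),
                    }
                )
    return HDXPeptideSet(pd.DataFrame(rows))
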