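"""Readers and writers for the text formats the pipeline exchanges.

Conventions: CV tables are TSV with unit-bearing column names
(frame, cv1_A, cv2_A, dV_kcal_mol); trajectories are multi-model PDB
(via mdtraj); spectra are two-column (ppm, intensity) text or simple
JCAMP-DX; titrations/HDX/observables are CSV with required unit-bearing
columns; wells and fits are JSON.  Readers refuse files whose headers do
not carry the expected columns and report malformed records with line
numbers rather than skipping them.
"""

from __future__ import annotations

import json
from pathlib import Path

import mdtraj as md
import numpy as np
import pandas as pd

from lbdens.landscape import LandscapeGrid, TrajectoryEnsemble, Well
from lbdens.nmr import Spectrum1D

__all__ = [
    "write_cv_table",
    "read_cv_table",
    "write_trajectory",
    "read_trajectory",
    "write_spectrum",
    "read_spectrum",
    "read_jcamp",
    "write_wells",
    "read_wells",
    "write_landscape",
    "write_json",
    "read_json",
    "read_table",
]

CV_COLUMNS = ("frame", "cv1_A", "cv2_A", "dV_kcal_mol")


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )


def write_cv_table(ensemble: TrajectoryEnsemble, path) -> None:
    df = pd.DataFrame(
        {
            "frame": ensemble.frame_ids,
            "cv1_A": ensemble.cv1,
            "cv2_A": ensemble.cv2,
            "dV_kcal_mol": ensemble.dv,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={ensemble.temperature}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cv_table(path) -> TrajectoryEnsemble:
    temperature = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "temperature_K=" in first:
        temperature = float(first.split("temperature_K=")[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    _check_columns(df, CV_COLUMNS, path)
    bad = df[df[list(CV_COLUMNS[1:])].isna().any(axis=1)]
    if not bad.empty:
        # +2: header line and 1-based counting (comment line adds one more)
        raise ValueError(f"{path}: malformed records at data rows {list(bad.index)}")
    kwargs = {} if temperature is None else {"temperature": temperature}
    return TrajectoryEnsemble(
        df["cv1_A"].to_numpy(),
        df["cv2_A"].to_numpy(),
        df["dV_kcal_mol"].to_numpy(),
        frame_ids=df["frame"].to_numpy(),
        **kwargs,
    )


def write_trajectory(traj: md.Trajectory, path) -> None:
    traj.save_pdb(str(path))


def read_trajectory(path) -> md.Trajectory:
    traj = md.load(str(path))
    for res in traj.topology.residues:
        names = {a.name for a in res.atoms}
        missing = {"N", "CA", "C"} - names
        if missing:
            raise ValueError(
                f"{path}: residue {res.name}{res.resSeq} missing backbone "
                f"atoms {sorted(missing)}"
            )
    return traj


def write_spectrum(spectrum: Spectrum1D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# base_freq_MHz={spectrum.base_freq_mhz}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.17g},{y:.17g}\n")


def read_spectrum(path, base_freq_mhz: float | None = None) -> Spectrum1D:
    """Two-column (ppm, intensity) text; '#' comments may set base_freq_MHz."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "base_freq_MHz=" in first:
        base_freq_mhz = float(first.split("base_freq_MHz=")[1].strip())
    if base_freq_mhz is None:
        raise ValueError(f"{path}: base frequency not in header; pass base_freq_mhz")
    df = pd.read_csv(path, comment="#")
    _check_columns(df, ("ppm", "intensity"), path)
    return Spectrum1D(df["ppm"].to_numpy(), df["intensity"].to_numpy(), base_freq_mhz)


def read_jcamp(path, base_freq_mhz: float | None = None) -> Spectrum1D:
    """Minimal JCAMP-DX reader: X++(Y..Y) tables with FIRSTX/LASTX/NPOINTS."""
    meta: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                if key == "XYDATA":
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                meta[key] = val.strip()
                continue
            if in_table:
                try:
                    vals = [float(v) for v in line.replace(",", " ").split()]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed data line") from exc
                ys.extend(vals[1:])  # first value is the X of the row
    for key in ("FIRSTX", "LASTX", "NPOINTS"):
        if key not in meta:
            raise ValueError(f"{path}: missing ##{key}=")
    npoints = int(float(meta["NPOINTS"]))
    if len(ys) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    if base_freq_mhz is None:
        if ".OBSERVE FREQUENCY" in meta:
            base_freq_mhz = float(meta[".OBSERVE FREQUENCY"])
        else:
            raise ValueError(f"{path}: observe frequency unknown; pass base_freq_mhz")
    x = np.linspace(float(meta["FIRSTX"]), float(meta["LASTX"]), npoints)
    yfactor = float(meta.get("YFACTOR", 1.0))
    return Spectrum1D(x, np.asarray(ys) * yfactor, base_freq_mhz)


def write_wells(wells: list[Well], path) -> None:
    payload = [
        {
            "center_A": list(w.center),
            "index": list(w.index),
            "energy_kcal_mol": w.energy,
        }
        for w in wells
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_wells(path) -> list[Well]:
    payload = json.loads(Path(path).read_text())
    return [
        Well(
            center=tuple(item["center_A"]),
            index=tuple(item["index"]),
            energy=float(item["energy_kcal_mol"]),
        )
        for item in payload
    ]


def write_landscape(grid: LandscapeGrid, path) -> None:
    """Gridded CSV: one row per occupied bin (cv1_A, cv2_A, prob, pmf)."""
    xi, yi = np.nonzero(grid.occupied)
    df = pd.DataFrame(
        {
            "cv1_A": grid.x_centers[xi],
            "cv2_A": grid.y_centers[yi],
            "probability": grid.prob[xi, yi],
            "pmf_kcal_mol": grid.pmf[xi, yi],
        }
    )
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())


def read_table(path, required: tuple[str, ...], sep: str = ",") -> pd.DataFrame:
    """CSV/TSV reader that refuses files without the required unit columns."""
    df = pd.read_csv(path, sep=sep, comment="#")
    _check_columns(df, required, path)
    bad = df[df[list(required)].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(f"{path}: malformed records at data rows {list(bad.index)}")
    return df
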