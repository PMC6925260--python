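"""HDX-MS uptake conversion, back-exchange correction and residue consolidation.

Peptide-level deuterium uptake (from intensity-weighted centroid m/z) is
converted to %D against undeuterated and fully deuterated references,
corrected for back-exchange using the estimated deuterium recovery (0.70)
and the deuterium content of the labeling buffer (0.80), and consolidated
from overlapping peptides to per-residue values.  Consolidation weights
each peptide by the reciprocal of its effective length (residues minus
the first two and any prolines, which carry no observable amide
deuterium), so shorter peptides — which localize uptake better — count
more.  Differential comparisons between two states use an unpaired
two-tailed t test per peptide and timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HDXPeptideSet",
    "ResidueUptake",
    "effective_residues",
    "centroid_to_uptake",
    "back_exchange_correct",
    "consolidate_residues",
    "differential_hdx",
]

#: how far above 100 %D a value may sit (noise) before it is clipped
UPTAKE_TOLERANCE = 5.0

REQUIRED_COLUMNS = ("sequence", "start", "end", "timepoint_s", "replicate", "percentD")


@dataclass
class HDXPeptideSet:
    """Peptide-level %D table.

    ``data`` columns: sequence, start, end (1-based inclusive),
    timepoint_s, replicate, percentD.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peptide table missing columns {missing}")
        bad = self.data["start"] > self.data["end"]
        if bad.any():
            raise ValueError("peptides with start > end")
        if (self.data["timepoint_s"] < 0).any():
            raise ValueError("timepoints must be nonnegative")

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["timepoint_s"].unique())

    def peptides(self) -> pd.DataFrame:
        return (
            self.data[["sequence", "start", "end"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


@dataclass
class ResidueUptake:
    """Consolidated per-residue %D: rows = residue index, cols = timepoint."""

    values: pd.DataFrame
    coverage: pd.Series  # residue -> number of contributing peptides


def effective_residues(sequence: str, start: int) -> list[int]:
    """Exchange-competent residue indices of a peptide.

    Excludes the peptide's first two residues (rapid back-exchange) and
    all prolines (no amide hydrogen).  ``start`` is the 1-based index of
    the peptide's first residue in the protein.
    """
    out = []
    for offset, aa in enumerate(sequence):
        if offset < 2:
            continue
        if aa.upper() == "P":
            continue
        out.append(start + offset)
    return out


def centroid_to_uptake(
    centroid_mz: float, undeut_mz: float, fulldeut_mz: float
) -> float:
    """%D from a peptide's centroid m/z and its two reference centroids."""
    if fulldeut_mz <= undeut_mz:
        raise ValueError("fully deuterated centroid must exceed undeuterated")
    pct = 100.0 * (centroid_mz - undeut_mz) / (fulldeut_mz - undeut_mz)
    return float(np.clip(pct, 0.0, 100.0 + UPTAKE_TOLERANCE))


def back_exchange_correct(
    observed: float | np.ndarray,
    recovery: float = 0.70,
    d_content: float = 0.80,
) -> float | np.ndarray:
    """Correct observed %D for back-exchange and buffer deuterium content.

    corrected = observed / (recovery * d_content); values beyond
    100 + tolerance trigger a warning and are clipped.
    """
    if not (0 < recovery <= 1) or not (0 < d_content <= 1):
        raise ValueError("recovery and d_content must be in (0, 1]")
    corrected = np.asarray(observed, dtype=float) / (recovery * d_content)
    if (corrected > 100.0 + UPTAKE_TOLERANCE).any():
        warnings.warn("corrected uptake exceeds 100%% + tolerance; clipping")
        corrected = np.clip(corrected, None, 100.0 + UPTAKE_TOLERANCE)
    if np.isscalar(observed) or np.ndim(observed) == 0:
        return float(corrected)
    return corrected


def consolidate_residues(peptide_set: HDXPeptideSet) -> ResidueUptake:
    """Residue-averaged %D from overlapping peptides.

    For each residue and timepoint the consolidated value is the weighted
    mean over all covering peptides for which the residue is
    exchange-competent, with weight 1/(effective length).  Residues with
    no coverage are absent from the output, never zero.
    """
    df = peptide_set.data
    # replicate-mean per peptide/timepoint first
    per_pep = (
        df.groupby(["sequence", "start", "end", "timepoint_s"], as_index=False)[
            "percentD"
        ].mean()
    )
    acc: dict[tuple[int, float], list[tuple[float, float]]] = {}
    contributing: dict[int, set[tuple[str, int, int]]] = {}
    for row in per_pep.itertuples(index=False):
        residues = effective_residues(row.sequence, int(row.start))
        if not residues:
            warnings.warn(
                f"peptide {row.sequence} ({row.start}-{row.end}) has zero "
                "effective length; excluded"
            )
            continue
        weight = 1.0 / len(residues)
        for r in residues:
            acc.setdefault((r, row.timepoint_s), []).append((weight, row.percentD))
            contributing.setdefault(r, set()).add(
                (row.sequence, int(row.start), int(row.end))
            )
    if not acc:
        raise ValueError("no peptide contributed any residue")
    residues = sorted({r for r, _ in acc})
    timepoints = sorted({t for _, t in acc})
    values = pd.DataFrame(index=residues, columns=timepoints, dtype=float)
    for (r, t), pairs in acc.items():
        w = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        values.loc[r, t] = float((w * v).sum() / w.sum())
    coverage = pd.Series({r: len(contributing[r]) for r in residues})
    values.index.name = "residue"
    values.columns.name = "timepoint_s"
    return ResidueUptake(values=values, coverage=coverage)


def differential_hdx(
    a: HDXPeptideSet, b: HDXPeptideSet, bh_correct: bool = False
) -> pd.DataFrame:
    """Per-peptide, per-timepoint differential uptake between two states.

    Returns delta = mean(b) - mean(a), the unpaired two-tailed t statistic
    and p value computed on replicate %D values.  Peptides absent from
    either side are dropped (with a warning).  ``bh_correct`` optionally
    adds Benjamini–Hochberg adjusted p values; off by default since
    differential HDX reports conventionally quote raw per-timepoint tests.
    """
    key = ["sequence", "start", "end", "timepoint_s"]
    ga = a.data.groupby(key)["percentD"]
    gb = b.data.groupby(key)["percentD"]
    common = sorted(set(ga.groups) & set(gb.groups))
    if len(common) < len(set(ga.groups) | set(gb.groups)):
        warnings.warn("peptide sets differ; using the intersection")
    if not common:
        raise ValueError("no common peptide/timepoint combinations")
    rows = []
    for k in common:
        va = ga.get_group(k).to_numpy()
        vb = gb.get_group(k).to_numpy()
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"need >= 2 replicates per side for {k}")
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_ind(vb, va, equal_var=True)
        rows.append(
            dict(
                zip(key, k),
                delta_percentD=float(vb.mean() - va.mean()),
                t=float(tstat),
                p=float(p),
            )
        )
    out = pd.DataFrame(rows)
    if bh_correct:
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, out["p"].iloc[idx] * m / rank)
            adj[idx] = prev
        out["p_adj"] = adj
    return out
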