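"""Hot-spot classification, alanine scanning and the burial baseline.

A residue is a *hot spot* when its ensemble-mean contribution to the
effective dimerization energy is below a strict cutoff (default -2 kcal/mol).
*Cold spots* are interface residues (relative burial above a threshold)
whose contribution is only marginal; they serve as negative controls.
The alanine scan truncates one side chain at a time on the fixed ensemble
coordinates (single-trajectory philosophy, no re-minimization) and reports

    ddG = dG_eff(mutant) - dG_eff(wild type)

so that a positive ddG means the mutation destabilizes binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import (
    GBOptions,
    SASAOptions,
    ResidueEnergyTable,
    effective_binding_energy,
    sasa,
)
from .forcefield import (
    ParameterSet,
    ParameterizedSystem,
    assign_parameters,
    build_hydrogens,
    mutate_to_alanine,
)
from .structure import Ensemble

__all__ = [
    "SpotThresholds",
    "HotspotReport",
    "ScanResult",
    "aggregate_ensemble",
    "classify_spots",
    "alanine_scan",
    "relative_burial",
    "export_report",
    "read_report",
]


@dataclass(frozen=True)
class SpotThresholds:
    """Classification thresholds (kcal/mol and relative-burial fraction)."""

    hot_cutoff: float = -2.0  # strict: hot iff mean dG < hot_cutoff
    cold_band: float = 1.0  # cold iff interface and |mean dG| <= cold_band
    interface_burial: float = 0.05  # relative dSASA marking interface residues

    def __post_init__(self) -> None:
        if self.hot_cutoff >= 0:
            raise ValueError("hot_cutoff must be negative")


@dataclass
class HotspotReport:
    """Per-residue classification table.

    Columns: chain, resnum, resname, dg_mean, dg_sem, rel_burial,
    interface, spot_class (hot / cold / neutral).
    """

    table: pd.DataFrame
    thresholds: SpotThresholds

    COLUMNS = ["chain", "resnum", "resname", "dg_mean", "dg_sem", "rel_burial", "interface", "spot_class"]

    def residues_in_class(self, spot_class: str) -> list[tuple[str, int]]:
        sel = self.table[self.table.spot_class == spot_class]
        return list(zip(sel.chain, sel.resnum))


@dataclass
class ScanResult:
    """Alanine-scan table: ddG = dG_eff(mutant) - dG_eff(wild type).

    Positive ddG means truncating the side chain destabilizes binding.
    """

    table: pd.DataFrame  # chain, resnum, resname, ddg_mean, ddg_sem, n_frames


def aggregate_ensemble(table: ResidueEnergyTable, component: str = "total") -> pd.DataFrame:
    """Ensemble mean and SEM per residue.

    SEM is the sample standard deviation over frames divided by sqrt(n);
    it is NaN (undefined) for single-frame tables.
    """
    if len(table.keys) == 0:
        raise ValueError("empty residue energy table")
    return pd.DataFrame(
        {
            "chain": [k[0] for k in table.keys],
            "resnum": [k[1] for k in table.keys],
            "resname": [k[2] for k in table.keys],
            "dg_mean": table.mean(component),
            "dg_sem": table.sem(component),
            "n_frames": table.n_frames,
        }
    )


def relative_burial(
    system: ParameterizedSystem,
    frames: range | list[int] | None = None,
    sasa_options: SASAOptions = SASAOptions(),
) -> pd.DataFrame:
    """Residue-wise relative SASA loss upon complex formation.

    rb_r = (SASA_r(monomer) - SASA_r(complex)) / SASA_r(monomer), with the
    monomer evaluated on the same frame coordinates; averaged over frames.
    Residues whose monomer SASA is below 1 A^2 are flagged undefined (NaN).
    """
    frame_list = list(frames) if frames is not None else list(range(system.n_frames))
    n_res = len(system.residue_keys)
    idx_a = np.flatnonzero(system.side_a_mask)
    idx_b = np.flatnonzero(~system.side_a_mask)
    mono = np.zeros((n_res, len(frame_list)))
    cx = np.zeros((n_res, len(frame_list)))
    for col, k in enumerate(frame_list):
        sa_cx = sasa(system, k, sasa_options)
        sa_mono = np.empty_like(sa_cx)
        for idx in (idx_a, idx_b):
            sa_mono[idx] = sasa(system, k, sasa_options, idx)
        cx[:, col] = np.bincount(system.atom_residue, weights=sa_cx, minlength=n_res)
        mono[:, col] = np.bincount(system.atom_residue, weights=sa_mono, minlength=n_res)
    mono_mean = mono.mean(axis=1)
    cx_mean = cx.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = (mono_mean - cx_mean) / mono_mean
    rb = np.where(mono_mean < 1.0, np.nan, rb)
    return pd.DataFrame(
        {
            "chain": [k[0] for k in system.residue_keys],
            "resnum": [k[1] for k in system.residue_keys],
            "resname": [k[2] for k in system.residue_keys],
            "sasa_monomer": mono_mean,
            "sasa_complex": cx_mean,
            "rel_burial": rb,
        }
    )


def classify_spots(
    aggregated: pd.DataFrame,
    thresholds: SpotThresholds = SpotThresholds(),
    burial: pd.DataFrame | None = None,
) -> HotspotReport:
    """Classify residues as hot, cold or neutral.

    hot: mean dG strictly below ``hot_cutoff``.  cold: interface residue
    (relative burial >= ``interface_burial``) with |mean dG| <= ``cold_band``.
    Classification is row-local: adding or removing residues cannot change
    another residue's class.
    """
    if burial is None:
        raise ValueError("burial table required for cold-spot classification")
    merged = aggregated.merge(
        burial[["chain", "resnum", "rel_burial"]], on=["chain", "resnum"], how="left"
    )
    interface = merged.rel_burial >= thresholds.interface_burial
    hot = merged.dg_mean < thresholds.hot_cutoff
    cold = interface & ~hot & (merged.dg_mean.abs() <= thresholds.cold_band)
    spot_class = np.where(hot, "hot", np.where(cold, "cold", "neutral"))
    table = merged.assign(interface=interface.fillna(False), spot_class=spot_class)
    return HotspotReport(table=table[HotspotReport.COLUMNS + ["n_frames"]], thresholds=thresholds)


def alanine_scan(
    system: ParameterizedSystem,
    positions: list[tuple[str, int]],
    gb_options: GBOptions = GBOptions(),
    sasa_options: SASAOptions = SASAOptions(),
    pset: ParameterSet | None = None,
    frames: range | list[int] | None = None,
) -> ScanResult:
    """In-silico alanine scanning on the fixed ensemble.

    For every position and frame the side chain is truncated at C-beta
    (coordinates otherwise untouched), the mutant is re-parameterized, and
    the full effective binding energy is recomputed; no ledger shortcuts.
    Gly and Pro positions are rejected.
    """
    pset = pset or ParameterSet.default()
    frame_list = list(frames) if frames is not None else list(range(system.n_frames))
    wt = np.array(
        [effective_binding_energy(system, k, gb_options, sasa_options).total for k in frame_list]
    )
    rows = []
    for chain, resnum in positions:
        key = next((k for k in system.residue_keys if k[0] == chain and k[1] == resnum), None)
        if key is None:
            raise ValueError(f"unknown position {chain}{resnum}")
        resname = key[2]
        mut_frames = []
        topo = None
        for k in frame_list:
            s = mutate_to_alanine(system.ensemble.structure_for_frame(k), chain, resnum)
            s = build_hydrogens(s, pset)
            if topo is None:
                topo = s
            mut_frames.append(s.coords())
        mut_ens = Ensemble(topology=topo, frames=mut_frames)
        mut_sys = assign_parameters(mut_ens, pset, system.partition)
        mut = np.array(
            [
                effective_binding_energy(mut_sys, i, gb_options, sasa_options).total
                for i in range(len(frame_list))
            ]
        )
        ddg = mut - wt  # positive destabilizes binding
        sem = np.nan if len(ddg) < 2 else ddg.std(ddof=1) / np.sqrt(len(ddg))
        rows.append(
            {
                "chain": chain,
                "resnum": resnum,
                "resname": resname,
                "ddg_mean": ddg.mean(),
                "ddg_sem": sem,
                "n_frames": len(ddg),
            }
        )
    return ScanResult(table=pd.DataFrame(rows))


def export_report(report: HotspotReport, path) -> None:
    """Write the classification table as TSV (documented column order)."""
    report.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_report(path, thresholds: SpotThresholds = SpotThresholds()) -> HotspotReport:
    table = pd.read_csv(path, sep="\t")
    return HotspotReport(table=table, thresholds=thresholds)
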