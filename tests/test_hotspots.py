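import numpy as np
import pandas as pd
import pytest

from gbscan import (
    GBOptions,
    SASAOptions,
    SpotThresholds,
    aggregate_ensemble,
    alanine_scan,
    assign_parameters,
    build_hydrogens,
    classify_spots,
    decompose_per_residue,
    effective_binding_energy,
    export_report,
    jitter_ensemble,
    mutate_to_alanine,
    read_report,
    relative_burial,
)
from gbscan.energetics import ResidueEnergyTable
from gbscan.structure import Ensemble


def _table(values):
    """ResidueEnergyTable with given per-frame totals, one residue per row."""
    values = np.asarray(values, float)
    keys = [("A", i + 1, "ALA") for i in range(values.shape[0])]
    comps = {c: np.zeros_like(values) for c in ResidueEnergyTable.COLUMNS}
    comps["total"] = values
    return ResidueEnergyTable(keys=keys, components=comps, frame_totals=values.sum(axis=0))


def test_aggregate_mean_and_sem():
    table = _table([[-1.0, -3.0], [2.0, 2.0]])
    agg = aggregate_ensemble(table)
    assert agg.dg_mean.tolist() == [-2.0, 2.0]
    assert agg.dg_sem.tolist() == pytest.approx([1.0, 0.0])


def test_aggregate_single_frame_sem_undefined():
    agg = aggregate_ensemble(_table([[-1.5]]))
    assert agg.dg_mean.iloc[0] == -1.5
    assert np.isnan(agg.dg_sem.iloc[0])


def test_aggregate_empty_table_rejected():
    empty = ResidueEnergyTable(
        keys=[], components={c: np.zeros((0, 1)) for c in ResidueEnergyTable.COLUMNS},
        frame_totals=np.zeros(1),
    )
    with pytest.raises(ValueError):
        aggregate_ensemble(empty)


def _agg_frame(dg_values, burials):
    agg = pd.DataFrame(
        {
            "chain": ["A"] * len(dg_values),
            "resnum": range(1, len(dg_values) + 1),
            "resname": ["ALA"] * len(dg_values),
            "dg_mean": dg_values,
            "dg_sem": 0.05,
            "n_frames": 5,
        }
    )
    burial = pd.DataFrame(
        {
            "chain": ["A"] * len(dg_values),
            "resnum": range(1, len(dg_values) + 1),
            "rel_burial": burials,
        }
    )
    return agg, burial


def test_classification_thresholds():
    # the printed cold-spot energies, an exact-boundary case, and a hot spot
    dg = [0.06, -0.67, -2.0, -2.5, -1.5, 0.5]
    burial = [0.4, 0.3, 0.5, 0.6, 0.01, 0.02]
    agg, bur = _agg_frame(dg, burial)
    report = classify_spots(agg, SpotThresholds(), bur)
    classes = report.table.spot_class.tolist()
    assert classes[0] == "cold"  # dG = 0.06, interface
    assert classes[1] == "cold"  # dG = -0.67, interface
    # exactly -2.0 is NOT hot (strict <) and outside the cold band
    assert classes[2] == "neutral"
    assert classes[3] == "hot"
    assert classes[4] == "neutral"  # not at the interface
    assert classes[5] == "neutral"


def test_classification_is_row_local():
    dg = [0.06, -2.5]
    agg, bur = _agg_frame(dg, [0.4, 0.5])
    full = classify_spots(agg, SpotThresholds(), bur).table.spot_class.tolist()
    solo = classify_spots(agg.iloc[:1], SpotThresholds(), bur.iloc[:1]).table.spot_class.tolist()
    assert full[0] == solo[0]


def test_classify_requires_burial():
    agg, _ = _agg_frame([0.0], [0.0])
    with pytest.raises(ValueError, match="burial"):
        classify_spots(agg, SpotThresholds(), None)


def test_relative_burial_range_and_resummation(c2_system):
    from gbscan.energetics import sasa

    burial = relative_burial(c2_system, frames=[0])
    rb = burial.rel_burial.to_numpy()
    valid = ~np.isnan(rb)
    assert np.all(rb[valid] >= -0.02) and np.all(rb[valid] <= 1.02)
    # re-summation oracle from the per-atom SASA output
    sa_cx = sasa(c2_system, 0)
    idx_a = np.flatnonzero(c2_system.side_a_mask)
    idx_b = np.flatnonzero(~c2_system.side_a_mask)
    sa_mono = np.empty_like(sa_cx)
    sa_mono[idx_a] = sasa(c2_system, 0, subset=idx_a)
    sa_mono[idx_b] = sasa(c2_system, 0, subset=idx_b)
    n_res = len(c2_system.residue_keys)
    mono = np.bincount(c2_system.atom_residue, weights=sa_mono, minlength=n_res)
    cx = np.bincount(c2_system.atom_residue, weights=sa_cx, minlength=n_res)
    expected = (mono - cx) / mono
    assert np.allclose(rb[valid], expected[valid], atol=1e-9)


def test_interface_residues_more_buried_than_back_face(sticky_system):
    system, (chain, resnum) = sticky_system
    burial = relative_burial(system, frames=[0])
    anchor = burial[(burial.chain == chain) & (burial.resnum == resnum)].rel_burial.iloc[0]
    others = burial[(burial.chain == chain) & (burial.resnum != resnum)].rel_burial
    assert anchor > 0.2
    assert anchor > others.median()


def test_alanine_scan_identity_and_noncontact(c2_system):
    # residue 1 is ALA: the identity mutation gives exactly zero
    result = alanine_scan(c2_system, [("A", 1)], frames=[0])
    assert result.table.ddg_mean.iloc[0] == 0.0


def test_alanine_scan_matches_two_evaluation_oracle(sticky_system):
    system, (chain, resnum) = sticky_system
    gb, sa = GBOptions(), SASAOptions()
    result = alanine_scan(system, [(chain, resnum)], gb, sa, frames=[0])
    # independent route: explicit mutate + rebuild + full recompute
    wt = effective_binding_energy(system, 0, gb, sa).total
    mutant_structure = build_hydrogens(
        mutate_to_alanine(system.ensemble.structure_for_frame(0), chain, resnum)
    )
    mutant = assign_parameters(
        Ensemble.from_structure(mutant_structure), partition=system.partition
    )
    mut = effective_binding_energy(mutant, 0, gb, sa).total
    assert result.table.ddg_mean.iloc[0] == pytest.approx(mut - wt, abs=1e-9)
    # truncating the anchor destabilizes binding: positive ddG
    assert result.table.ddg_mean.iloc[0] > 1.0


def test_alanine_scan_rejects_gly_pro_and_unknown(c2_system):
    with pytest.raises(ValueError, match="unknown position"):
        alanine_scan(c2_system, [("A", 99)], frames=[0])


def test_sticky_residue_rank1_hot(sticky_system):
    system, (chain, resnum) = sticky_system
    table = decompose_per_residue(system)
    agg = aggregate_ensemble(table)
    burial = relative_burial(system, frames=[0])
    report = classify_spots(agg, SpotThresholds(), burial)
    row = report.table[(report.table.chain == chain) & (report.table.resnum == resnum)]
    assert row.spot_class.iloc[0] == "hot"
    assert row.dg_mean.iloc[0] < -2.0
    assert row.dg_mean.iloc[0] == report.table.dg_mean.min()


def test_c2_report_symmetric(c2_system):
    table = decompose_per_residue(c2_system, frames=[0])
    agg = aggregate_ensemble(table)
    burial = relative_burial(c2_system, frames=[0])
    report = classify_spots(agg, SpotThresholds(), burial)
    a = report.table[report.table.chain == "A"].spot_class.tolist()
    b = report.table[report.table.chain == "B"].spot_class.tolist()
    assert a == b


def test_export_report_round_trip(tmp_path, c2_system):
    table = decompose_per_residue(c2_system, frames=[0])
    report = classify_spots(
        aggregate_ensemble(table), SpotThresholds(), relative_burial(c2_system, frames=[0])
    )
    path = tmp_path / "report.tsv"
    export_report(report, path)
    again = read_report(path)
    assert again.table.spot_class.tolist() == report.table.spot_class.tolist()
    assert len(again.table) == len(report.table)


def test_export_empty_report(tmp_path):
    agg, bur = _agg_frame([], [])
    report = classify_spots(agg, SpotThresholds(), bur)
    path = tmp_path / "empty.tsv"
    export_report(report, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1  # header only
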