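"""Ensemble I/O, rigid-body superposition, RMSD-from-mean, restraint statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from nmrdyn import (
    AtomSelection,
    Ensemble,
    NoiseSpec,
    classify_restraint,
    make_template_ensemble,
    read_ensemble,
    read_restraints_mr,
    read_restraints_table,
    rmsd_from_mean,
    simulate_ensemble,
    summarize_restraints,
    superpose,
    write_ensemble,
)
from nmrdyn.restraints import RestraintRecord

from oracles import oracle_min_rmsd, oracle_rmsd_from_mean_no_motion


# ---------------------------------------------------------------------------
# I/O


def test_pdb_roundtrip_preserves_roster_and_coords(tmp_path):
    template = make_template_ensemble(8)
    ens = simulate_ensemble(template, 4, 0.3, NoiseSpec(0.0, seed=3))
    path = tmp_path / "ens.pdb"
    write_ensemble(ens, path)
    back = read_ensemble(path)
    assert back.n_models == 4
    assert list(back.atoms["atom_name"]) == list(ens.atoms["atom_name"])
    assert np.allclose(back.coords, ens.coords, atol=2e-3)  # PDB has 3 decimals


def test_single_model_rejected(tmp_path):
    template = make_template_ensemble(5)
    path = tmp_path / "single.pdb"
    write_ensemble(Ensemble(template.atoms, template.coords), path)
    with pytest.raises(ValueError, match="2 models"):
        read_ensemble(path)


def test_atom_missing_from_one_model_dropped_everywhere(tmp_path):
    template = make_template_ensemble(4)
    ens = simulate_ensemble(template, 3, 0.1, NoiseSpec(0.0, seed=4))
    path = tmp_path / "gap.pdb"
    write_ensemble(ens, path)
    # remove one CB line from MODEL 3 only
    lines = path.read_text().splitlines()
    out, model = [], 0
    removed = False
    for ln in lines:
        if ln.startswith("MODEL"):
            model = int(ln.split()[1])
        if (not removed and model == 3 and ln.startswith("ATOM")
                and " CB " in ln and " 2 " in ln):
            removed = True
            continue
        out.append(ln)
    assert removed
    path.write_text("\n".join(out) + "\n")
    back = read_ensemble(path)
    assert back.n_atoms == ens.n_atoms - 1
    cb2 = back.atoms[(back.atoms["atom_name"] == "CB") & (back.atoms["residue"] == 2)]
    assert cb2.empty


def test_heavy_selection_excludes_hydrogens():
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * 4,
            "residue": [1, 1, 1, 1],
            "res_name": ["ALA"] * 4,
            "atom_name": ["N", "CA", "H", "HA"],
            "element": ["N", "C", "H", "H"],
        }
    )
    sel = AtomSelection(mode="heavy")
    assert sel.mask(atoms).sum() == 2


def test_backbone_selection_and_range():
    template = make_template_ensemble(10)
    sel = AtomSelection(mode="backbone", residue_range=(3, 7))
    assert sel.mask(template.atoms).sum() == 5 * 3  # N, CA, C per residue
    sel_o = AtomSelection(mode="backbone", residue_range=(3, 7), include_carbonyl_O=True)
    assert sel_o.mask(template.atoms).sum() == 5 * 4


# ---------------------------------------------------------------------------
# superposition


def test_superpose_identity():
    coords = np.random.default_rng(0).normal(size=(10, 3))
    transform, rmsd = superpose(coords, coords)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(transform.rotation, np.eye(3), atol=1e-10)


def test_superpose_inverts_constructed_rigid_motion():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(12, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90° about z
    moved = ref @ Rz.T + np.array([1.0, 2.0, 3.0])
    transform, rmsd = superpose(moved, ref)
    assert rmsd <= 1e-9
    assert np.allclose(transform.apply(moved), ref, atol=1e-9)
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-12)


def test_superpose_matches_brute_force_search_oracle():
    """Kabsch minimum equals a rotation-search + simplex oracle to 1e-3 Å
    on random 10-atom pairs."""
    rng = np.random.default_rng(2)
    for seed in range(3):
        a = rng.normal(size=(10, 3)) * 3.0
        b = rng.normal(size=(10, 3)) * 3.0
        _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(oracle_min_rmsd(a, b, seed=seed), abs=1e-3)


def test_superposed_rmsd_never_exceeds_raw_rmsd():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.3, size=(15, 3))
        raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        _, fitted = superpose(a, b)
        assert fitted <= raw + 1e-12


def test_collinear_geometry_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)


# ---------------------------------------------------------------------------
# RMSD from mean


def test_identical_models_have_zero_rmsd():
    template = make_template_ensemble(6)
    coords = np.repeat(template.coords, 5, axis=0)
    ens = Ensemble(template.atoms, coords)
    report = rmsd_from_mean(ens, AtomSelection(mode="heavy"))
    assert report.mean == pytest.approx(0.0, abs=1e-10)
    assert report.sd == pytest.approx(0.0, abs=1e-10)


def test_two_model_hand_computed_case():
    """Two models differing only at an atom placed exactly at the centroid
    (so superposition is exactly translation-free in rotation): displacing it
    by 0.6 Å gives per-model RMSD 0.3·√(n−1)/n with n = 4 atoms."""
    base = np.array(
        [[1.0, 0.0, 0.0],
         [-0.5, math.sqrt(3) / 2, 0.0],
         [-0.5, -math.sqrt(3) / 2, 0.0],
         [0.0, 0.0, 0.0]]  # at the centroid of the set
    )
    moved = base.copy()
    moved[3, 2] += 0.6
    atoms = pd.DataFrame(
        {"chain": "A", "residue": [1, 2, 3, 4], "res_name": "ALA",
         "atom_name": ["CA"] * 4, "element": ["C"] * 4}
    )
    ens = Ensemble(atoms, np.stack([base, moved]))
    report = rmsd_from_mean(ens, AtomSelection(mode="heavy"))
    expected = 0.3 * math.sqrt(4 - 1) / 4
    assert report.per_model_rmsd == pytest.approx([expected, expected], abs=1e-9)


def test_rmsd_invariant_under_rigid_motion_of_one_model():
    template = make_template_ensemble(8)
    ens = simulate_ensemble(template, 5, 0.4, NoiseSpec(0.0, seed=5))
    sel = AtomSelection(mode="heavy")
    base_report = rmsd_from_mean(ens, sel)
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    coords = ens.coords.copy()
    coords[2] = coords[2] @ Rz.T + np.array([5.0, -3.0, 11.0])
    moved = Ensemble(ens.atoms, coords)
    moved_report = rmsd_from_mean(moved, sel)
    assert np.allclose(moved_report.per_model_rmsd, base_report.per_model_rmsd, atol=1e-8)


def test_scatter_ensemble_matches_no_motion_oracle():
    """20 models at 0.5 Å scatter: reported RMSD-from-mean within 15% of the
    brute-force mean-deviation oracle applied to the un-rotated copies."""
    template = make_template_ensemble(20)
    rng = np.random.default_rng(17)
    base = template.coords[0]
    scattered = np.array([base + rng.normal(0.0, 0.5, size=base.shape) for _ in range(20)])
    oracle = oracle_rmsd_from_mean_no_motion(scattered)
    # apply random rigid motions to the same scattered copies, then analyse
    from nmrdyn.synthetic import _random_rotation

    moved = np.array(
        [c @ _random_rotation(rng, 180.0).T + rng.uniform(-10, 10, 3) for c in scattered]
    )
    ens = Ensemble(template.atoms, moved)
    report = rmsd_from_mean(ens, AtomSelection(mode="heavy"))
    assert report.mean == pytest.approx(float(oracle.mean()), rel=0.15)
    # closed-form expectation for isotropic scatter: sd·sqrt(3·(1−1/M))
    closed_form = 0.5 * math.sqrt(3.0 * (1.0 - 1.0 / 20.0))
    assert report.mean == pytest.approx(closed_form, rel=0.15)


# ---------------------------------------------------------------------------
# restraints


@pytest.mark.parametrize(
    "i, j, category",
    [(50, 50, "intra"), (50, 51, "sequential"), (51, 50, "sequential"),
     (50, 53, "medium"), (50, 54, "medium"), (50, 55, "long"), (50, 60, "long")],
)
def test_restraint_classification(i, j, category):
    assert classify_restraint(i, j) == category


def test_restraint_summary_partitions_total():
    records = [RestraintRecord(10, 10), RestraintRecord(10, 10),
               RestraintRecord(10, 11), RestraintRecord(13, 14), RestraintRecord(11, 12),
               RestraintRecord(10, 13), RestraintRecord(10, 14), RestraintRecord(14, 10),
               RestraintRecord(10, 20), RestraintRecord(5, 30)]
    counts = summarize_restraints(records)
    assert counts == {"intra": 2, "sequential": 3, "medium": 3, "long": 2, "total": 10}
    assert sum(counts[c] for c in ("intra", "sequential", "medium", "long")) == counts["total"]


def test_empty_restraint_list():
    counts = summarize_restraints([])
    assert counts["total"] == 0 and all(counts[c] == 0 for c in ("intra", "sequential"))


def test_xplor_mr_parser_counts_or_groups_once(tmp_path):
    text = """
assign (resid 12 and name HA)(resid 50 and name HB#) 4.0 2.2 0.5
assign (resid 13 and name HN)(resid 14 and name HA) 3.5 1.7 0.5
assign (resid 20 and name HG#)
       ((resid 80 and name HD#) or (resid 91 and name HE#)) 5.0 3.2 1.0
"""
    path = tmp_path / "test.mr"
    path.write_text(text)
    records = read_restraints_mr(path)
    assert len(records) == 3
    assert [(r.residue_i, r.residue_j) for r in records] == [(12, 50), (13, 14), (20, 80)]
    assert [r.category for r in records] == ["long", "sequential", "long"]


def test_cyana_style_parser(tmp_path):
    text = """# upper distance limits
 12 ALA HA   50 LEU HB2  4.50
 13 GLY HN   14 SER HA   3.20
"""
    path = tmp_path / "test.upl"
    path.write_text(text)
    records = read_restraints_mr(path)
    assert [(r.residue_i, r.residue_j) for r in records] == [(12, 50), (13, 14)]
    assert records[0].bound == pytest.approx(4.5)


def test_tabular_restraint_reader(tmp_path):
    df = pd.DataFrame(
        {"residue_i": [1, 2, 3], "atom_i": ["HA", "HN", "HB"],
         "residue_j": [1, 3, 30], "atom_j": ["HB", "HA", "HN"],
         "upper_bound": [3.0, 4.0, 5.5]}
    )
    path = tmp_path / "restraints.csv"
    df.to_csv(path, index=False)
    records = read_restraints_table(path)
    assert summarize_restraints(records) == {
        "intra": 1, "sequential": 1, "medium": 0, "long": 1, "total": 3
    }
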