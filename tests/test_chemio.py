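import json

import pytest
from rdkit import Chem

import targetfish as tf
from targetfish import chemio


@pytest.fixture
def smi_file(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("CCO ethanol\nc1ccccc1 benzene\nCC(=O)O acetic\n")
    return p


def test_smiles_reader_count_preservation(smi_file):
    mols, report = chemio.read_molecules(smi_file)
    assert len(mols) == 3
    assert report.n_failed == 0
    assert {m.id for m in mols} == {"ethanol", "benzene", "acetic"}


def test_smiles_reader_isolates_failures(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("CCO m1\nC1CC m2\nCCN m3\nCCC m4\nCCCl m5\nCOC m6\n")  # m2 has an open ring
    mols, report = chemio.read_molecules(p)
    assert len(mols) == 5
    assert report.n_failed == 1
    assert report.failures[0][0] == 2  # line index of the bad record


def test_duplicate_ids_are_reported_not_silently_kept(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("CCO a\nCCN a\n")
    mols, report = chemio.read_molecules(p)
    assert len(mols) == 1 and report.n_failed == 1


def test_missing_file_and_zero_parseable_records(tmp_path):
    with pytest.raises(FileNotFoundError):
        chemio.read_molecules(tmp_path / "nope.smi")
    p = tmp_path / "bad.smi"
    p.write_text("notasmiles!!!x x1\n")
    with pytest.raises(ValueError):
        chemio.read_molecules(p)


def test_sdf_and_smiles_agree_on_canonical_structure(tmp_path):
    # same structures through both encodings -> identical canonical SMILES per id
    smiles = {"m1": "OCC", "m2": "c1ccncc1", "m3": "CC(C)CO"}
    smi = tmp_path / "lib.smi"
    smi.write_text("".join(f"{s} {i}\n" for i, s in smiles.items()))
    sdf = tmp_path / "lib.sdf"
    with Chem.SDWriter(str(sdf)) as w:
        for i, s in smiles.items():
            mol = Chem.MolFromSmiles(s)
            mol.SetProp("_Name", i)
            w.write(mol)
    from_smi, _ = chemio.read_molecules(smi, format="smiles")
    from_sdf, _ = chemio.read_molecules(sdf, format="sdf")
    assert {m.id: m.smiles for m in from_smi} == {m.id: m.smiles for m in from_sdf}


def activity_csv(tmp_path, rows, header="compound_id,family_id,activity_type,relation,value,unit,explicit_label"):
    p = tmp_path / "acts.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def test_activity_table_loads_all_eight_types(tmp_path):
    rows = [
        "c1,F1,IC50,=,50,uM,",
        "c2,F1,Ki,=,1,uM,",
        "c3,F1,Kd,<,5,uM,",
        "c4,F1,EC50,=,40,uM,",
        "c5,F1,ED50,=,2,nM,",
        "c6,F1,Potency,=,0.1,mM,",
        "c7,F1,Activity,=,80,percent,",
        "c8,F1,Inhibition,>=,50,percent,active",
    ]
    records, report = chemio.read_activity_table(activity_csv(tmp_path, rows))
    assert len(records) == 8 and report.n_failed == 0
    assert {r.activity_type for r in records} == set(tf.ACTIVITY_TYPES)


def test_unknown_activity_type_excluded_and_reported(tmp_path):
    rows = ["c1,F1,IC50,=,50,uM,", "c2,F1,LogP,=,3,uM,"]
    records, report = chemio.read_activity_table(activity_csv(tmp_path, rows))
    assert len(records) == 1
    assert report.n_failed == 1 and "LogP" in report.failures[0][1]


def test_values_and_units_are_loaded_losslessly(tmp_path):
    rows = ["c1,F1,IC50,=,50,uM,"]
    records, _ = chemio.read_activity_table(activity_csv(tmp_path, rows))
    assert records[0].value == 50.0 and records[0].unit == "uM"


def test_tab_delimiter_autodetected(tmp_path):
    p = tmp_path / "acts.tsv"
    p.write_text("compound_id\tfamily_id\tactivity_type\trelation\tvalue\tunit\n"
                 "c1\tF1\tKi\t=\t10\tnM\n")
    records, _ = chemio.read_activity_table(p)
    assert len(records) == 1 and records[0].unit == "nM"


def test_missing_required_column_raises(tmp_path):
    p = tmp_path / "acts.csv"
    p.write_text("compound_id,activity_type,relation,value,unit\nc1,IC50,=,1,uM\n")
    with pytest.raises(ValueError, match="family_id"):
        chemio.read_activity_table(p)


def test_family_roundtrip_preserves_stage_and_parentage(tmp_path):
    fams = [
        tf.Family("F1.r1", "refined", frozenset({"a", "b"}), parent_id="F1"),
        tf.Family("F1.r2", "refined", frozenset({"c"}), parent_id="F1", target_name="T"),
    ]
    path = tmp_path / "fams.json"
    chemio.write_families(fams, path)
    back = chemio.read_families(path)
    assert sorted(back, key=lambda f: f.family_id) == sorted(fams, key=lambda f: f.family_id)


def test_empty_family_is_unrepresentable():
    with pytest.raises(ValueError):
        tf.Family("F1", "filtered", frozenset())


def test_bulk_family_roundtrip_counts_per_stage(tmp_path):
    fams = []
    for k in range(500):
        fams.append(tf.Family(f"O{k}", "original", frozenset({f"c{k}", f"d{k}"})))
        fams.append(tf.Family(f"O{k}.r1", "refined", frozenset({f"c{k}"}), parent_id=f"O{k}"))
    path = tmp_path / "bulk.json"
    chemio.write_families(fams, path)
    back = chemio.read_families(path)
    for stage in ("original", "refined"):
        assert sum(f.stage == stage for f in back) == sum(f.stage == stage for f in fams)
    assert sorted(f.family_id for f in back) == sorted(f.family_id for f in fams)


def test_malformed_family_file_raises(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text(json.dumps({"not_families": []}))
    with pytest.raises(ValueError):
        chemio.read_families(p)


def test_score_matrix_roundtrip(tmp_path):
    mat = tf.ProfileMatrix(["F1", "F2"], ["c1", "c2", "c3"],
                           [[0.1, 0.5, 1.0], [0.9, 0.0312, 0.7]])
    p = tmp_path / "scores.csv"
    chemio.write_score_matrix(mat, p, meta={"seed": 1})
    back = chemio.read_score_matrix(p)
    assert back.family_ids == mat.family_ids
    assert back.compound_ids == mat.compound_ids
    assert (back.scores == mat.scores).all()


def test_loading_is_deterministic(smi_file):
    a, _ = chemio.read_molecules(smi_file)
    b, _ = chemio.read_molecules(smi_file)
    assert a == b
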