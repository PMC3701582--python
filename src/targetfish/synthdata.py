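"""Self-contained synthetic libraries with planted ground truth.

The generator emulates the structure of a curated bioactivity database
at desk scale: each target family is planted as one or more *scaffold
series* (a ring-system core decorated with a family-specific tail and
an enumerated small substituent), so that within-series Tanimoto
similarity is high and between-series similarity low.  Activity records
are placed explicitly on the active or inactive side of the per-assay
threshold rules, inactive "noise" members are drawn from a shared pool
of unrelated scaffolds (so they also create cross-family compound
sharing), and every generated fact is recorded in a truth object that
downstream recovery tests can check against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .activity_filter import DEFAULT_RULES
from .chemio import write_activity_table, write_molecules
from .models import ACTIVITY_TYPES, ActivityRecord, Molecule, SimilarityMatrix

#: Versioned scaffold vocabulary: (ring-system core, family-specific tail).
#: Cores are distinct ring systems; the tail is shared by every member of
#: one series, so members differ only in a small terminal substituent.
SCAFFOLD_CORES: tuple[tuple[str, str], ...] = (
    ("c1ccc2ccccc2c1", "CCNC(=O)"),
    ("c1ccc2[nH]ccc2c1", "CCOC(=O)"),
    ("c1ccc2ncccc2c1", "CS(=O)(=O)N"),
    ("c1ccoc1", "CCCNC(=O)C"),
    ("c1ccsc1", "CCOCC(=O)O"),
    ("c1ccncc1", "CC(=O)NCC"),
    ("C1CCCCC1", "CCC(=O)OC"),
    ("c1cnc2[nH]ccc2c1", "CCCS(=O)C"),
    ("c1ccc(cc1)O", "CCN(C)C(=O)"),
    ("C1CCNCC1", "CCOC(=O)N"),
    ("c1cc2ccccc2o1", "CCNS(=O)(=O)"),
    ("c1cc2ccccc2s1", "CCC(=O)NC"),
    ("c1ccc2c(c1)cccn2", "CCCOC(=O)"),
    ("C1CCOC1", "CCNC(=O)C"),
    ("c1cnon1", "CCCC(=O)N"),
    ("c1cncnc1", "CCSC(=O)"),
    ("C1CCNC1", "CCCN(C)C(=O)"),
    ("c1ccc2c(c1)OCO2", "CCNC(=S)"),
    ("C1=CC2CCC1CC2", "CCOC(=O)C"),
    ("c1cc[nH]c1", "CCCS(=O)(=O)N"),
    ("C1CCOCC1", "CCN(CC)C(=O)"),
    ("c1ccc2c(c1)ncs2", "CCCNC(=O)"),
    ("c1ccc2c(c1)nco2", "CCSCC(=O)"),
    ("C1CCC2(CC1)CCCCC2", "CCNC(=O)O"),
)

#: Cores for inactive noise members, disjoint from the family scaffolds.
NOISE_CORES: tuple[str, ...] = (
    "OCC(O)C(O)C(O)C(O)C",
    "NCCCCC(N)C",
    "CC(C)CC(N)C",
    "OC(=O)CCCC",
    "NC(=O)CCCC",
    "OCCOCCOCC",
)

#: Enumerated terminal substituents (one per series member).
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "NCC",
    "F", "Cl", "Br", "C(C)C", "CO", "CN", "C(=O)C", "CCO", "CCN", "C(C)(C)C",
    "OCCC", "NCCC", "CCCl", "CCF",
)


@dataclass(frozen=True)
class SynthConfig:
    """Shape of the generated study library.

    Defaults plant three targets of two scaffold series with eight
    members each, plus ~30% structurally unrelated inactive members per
    family — enough members per family that a 10% cross-validation
    holdout is non-trivial, with scaffold counts small enough to keep
    the whole pipeline fast.
    """

    n_families: int = 3
    scaffolds_per_family: int = 2
    members_per_scaffold: int = 8
    inactive_fraction: float = 0.3
    activity_types: tuple[str, ...] = ACTIVITY_TYPES
    noise: float = 0.5  # relative offset of values from each rule threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.scaffolds_per_family, self.members_per_scaffold) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.inactive_fraction <= 1:
            raise ValueError("inactive_fraction must lie in [0, 1]")
        if not 0 < self.noise < 1:
            raise ValueError("noise must lie in (0, 1)")
        unknown = set(self.activity_types) - set(ACTIVITY_TYPES)
        if unknown:
            raise ValueError(f"unknown activity types: {sorted(unknown)}")
        needed = self.n_families * self.scaffolds_per_family
        if needed > len(SCAFFOLD_CORES):
            raise ValueError(
                f"need {needed} scaffolds but the vocabulary holds {len(SCAFFOLD_CORES)}"
            )
        if self.members_per_scaffold > len(SUBSTITUENTS):
            raise ValueError(
                f"at most {len(SUBSTITUENTS)} members per scaffold are enumerable"
            )


@dataclass
class SynthLibrary:
    """A generated library plus its ground truth."""

    molecules: list[Molecule]
    records: list[ActivityRecord]
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "molecules": out / "lib.smi",
            "activities": out / "activities.csv",
            "truth": out / "truth.json",
        }
        write_molecules(self.molecules, paths["molecules"])
        write_activity_table(self.records, paths["activities"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - the vocabulary is fixed and valid
        raise ValueError(f"generated invalid SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def _value_records(
    compound_id: str,
    family_id: str,
    atype: str,
    kind: str,  # active | inactive | indeterminate
    noise: float,
    unit_in_nm: bool,
) -> ActivityRecord:
    rule = DEFAULT_RULES[atype]
    t = rule.threshold_value
    if rule.direction in ("at_most", "less_than"):
        if kind == "active":
            relation, value = "=", t * (1 - noise)
        elif kind == "inactive":
            relation, value = "=", t * (1 + noise)
        else:  # a censored lower bound short of the threshold decides nothing
            relation, value = ">", t * (1 - noise)
        unit = "uM"
        if unit_in_nm:
            value, unit = value * 1e3, "nM"
    else:  # percent rules: active side is above the threshold
        if kind == "active":
            relation, value = "=", t * (1 + noise)
        elif kind == "inactive":
            relation, value = "=", t * (1 - noise)
        else:
            relation, value = "<", t * (1 + noise)
        unit = "percent"
    return ActivityRecord(
        compound_id=compound_id,
        family_id=family_id,
        activity_type=atype,
        relation=relation,
        value=value,
        unit=unit,
        target_name=f"target {family_id}",
    )


def generate_library(config: SynthConfig) -> SynthLibrary:
    """Generate molecules, activity records and ground truth per the config.

    Deterministic for a fixed config (including its seed): two calls
    produce identical objects, and :meth:`SynthLibrary.write` produces
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    molecules: list[Molecule] = []
    records: list[ActivityRecord] = []
    compounds_truth: dict[str, dict] = {}
    scaffold_truth: dict[str, list[str]] = {}
    atype_cycle = 0
    all_inactive = config.inactive_fraction >= 1.0

    n_active_per_family = config.scaffolds_per_family * config.members_per_scaffold
    if all_inactive:
        n_noise = 0
    else:
        f = config.inactive_fraction
        n_noise = round(f / (1 - f) * n_active_per_family)

    for fam_idx in range(config.n_families):
        fid = f"FAM{fam_idx + 1}"
        for s_idx in range(config.scaffolds_per_family):
            core, tail = SCAFFOLD_CORES[fam_idx * config.scaffolds_per_family + s_idx]
            skey = f"{fid}:scaffold{s_idx + 1}"
            scaffold_truth[skey] = []
            for m_idx in range(config.members_per_scaffold):
                cid = f"{fid}S{s_idx + 1}M{m_idx + 1}"
                smiles = _canon(core + tail + SUBSTITUENTS[m_idx])
                molecules.append(Molecule(id=cid, smiles=smiles))
                scaffold_truth[skey].append(cid)
                atype = config.activity_types[atype_cycle % len(config.activity_types)]
                atype_cycle += 1
                kind = "inactive" if all_inactive else "active"
                records.append(
                    _value_records(cid, fid, atype, kind, config.noise, m_idx % 3 == 2)
                )
                if kind == "active" and m_idx % 5 == 4:
                    # conflicting duplicate assay: an inactive record on the
                    # same target must not evict the compound (any-active rule)
                    records.append(
                        _value_records(cid, fid, atype, "inactive", config.noise, False)
                    )
                compounds_truth[cid] = {
                    "families": [fid],
                    "scaffold": skey,
                    "role": "planted",
                    "label": kind,
                }

        subs = rng.permutation(len(SUBSTITUENTS))
        for k in range(n_noise):
            cid = f"{fid}N{k + 1}"
            core = NOISE_CORES[k % len(NOISE_CORES)]
            smiles = _canon(core + SUBSTITUENTS[subs[k % len(SUBSTITUENTS)]])
            molecules.append(Molecule(id=cid, smiles=smiles))
            atype = config.activity_types[atype_cycle % len(config.activity_types)]
            atype_cycle += 1
            kind = "inactive" if k % 2 == 0 else "indeterminate"
            records.append(_value_records(cid, fid, atype, kind, config.noise, False))
            fams = [fid]
            if k % 2 == 1 and config.n_families > 1:
                # share some noise compounds across families, as real
                # databases associate one compound with several targets
                other = f"FAM{(fam_idx + 1) % config.n_families + 1}"
                if other != fid:
                    records.append(
                        _value_records(cid, other, atype, "inactive", config.noise, False)
                    )
                    fams.append(other)
            compounds_truth[cid] = {
                "families": fams,
                "scaffold": None,
                "role": "noise",
                "label": kind,
            }

    truth = {
        "config": asdict(config),
        "compounds": compounds_truth,
        "scaffolds": scaffold_truth,
        "expected": {
            "n_molecules": len(molecules),
            "n_original_families": config.n_families,
            "n_filtered_families": 0 if all_inactive else config.n_families,
            "n_refined_families": 0
            if all_inactive
            else config.n_families * config.scaffolds_per_family,
        },
    }
    return SynthLibrary(molecules=molecules, records=records, truth=truth)


def generate_similarity_fixture(
    blocks: list[tuple[int, float, float]],
    seed: int = 0,
    jitter: float = 0.02,
) -> tuple[SimilarityMatrix, list[int]]:
    """Block-structured similarity matrix with planted labels.

    ``blocks`` lists ``(size, within, between)`` per planted cluster;
    off-diagonal entries get +/- ``jitter`` uniform noise (clipped to
    [0, 1]), the diagonal is exactly 1.  Returns the matrix and the
    planted block label of every item.
    """
    for size, within, between in blocks:
        if size < 1:
            raise ValueError("block sizes must be >= 1")
        if not 0 <= between < within <= 1:
            raise ValueError("need 0 <= between < within <= 1")
    rng = np.random.default_rng(seed)
    labels = [b for b, (size, _, _) in enumerate(blocks) for _ in range(size)]
    n = len(labels)
    sizes = [b[0] for b in blocks]
    values = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = labels[i], labels[j]
            if bi == bj:
                base = blocks[bi][1]
            else:
                base = 0.5 * (blocks[bi][2] + blocks[bj][2])
            v = base + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)
            values[i, j] = values[j, i] = min(1.0, max(0.0, v))
    np.fill_diagonal(values, 1.0)
    ids = [f"b{b}_{k}" for b, size in enumerate(sizes) for k in range(size)]
    return SimilarityMatrix(ids=ids, values=values), labels
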