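"""Reading and writing of conformational ensembles, parameter tables and profiles.

The on-disk formats are deliberately plain text:

* ensembles  -- multi-model PDB (``MODEL``/``ENDMDL`` records),
* force-field parameters -- TSV, one row per atom,
* residue labels -- TSV with a ``#ligand_resname`` directive,
* interaction profiles -- TSV with ``#``-prefixed metadata lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "AtomRecord",
    "ForceFieldParameters",
    "ResidueLabelMap",
    "ConformationEnsemble",
    "InteractionProfile",
    "read_ensemble",
    "read_parameters",
    "read_labels",
    "read_profile",
    "write_profile",
    "subsample",
]

PARAM_COLUMNS = [
    "atom_id",
    "charge",
    "lj_rmin_half",
    "lj_epsilon",
    "gb_radius",
    "gb_screen",
    "atom_type",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom template shared by every snapshot of an ensemble."""

    atom_id: int
    name: str
    residue_key: tuple[str, int, str]  # (chain, resid, resname)
    segment: str  # "receptor" | "ligand"

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValueError(f"atom_id must be >= 1, got {self.atom_id}")
        if self.segment not in ("receptor", "ligand"):
            raise ValueError(f"segment must be receptor/ligand, got {self.segment!r}")


@dataclass
class ForceFieldParameters:
    """Per-atom nonbonded parameters, indexed by atom_id."""

    charge: dict[int, float]
    lj_rmin_half: dict[int, float]
    lj_epsilon: dict[int, float]
    gb_radius: dict[int, float]
    gb_screen: dict[int, float]
    atom_type: dict[int, str]

    def validate_for(self, atom_ids: Iterable[int]) -> None:
        for aid in atom_ids:
            if aid not in self.charge:
                raise KeyError(f"no force-field parameter row for atom_id {aid}")
        for aid, r in self.lj_rmin_half.items():
            if r <= 0:
                raise ValueError(f"lj_rmin_half must be > 0 for atom {aid}")
        for aid, e in self.lj_epsilon.items():
            if e < 0:
                raise ValueError(f"lj_epsilon must be >= 0 for atom {aid}")
        for aid, r in self.gb_radius.items():
            if r <= 0:
                raise ValueError(f"gb_radius must be > 0 for atom {aid}")
        for aid, s in self.gb_screen.items():
            if not (0 < s <= 1.5):
                raise ValueError(f"gb_screen must be in (0, 1.5] for atom {aid}")


@dataclass
class ResidueLabelMap:
    """Mapping from residue keys to display labels plus the ligand residue name.

    Receptor residues without an explicit entry fall back to the
    ``RESNAME+RESID`` convention (e.g. ``PHE183``).
    """

    labels: dict[tuple[str, int, str], str]
    ligand_resname: str

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, int, str]] = {}
        for key, label in self.labels.items():
            if label in seen:
                raise ValueError(
                    f"duplicate residue label {label!r} for {seen[label]} and {key}"
                )
            seen[label] = key

    def label_for(self, residue_key: tuple[str, int, str]) -> str:
        try:
            return self.labels[residue_key]
        except KeyError:
            _, resid, resname = residue_key
            return f"{resname}{resid}"


@dataclass
class ConformationEnsemble:
    """Ordered coordinate snapshots of one receptor-ligand complex."""

    atoms: list[AtomRecord]
    snapshots: np.ndarray  # (n_snapshots, n_atoms, 3)
    params: ForceFieldParameters
    labels: ResidueLabelMap

    def __post_init__(self) -> None:
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        if self.snapshots.ndim != 3 or self.snapshots.shape[2] != 3:
            raise ValueError("snapshots must have shape (n_snapshots, n_atoms, 3)")
        if self.snapshots.shape[0] < 1:
            raise ValueError("ensemble must contain at least one snapshot")
        if self.snapshots.shape[1] != len(self.atoms):
            raise ValueError(
                f"snapshot atom count {self.snapshots.shape[1]} != "
                f"{len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.snapshots)):
            raise ValueError("snapshot coordinates must be finite")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique")
        self.params.validate_for(ids)

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ligand_mask(self) -> np.ndarray:
        return np.array([a.segment == "ligand" for a in self.atoms], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Receptor residue keys in order of first appearance."""
        seen: list[tuple[str, int, str]] = []
        for atom in self.atoms:
            if atom.segment == "receptor" and atom.residue_key not in seen:
                seen.append(atom.residue_key)
        return seen

    def residue_labels(self) -> list[str]:
        return [self.labels.label_for(key) for key in self.residue_keys()]


@dataclass
class InteractionProfile:
    """Per-residue mean ligand interaction energies for one compound."""

    compound_id: str
    receptor_state: str
    energies: dict[str, float]
    n_snapshots: int = 1

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        for label, e in self.energies.items():
            if not math.isfinite(e):
                raise ValueError(f"non-finite energy for residue {label!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_parameters(path: str | Path) -> ForceFieldParameters:
    """Read a flat TSV force-field parameter table (one row per atom)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    if df["atom_id"].duplicated().any():
        dupes = sorted(df.loc[df["atom_id"].duplicated(), "atom_id"])
        raise ValueError(f"duplicate atom_id rows in parameter table: {dupes}")
    ids = df["atom_id"].astype(int).tolist()
    return ForceFieldParameters(
        charge=dict(zip(ids, df["charge"].astype(float))),
        lj_rmin_half=dict(zip(ids, df["lj_rmin_half"].astype(float))),
        lj_epsilon=dict(zip(ids, df["lj_epsilon"].astype(float))),
        gb_radius=dict(zip(ids, df["gb_radius"].astype(float))),
        gb_screen=dict(zip(ids, df["gb_screen"].astype(float))),
        atom_type=dict(zip(ids, df["atom_type"].astype(str))),
    )


def write_parameters(params: ForceFieldParameters, path: str | Path) -> None:
    ids = sorted(params.charge)
    df = pd.DataFrame(
        {
            "atom_id": ids,
            "charge": [params.charge[i] for i in ids],
            "lj_rmin_half": [params.lj_rmin_half[i] for i in ids],
            "lj_epsilon": [params.lj_epsilon[i] for i in ids],
            "gb_radius": [params.gb_radius[i] for i in ids],
            "gb_screen": [params.gb_screen[i] for i in ids],
            "atom_type": [params.atom_type[i] for i in ids],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_labels(path: str | Path) -> ResidueLabelMap:
    """Read the residue-label map.

    Format: optional ``#ligand_resname<TAB>NAME`` directive line, then a
    header ``chain  resid  resname  label`` and one row per labelled residue.
    """
    ligand_resname: str | None = None
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2 and parts[0] == "ligand_resname":
                    ligand_resname = parts[1]
                continue
            if line.strip():
                rows.append(line)
    if ligand_resname is None:
        raise ValueError(f"labels file {path} lacks a '#ligand_resname' directive")
    header, *body = rows
    cols = header.rstrip("\n").split("\t")
    expected = ["chain", "resid", "resname", "label"]
    if cols != expected:
        raise ValueError(f"labels file header must be {expected}, got {cols}")
    labels: dict[tuple[str, int, str], str] = {}
    for line in body:
        chain, resid, resname, label = line.rstrip("\n").split("\t")
        labels[(chain, int(resid), resname)] = label
    return ResidueLabelMap(labels=labels, ligand_resname=ligand_resname)


def write_labels(label_map: ResidueLabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ligand_resname\t{label_map.ligand_resname}\n")
        fh.write("chain\tresid\tresname\tlabel\n")
        for (chain, resid, resname), label in label_map.labels.items():
            fh.write(f"{chain}\t{resid}\t{resname}\t{label}\n")


def _parse_multimodel_pdb(
    pdb_path: str | Path,
) -> tuple[list[tuple[int, str, tuple[str, int, str]]], np.ndarray]:
    """Parse a multi-model PDB into atom templates and a coordinate stack."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ensemble", str(pdb_path))
    models = list(structure)
    if not models:
        raise ValueError(f"no MODEL records found in {pdb_path}")

    templates: list[tuple[int, str, tuple[str, int, str]]] = []
    frames: list[np.ndarray] = []
    for model_index, model in enumerate(models):
        atoms = []
        coords = []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                resid = residue.get_id()[1]
                for atom in residue:
                    atoms.append(
                        (
                            atom.serial_number,
                            atom.get_name(),
                            (chain.get_id(), resid, resname),
                        )
                    )
                    coords.append(atom.get_coord())
        if model_index == 0:
            templates = atoms
        else:
            if len(atoms) != len(templates):
                raise ValueError(
                    f"model {model_index} has {len(atoms)} atoms, "
                    f"expected {len(templates)}"
                )
            if atoms != templates:
                raise ValueError(
                    f"model {model_index} differs in atom ordering from model 0"
                )
        frames.append(np.asarray(coords, dtype=float))
    return templates, np.stack(frames)


def read_ensemble(
    pdb_path: str | Path,
    params_path: str | Path,
    labels_path: str | Path,
) -> ConformationEnsemble:
    """Read a multi-model PDB plus parameter and label tables into an ensemble.

    The ligand is every residue whose name equals the ``ligand_resname``
    declared in the labels file; everything else is receptor.
    """
    templates, frames = _parse_multimodel_pdb(pdb_path)
    params = read_parameters(params_path)
    label_map = read_labels(labels_path)
    atoms = [
        AtomRecord(
            atom_id=serial,
            name=name,
            residue_key=key,
            segment="ligand" if key[2] == label_map.ligand_resname else "receptor",
        )
        for serial, name, key in templates
    ]
    return ConformationEnsemble(
        atoms=atoms, snapshots=frames, params=params, labels=label_map
    )


def write_ensemble_pdb(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB with fixed numeric formatting."""
    with open(path, "w") as fh:
        for frame_index in range(ensemble.n_snapshots):
            fh.write(f"MODEL     {frame_index + 1:4d}\n")
            for atom, xyz in zip(ensemble.atoms, ensemble.snapshots[frame_index]):
                chain, resid, resname = atom.residue_key
                fh.write(
                    f"ATOM  {atom.atom_id:5d} {atom.name:<4s}{resname:>4s} "
                    f"{chain:1s}{resid:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def subsample(ensemble: ConformationEnsemble, stride: int) -> ConformationEnsemble:
    """Evenly subsample snapshots with the given stride, preserving order."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > ensemble.n_snapshots:
        raise ValueError(
            f"stride {stride} exceeds ensemble size {ensemble.n_snapshots}"
        )
    return ConformationEnsemble(
        atoms=ensemble.atoms,
        snapshots=ensemble.snapshots[::stride].copy(),
        params=ensemble.params,
        labels=ensemble.labels,
    )


def write_profile(profile: InteractionProfile, path: str | Path) -> None:
    """Write an interaction profile as TSV, residues ordered by label."""
    if not profile.energies:
        raise ValueError("cannot write an empty profile")
    with open(path, "w") as fh:
        fh.write(f"#compound_id\t{profile.compound_id}\n")
        fh.write(f"#receptor_state\t{profile.receptor_state}\n")
        fh.write(f"#n_snapshots\t{profile.n_snapshots}\n")
        fh.write("residue\tenergy\n")
        for label in sorted(profile.energies):
            fh.write(f"{label}\t{profile.energies[label]:.9f}\n")


def read_profile(path: str | Path) -> InteractionProfile:
    meta: dict[str, str] = {}
    energies: dict[str, float] = {}
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("\t")
            meta[key] = value
        else:
            body.append(line)
    if not body or body[0].rstrip("\n").split("\t") != ["residue", "energy"]:
        raise ValueError(f"profile file {path} lacks a 'residue\\tenergy' header")
    for line in body[1:]:
        label, value = line.rstrip("\n").split("\t")
        if label in energies:
            raise ValueError(f"duplicate residue label {label!r} in {path}")
        energies[label] = float(value)
    if not energies:
        raise ValueError(f"profile file {path} contains no residues")
    return InteractionProfile(
        compound_id=meta.get("compound_id", "unknown"),
        receptor_state=meta.get("receptor_state", "other"),
        energies=energies,
        n_snapshots=int(meta.get("n_snapshots", 1)),
    )
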