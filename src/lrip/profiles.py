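"""Interaction profiles, reference signatures and profile-similarity metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .complex_io import InteractionProfile
from .energetics import ResidueEnergyRow

__all__ = [
    "SignatureProfile",
    "SimilarityScores",
    "KEY_RESIDUE_THRESHOLD",
    "build_profile",
    "select_key_residues",
    "build_signature",
    "similarity",
    "read_signature",
    "write_signature",
]

#: a residue is "key" when its mean interaction energy is at least this
#: favourable (more negative or equal)
KEY_RESIDUE_THRESHOLD = -0.1  # kcal/mol


@dataclass
class SignatureProfile:
    """Mean reference interaction profile for one (receptor, state) pair."""

    receptor_state: str
    residues: list[str]
    mean_energy: np.ndarray
    sd_energy: np.ndarray
    reference_ids: list[str]

    def __post_init__(self) -> None:
        self.mean_energy = np.asarray(self.mean_energy, dtype=float)
        self.sd_energy = np.asarray(self.sd_energy, dtype=float)
        if len(self.residues) == 0:
            raise ValueError("signature must cover at least one residue")
        if len(self.residues) != len(self.mean_energy) or len(self.residues) != len(
            self.sd_energy
        ):
            raise ValueError("residues, mean_energy and sd_energy must align")
        if np.any(self.sd_energy < 0):
            raise ValueError("sd_energy must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.residues, self.mean_energy))


@dataclass(frozen=True)
class SimilarityScores:
    """The four profile-similarity metrics plus the correlation itself."""

    r: float
    r2: float
    rmse: float
    aue: float
    ase: float
    n_residues: int
    r_defined: bool = True


def build_profile(
    rows: Sequence[Sequence[ResidueEnergyRow]],
    compound_id: str,
    receptor_state: str = "other",
) -> InteractionProfile:
    """Average per-snapshot residue rows into an interaction profile.

    Uniform snapshot weights; every snapshot must cover the same residues.
    """
    if len(rows) < 1:
        raise ValueError("need at least one snapshot of residue rows")
    reference_labels = [row.label for row in rows[0]]
    reference_set = set(reference_labels)
    sums = {label: 0.0 for label in reference_labels}
    for snapshot_rows in rows:
        labels = {row.label for row in snapshot_rows}
        if labels != reference_set:
            diff = sorted(labels.symmetric_difference(reference_set))
            raise ValueError(f"inconsistent residue labels across snapshots: {diff}")
        for row in snapshot_rows:
            sums[row.label] += row.total
    n = len(rows)
    return InteractionProfile(
        compound_id=compound_id,
        receptor_state=receptor_state,
        energies={label: sums[label] / n for label in reference_labels},
        n_snapshots=n,
    )


def select_key_residues(
    profile: InteractionProfile, threshold: float = KEY_RESIDUE_THRESHOLD
) -> list[str]:
    """Residues interacting at least as favourably as the threshold.

    "Stronger" means more negative; the boundary value is included.
    Result is sorted by label.
    """
    if not profile.energies:
        raise ValueError("profile is empty")
    return sorted(
        label for label, e in profile.energies.items() if e <= threshold
    )


def build_signature(
    reference_profiles: Sequence[InteractionProfile],
    residue_rule: Literal["union", "intersection"] = "union",
    sd_cap: float | None = None,
) -> SignatureProfile:
    """Average key-residue energies of reference ligands into a signature.

    The residue set is the per-reference key residues combined by
    ``residue_rule``; a residue missing from a reference contributes
    0.0 kcal/mol.  With ``sd_cap`` set, residues whose sample standard
    deviation across references exceeds the cap are dropped.
    """
    if len(reference_profiles) < 1:
        raise ValueError("need at least one reference profile")
    states = {p.receptor_state for p in reference_profiles}
    if len(states) > 1:
        raise ValueError(f"mixed receptor states in reference set: {sorted(states)}")

    key_sets = [set(select_key_residues(p)) for p in reference_profiles]
    if residue_rule == "union":
        residues = set().union(*key_sets)
    elif residue_rule == "intersection":
        residues = set.intersection(*key_sets)
    else:
        raise ValueError(f"unknown residue_rule {residue_rule!r}")
    residues = sorted(residues)
    if not residues:
        raise ValueError("signature residue set is empty")

    values = np.array(
        [[p.energies.get(label, 0.0) for label in residues] for p in reference_profiles]
    )
    mean = values.mean(axis=0)
    sd = (
        values.std(axis=0, ddof=1)
        if len(reference_profiles) > 1
        else np.zeros(len(residues))
    )
    if sd_cap is not None:
        keep = sd <= sd_cap
        if not keep.any():
            raise ValueError("sd_cap removed every signature residue")
        residues = [label for label, k in zip(residues, keep) if k]
        mean, sd = mean[keep], sd[keep]
    return SignatureProfile(
        receptor_state=reference_profiles[0].receptor_state,
        residues=list(residues),
        mean_energy=mean,
        sd_energy=sd,
        reference_ids=[p.compound_id for p in reference_profiles],
    )


def similarity(
    query: InteractionProfile, signature: SignatureProfile
) -> SimilarityScores:
    """The four profile-similarity metrics over the signature's residue list.

    Signature residues absent from the query contribute 0.0 kcal/mol.
    If either vector has zero variance the correlation is undefined and
    the result is flagged (``r_defined=False``, r = nan).
    """
    if len(signature.residues) < 3:
        raise ValueError("signature must cover at least 3 residues")
    x = np.array([query.energies.get(label, 0.0) for label in signature.residues])
    y = signature.mean_energy
    diff = x - y
    ase = float(diff.mean())
    aue = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return SimilarityScores(
            r=float("nan"),
            r2=float("nan"),
            rmse=rmse,
            aue=aue,
            ase=ase,
            n_residues=len(x),
            r_defined=False,
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return SimilarityScores(
        r=r, r2=r * r, rmse=rmse, aue=aue, ase=ase, n_residues=len(x)
    )


def write_signature(signature: SignatureProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#receptor_state\t{signature.receptor_state}\n")
        fh.write(f"#reference_ids\t{','.join(signature.reference_ids)}\n")
        fh.write("residue\tmean_energy\tsd_energy\n")
        for label, m, s in zip(
            signature.residues, signature.mean_energy, signature.sd_energy
        ):
            fh.write(f"{label}\t{m:.9f}\t{s:.9f}\n")


def read_signature(path) -> SignatureProfile:
    meta: dict[str, str] = {}
    residues: list[str] = []
    means: list[float] = []
    sds: list[float] = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("\t")
            meta[key] = value
        else:
            body.append(line)
    header = body[0].rstrip("\n").split("\t") if body else []
    if header != ["residue", "mean_energy", "sd_energy"]:
        raise ValueError(f"bad signature header in {path}: {header}")
    for line in body[1:]:
        label, m, s = line.rstrip("\n").split("\t")
        residues.append(label)
        means.append(float(m))
        sds.append(float(s))
    refs = [r for r in meta.get("reference_ids", "").split(",") if r]
    return SignatureProfile(
        receptor_state=meta.get("receptor_state", "other"),
        residues=residues,
        mean_energy=np.array(means),
        sd_energy=np.array(sds),
        reference_ids=refs,
    )
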