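"""Molecular-mechanics and implicit-solvent energies with per-residue decomposition.

All energies are in kcal/mol, distances in Angstrom, charges in elementary
charge units.  Sums are exact O(N^2) over intermolecular pairs: no cutoffs,
no periodicity, no bonded terms (internal terms cancel in the
single-trajectory protocol and never enter ligand-residue rows).

The polar solvation term uses the Hawkins-Cramer-Truhlar pairwise
descreening model for effective Born radii combined with the Still
interpolation formula.  The nonpolar term is a linear function of
solvent-accessible surface area computed with a deterministic
Shrake-Rupley sphere lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .complex_io import ConformationEnsemble

__all__ = [
    "GBSettings",
    "EnergyComponents",
    "ResidueEnergyRow",
    "coulomb_pair",
    "lj_pair",
    "effective_born_radii",
    "gb_polar_energy",
    "sasa",
    "decompose_ligand_residue",
]

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)


@dataclass(frozen=True)
class GBSettings:
    """Dielectric, surface-area and lattice settings for the implicit solvent."""

    eps_in: float = 1.0
    eps_out: float = 78.5
    coulomb_k: float = COULOMB_K
    sasa_gamma: float = 0.0072  # kcal/(mol*A^2)
    sasa_beta: float = 0.0  # kcal/mol
    probe_radius: float = 1.4  # A
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.sasa_points < 1:
            raise ValueError("sasa_points must be >= 1")


@dataclass(frozen=True)
class EnergyComponents:
    ele: float
    vdw: float
    gb_polar: float
    nonpolar: float

    @property
    def total(self) -> float:
        return self.ele + self.vdw + self.gb_polar + self.nonpolar


@dataclass(frozen=True)
class ResidueEnergyRow:
    """Decomposed ligand interaction energy for one receptor residue."""

    label: str
    ele: float
    vdw: float
    gb_polar: float
    nonpolar: float

    @property
    def total(self) -> float:
        return self.ele + self.vdw + self.gb_polar + self.nonpolar


def coulomb_pair(
    qi: float, qj: float, rij: float, eps_in: float = 1.0, k: float = COULOMB_K
) -> float:
    """Coulomb interaction energy of one atom pair: k*qi*qj/(eps_in*rij)."""
    if rij <= 0:
        raise ValueError(f"overlapping atoms: rij = {rij}")
    return k * qi * qj / (eps_in * rij)


def lj_pair(
    rmin_half_i: float,
    eps_i: float,
    rmin_half_j: float,
    eps_j: float,
    rij: float,
) -> float:
    """12-6 Lennard-Jones energy with Rmin_ij = Rmin/2_i + Rmin/2_j and
    eps_ij = sqrt(eps_i*eps_j); minimum value -eps_ij at rij = Rmin_ij."""
    if rij <= 0:
        raise ValueError(f"overlapping atoms: rij = {rij}")
    rmin = rmin_half_i + rmin_half_j
    eps = np.sqrt(eps_i * eps_j)
    x6 = (rmin / rij) ** 6
    return eps * (x6 * x6 - 2.0 * x6)


def _hct_descreen_term(rho_i: float, r: float, s_j: float) -> float:
    """Analytic pairwise-descreening integral of atom j (scaled radius s_j)
    against atom i (intrinsic radius rho_i) at separation r.

    Equals (1/4pi) * integral of |x - x_i|^-4 over the part of sphere j
    lying outside the intrinsic sphere of atom i.  Units: 1/A.
    """
    if r + s_j <= rho_i:
        return 0.0  # sphere j fully buried inside atom i
    lower = max(rho_i, abs(r - s_j))
    upper = r + s_j
    inv_l = 1.0 / lower
    inv_u = 1.0 / upper
    term = (
        inv_l
        - inv_u
        + (r / 4.0) * (inv_u**2 - inv_l**2)
        + (1.0 / (2.0 * r)) * np.log(lower / upper)
        + (s_j**2 / (4.0 * r)) * (inv_l**2 - inv_u**2)
    )
    term *= 0.5
    if rho_i < s_j - r:
        # atom i engulfed by the scaled sphere of j: shells between
        # rho_i and s_j - r are fully covered
        term += 1.0 / rho_i - 1.0 / (s_j - r)
    return term


def effective_born_radii(
    coords: np.ndarray,
    gb_radius: np.ndarray,
    gb_screen: np.ndarray,
) -> np.ndarray:
    """Hawkins-Cramer-Truhlar effective Born radii for one snapshot.

    1/R_eff_i = 1/rho_i - sum_{j != i} H(rho_i, r_ij, screen_j*rho_j).
    An isolated atom keeps its intrinsic radius.
    """
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(gb_radius, dtype=float)
    scaled = np.asarray(gb_screen, dtype=float) * rho
    n = len(rho)
    inv_eff = 1.0 / rho.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            inv_eff[i] -= _hct_descreen_term(rho[i], r, scaled[j])
    if np.any(inv_eff <= 0):
        bad = int(np.argmax(inv_eff <= 0))
        raise ValueError(
            f"nonpositive effective Born radius computed for atom index {bad}"
        )
    return 1.0 / inv_eff


def _f_gb(r: np.ndarray, ri: np.ndarray, rj: np.ndarray) -> np.ndarray:
    rirj = ri * rj
    return np.sqrt(r * r + rirj * np.exp(-(r * r) / (4.0 * rirj)))


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    gb_radius: np.ndarray,
    gb_screen: np.ndarray,
    settings: GBSettings = GBSettings(),
    effective_radii: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Still-form generalized-Born polar solvation energy.

    Returns ``(total, pair_matrix)`` where ``pair_matrix`` is symmetric;
    its diagonal holds the self terms and each off-diagonal entry holds
    the FULL unordered-pair cross term, so
    ``total = trace + sum of strict upper triangle``.
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    if effective_radii is None:
        effective_radii = effective_born_radii(coords, gb_radius, gb_screen)
    reff = np.asarray(effective_radii, dtype=float)
    prefactor = -settings.coulomb_k * (1.0 / settings.eps_in - 1.0 / settings.eps_out)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    fgb = _f_gb(r, reff[:, None], reff[None, :])
    np.fill_diagonal(fgb, reff)  # f_GB(i, i) = R_eff_i
    matrix = prefactor * np.outer(q, q) / fgb
    np.fill_diagonal(matrix, 0.5 * np.diag(matrix))
    total = float(np.trace(matrix) + np.triu(matrix, k=1).sum())
    return total, matrix


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    sasa_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    Deterministic for a fixed ``sasa_points`` lattice; areas are >= 0 and
    converge to the closed-form sphere area as the lattice is refined.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    expanded = radii + probe_radius
    lattice = _sphere_lattice(sasa_points)
    n = len(radii)
    areas = np.empty(n)
    for i in range(n):
        points = coords[i] + expanded[i] * lattice
        accessible = np.ones(sasa_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def _ensemble_arrays(
    ensemble: ConformationEnsemble,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ids = [a.atom_id for a in ensemble.atoms]
    p = ensemble.params
    q = np.array([p.charge[i] for i in ids])
    rmh = np.array([p.lj_rmin_half[i] for i in ids])
    eps = np.array([p.lj_epsilon[i] for i in ids])
    rho = np.array([p.gb_radius[i] for i in ids])
    screen = np.array([p.gb_screen[i] for i in ids])
    return q, rmh, eps, rho, screen


def _pairwise_mm(
    coords: np.ndarray,
    q: np.ndarray,
    rmh: np.ndarray,
    eps: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    eps_in: float,
    k: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coulomb and LJ energy matrices restricted to mask_a x mask_b pairs."""
    ca, cb = coords[mask_a], coords[mask_b]
    diff = ca[:, None, :] - cb[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r <= 0):
        raise ValueError("overlapping atoms between ligand and receptor")
    ele = k * np.outer(q[mask_a], q[mask_b]) / (eps_in * r)
    rmin = rmh[mask_a][:, None] + rmh[mask_b][None, :]
    epsij = np.sqrt(np.outer(eps[mask_a], eps[mask_b]))
    x6 = (rmin / r) ** 6
    vdw = epsij * (x6 * x6 - 2.0 * x6)
    return ele, vdw


def decompose_ligand_residue(
    ensemble: ConformationEnsemble,
    settings: GBSettings = GBSettings(),
    include_nonpolar: bool = False,
) -> list[list[ResidueEnergyRow]]:
    """Per-snapshot ligand-residue energy decomposition.

    For each receptor residue: Coulomb and LJ sums over ligand x residue
    atom pairs, the full GB cross terms for those pairs (each unordered
    pair counted once), and optionally a desolvation-style nonpolar term
    gamma * sum_{j in residue} [SASA_j(receptor alone) - SASA_j(complex)].
    Receptor-receptor and ligand-internal terms are excluded throughout.
    """
    lig_mask = ensemble.ligand_mask
    if not lig_mask.any():
        raise ValueError("ensemble has no ligand atoms")
    rec_mask = ~lig_mask
    q, rmh, eps, rho, screen = _ensemble_arrays(ensemble)

    residue_keys = ensemble.residue_keys()
    atom_keys = [a.residue_key for a in ensemble.atoms]
    residue_atom_idx = {
        key: np.array(
            [i for i, k in enumerate(atom_keys) if k == key and rec_mask[i]]
        )
        for key in residue_keys
    }
    lig_idx = np.flatnonzero(lig_mask)
    rec_idx = np.flatnonzero(rec_mask)
    rec_pos = {int(g): i for i, g in enumerate(rec_idx)}

    per_snapshot: list[list[ResidueEnergyRow]] = []
    for coords in ensemble.snapshots:
        ele_m, vdw_m = _pairwise_mm(
            coords, q, rmh, eps, lig_mask, rec_mask, settings.eps_in, settings.coulomb_k
        )
        _, gb_matrix = gb_polar_energy(coords, q, rho, screen, settings)
        if include_nonpolar:
            areas_complex = sasa(
                coords, rho, settings.probe_radius, settings.sasa_points
            )
            areas_receptor = sasa(
                coords[rec_mask],
                rho[rec_mask],
                settings.probe_radius,
                settings.sasa_points,
            )
        rows: list[ResidueEnergyRow] = []
        for key in residue_keys:
            res_idx = residue_atom_idx[key]
            cols = np.array([rec_pos[int(g)] for g in res_idx])
            ele = float(ele_m[:, cols].sum())
            vdw = float(vdw_m[:, cols].sum())
            gb = float(gb_matrix[np.ix_(lig_idx, res_idx)].sum())
            nonpolar = 0.0
            if include_nonpolar:
                buried = sum(
                    areas_receptor[rec_pos[int(g)]] - areas_complex[int(g)]
                    for g in res_idx
                )
                nonpolar = settings.sasa_gamma * float(buried)
            rows.append(
                ResidueEnergyRow(
                    label=ensemble.labels.label_for(key),
                    ele=ele,
                    vdw=vdw,
                    gb_polar=gb,
                    nonpolar=nonpolar,
                )
            )
        per_snapshot.append(rows)
    return per_snapshot
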