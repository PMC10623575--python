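"""End-point binding free energies from snapshot ensembles.

Single-trajectory protocol: for each retained snapshot every component is
E(complex) - E(receptor alone) - E(ligand alone) on identical coordinates,
so internal bonded terms cancel and only intermolecular plus desolvation
contributions survive.  The entropy change on binding is estimated with a
pluggable weighted-SASA linear model evaluated on its own subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complex_io import ConformationEnsemble
from .energetics import (
    GBSettings,
    _ensemble_arrays,
    effective_born_radii,
    gb_polar_energy,
    sasa,
)

__all__ = [
    "EnergyReport",
    "WsasWeights",
    "binding_energy",
    "classify_energy_gate",
]

DE_GATE_THRESHOLD = -10.0  # kcal/mol


@dataclass(frozen=True)
class EnergyReport:
    """Decomposed binding-energy components (ensemble means)."""

    de_ele: float
    de_vdw: float
    dg_polar: float
    dg_nonpolar: float
    tds: float
    n_snapshots_de: int
    n_snapshots_tds: int
    polar_method: str = "GB(HCT)"

    @property
    def de_total(self) -> float:
        return self.de_ele + self.de_vdw + self.dg_polar + self.dg_nonpolar

    @property
    def dg_total(self) -> float:
        return self.de_total - self.tds


@dataclass(frozen=True)
class WsasWeights:
    """Linear SASA entropy model: S = sum_atoms w(atom_type)*SASA + intercept."""

    weights: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    temperature: float = 298.15

    def weight_for(self, atom_type: str) -> float:
        return self.weights.get(atom_type, 0.0)


def _mm_total(coords, q, rmh, eps, eps_in, k) -> tuple[float, float]:
    """Total Coulomb + LJ over all unordered pairs within one atom set."""
    n = len(q)
    if n < 2:
        return 0.0, 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if np.any(rij <= 0):
        raise ValueError("overlapping atoms")
    ele = float(np.sum(k * np.outer(q, q)[iu] / (eps_in * rij)))
    rmin = (rmh[:, None] + rmh[None, :])[iu]
    epsij = np.sqrt(np.outer(eps, eps))[iu]
    x6 = (rmin / rij) ** 6
    vdw = float(np.sum(epsij * (x6 * x6 - 2.0 * x6)))
    return ele, vdw


def _wsas_entropy(
    coords: np.ndarray,
    radii: np.ndarray,
    atom_types: list[str],
    weights: WsasWeights,
    settings: GBSettings,
) -> float:
    areas = sasa(coords, radii, settings.probe_radius, settings.sasa_points)
    w = np.array([weights.weight_for(t) for t in atom_types])
    return float(np.dot(w, areas) + weights.intercept)


def binding_energy(
    ensemble: ConformationEnsemble,
    settings: GBSettings = GBSettings(),
    stride_de: int = 1,
    stride_tds: int = 25,
    weights: WsasWeights = WsasWeights(),
) -> EnergyReport:
    """MM-GBSA binding energy plus weighted-SASA entropy over subsamples.

    ``stride_de`` selects the snapshots used for the energy components and
    ``stride_tds`` those for the entropy term (both evenly spaced from the
    start of the ensemble).
    """
    n = ensemble.n_snapshots
    for name, stride in (("stride_de", stride_de), ("stride_tds", stride_tds)):
        if stride < 1:
            raise ValueError(f"{name} must be >= 1")
        if stride > n:
            raise ValueError(f"{name}={stride} exceeds ensemble size {n}")

    lig = ensemble.ligand_mask
    rec = ~lig
    if not lig.any():
        raise ValueError("ensemble has no ligand atoms")
    q, rmh, eps, rho, screen = _ensemble_arrays(ensemble)
    ids = [a.atom_id for a in ensemble.atoms]
    atom_types = [ensemble.params.atom_type[i] for i in ids]

    de_frames = ensemble.snapshots[::stride_de]
    comp_sums = np.zeros(4)  # ele, vdw, polar, nonpolar
    for coords in de_frames:
        parts = []
        for mask in (np.ones(len(q), dtype=bool), rec, lig):
            c = coords[mask]
            ele, vdw = _mm_total(
                c, q[mask], rmh[mask], eps[mask], settings.eps_in, settings.coulomb_k
            )
            gb, _ = gb_polar_energy(c, q[mask], rho[mask], screen[mask], settings)
            areas = sasa(c, rho[mask], settings.probe_radius, settings.sasa_points)
            nonpolar = settings.sasa_gamma * float(areas.sum()) + settings.sasa_beta
            parts.append(np.array([ele, vdw, gb, nonpolar]))
        comp_sums += parts[0] - parts[1] - parts[2]
    comp_means = comp_sums / len(de_frames)

    tds_frames = ensemble.snapshots[::stride_tds]
    tds_sum = 0.0
    if weights.weights or weights.intercept != 0.0:
        for coords in tds_frames:
            s_complex = _wsas_entropy(coords, rho, atom_types, weights, settings)
            s_receptor = _wsas_entropy(
                coords[rec], rho[rec], [t for t, m in zip(atom_types, rec) if m],
                weights, settings,
            )
            s_ligand = _wsas_entropy(
                coords[lig], rho[lig], [t for t, m in zip(atom_types, lig) if m],
                weights, settings,
            )
            tds_sum += s_complex - s_receptor - s_ligand

    return EnergyReport(
        de_ele=float(comp_means[0]),
        de_vdw=float(comp_means[1]),
        dg_polar=float(comp_means[2]),
        dg_nonpolar=float(comp_means[3]),
        tds=tds_sum / len(tds_frames),
        n_snapshots_de=len(de_frames),
        n_snapshots_tds=len(tds_frames),
    )


def classify_energy_gate(
    report: EnergyReport, threshold: float = DE_GATE_THRESHOLD
) -> bool:
    """True iff the binding energy is strictly better (more negative) than
    the threshold; the boundary value fails the gate."""
    return report.de_total < threshold
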