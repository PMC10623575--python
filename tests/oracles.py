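"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain loops,
closed forms and numerical quadrature only.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def descreen_integral_quad(rho_i: float, r: float, s_j: float) -> float:
    """Numerical evaluation of the pairwise-descreening integral.

    (1/4pi) * integral of |x - x_i|^-4 over the region inside the scaled
    sphere of atom j (radius s_j, centre distance r) and outside the
    intrinsic sphere of atom i (radius rho_i), via shell quadrature.
    """
    if r + s_j <= rho_i:
        return 0.0

    def shell_fraction(rp: float) -> float:
        # fraction of the sphere of radius rp around atom i lying inside j
        if rp <= 0:
            return 0.0
        if r < s_j and rp <= s_j - r:
            return 1.0
        if rp <= abs(r - s_j) or rp >= r + s_j:
            return 0.0 if r >= s_j else 0.0
        cos_theta = (r * r + rp * rp - s_j * s_j) / (2.0 * r * rp)
        cos_theta = min(1.0, max(-1.0, cos_theta))
        return (1.0 - cos_theta) / 2.0

    lower = rho_i
    upper = r + s_j
    breakpoints = [p for p in (abs(r - s_j), s_j - r) if lower < p < upper]
    value, _ = quad(
        lambda rp: shell_fraction(rp) / rp**2,
        lower,
        upper,
        limit=400,
        points=breakpoints or None,
        epsabs=1e-12,
        epsrel=1e-12,
    )
    return value


def born_radii_quad(coords, gb_radius, gb_screen) -> np.ndarray:
    """Effective Born radii from the quadrature oracle, plain loops."""
    n = len(gb_radius)
    out = np.empty(n)
    for i in range(n):
        inv = 1.0 / gb_radius[i]
        for j in range(n):
            if j == i:
                continue
            r = math.dist(coords[i], coords[j])
            inv -= descreen_integral_quad(
                gb_radius[i], r, gb_screen[j] * gb_radius[j]
            )
        out[i] = 1.0 / inv
    return out


def coulomb_scalar(qi, qj, rij, eps_in=1.0, k=332.0636):
    return k * qi * qj / (eps_in * rij)


def lj_scalar(rmh_i, eps_i, rmh_j, eps_j, rij):
    rmin = rmh_i + rmh_j
    eps = math.sqrt(eps_i * eps_j)
    x6 = (rmin / rij) ** 6
    return eps * (x6 * x6 - 2 * x6)


def pearson_scalar(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def metrics_scalar(x, y) -> dict[str, float]:
    n = len(x)
    diffs = [a - b for a, b in zip(x, y)]
    return {
        "r": pearson_scalar(x, y),
        "ase": sum(diffs) / n,
        "aue": sum(abs(d) for d in diffs) / n,
        "rmse": math.sqrt(sum(d * d for d in diffs) / n),
    }


def sasa_sphere_closed_form(radius: float, probe: float) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2
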