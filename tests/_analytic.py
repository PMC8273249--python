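"""Independent analytic oracle: dipole in a homogeneous conducting sphere.

Series solution for the surface potential of a current dipole inside a
homogeneous sphere of radius R and conductivity sigma with insulating
exterior.  With the dipole at distance b from the center, moment split
into a radial part p_r (along the center-dipole axis e1) and tangential
part p_t (along e2), and an observation direction u on the surface,

    phi(u) = 1/(4 pi sigma R^2) * sum_{n>=1} (2n+1)/n * f^(n-1)
             * [ n p_r P_n(c) + p_t (u . e2) P_n'(c) ],

where f = b/R, c = u . e1, P_n the Legendre polynomial and P_n' its
derivative.  Derived from the exterior multipole expansion of the free
dipole plus the interior harmonic correction enforcing dphi/dr = 0 at R;
implemented here with explicit Legendre recurrences, fully independent
of the finite-difference code under test.
"""

from __future__ import annotations

import numpy as np


def sphere_dipole_potential(
    obs_dirs: np.ndarray,
    dipole_pos_mm: np.ndarray,
    dipole_moment: np.ndarray,
    radius_mm: float,
    sigma_s_per_m: float,
    n_terms: int = 300,
) -> np.ndarray:
    """Surface potential (volts) at unit observation directions.

    ``dipole_pos_mm`` is relative to the sphere center; the moment is in
    A m.  Lengths are converted to meters internally.
    """
    R = radius_mm * 1e-3
    r0 = np.asarray(dipole_pos_mm, dtype=float) * 1e-3
    p = np.asarray(dipole_moment, dtype=float)
    u = np.asarray(obs_dirs, dtype=float)
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)

    b = np.linalg.norm(r0)
    if b >= R:
        raise ValueError("dipole must be strictly inside the sphere")
    if b < 1e-12 * R:
        # central dipole: only the n = 1 term survives
        return (3.0 / (4.0 * np.pi * sigma_s_per_m * R**2)) * (u @ p)

    e1 = r0 / b
    p_r = float(p @ e1)
    p_tan = p - p_r * e1
    p_t = float(np.linalg.norm(p_tan))
    e2 = p_tan / p_t if p_t > 0 else np.zeros(3)

    c = u @ e1  # cos(gamma)
    ue2 = u @ e2  # sin(gamma) cos(alpha)
    f = b / R

    # Legendre recurrences: P_n and P_n' evaluated at c
    P_prev = np.ones_like(c)  # P_0
    P = c.copy()  # P_1
    dP_prev = np.zeros_like(c)  # P_0'
    dP = np.ones_like(c)  # P_1'
    acc = np.zeros_like(c)
    fpow = 1.0  # f^(n-1)
    for n in range(1, n_terms + 1):
        term = ((2 * n + 1) / n) * fpow * (n * p_r * P + p_t * ue2 * dP)
        acc += term
        if fpow > 0 and np.max(np.abs(term)) < 1e-16 * max(np.max(np.abs(acc)), 1e-300):
            break
        # advance to n+1
        P_next = ((2 * n + 1) * c * P - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P
        P_prev, P = P, P_next
        dP_prev, dP = dP, dP_next
        fpow *= f
    return acc / (4.0 * np.pi * sigma_s_per_m * R**2)


def relative_difference_measure(a: np.ndarray, b: np.ndarray) -> float:
    """RDM between two potential vectors after mean-referencing.

    ||a/||a|| - b/||b|||| with the mean removed first, the standard
    topography-shape discrepancy for comparing forward solutions.
    """
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero potential vector")
    return float(np.linalg.norm(a / na - b / nb))
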