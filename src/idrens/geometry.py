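"""Rigid backbone geometry: ideal bond lengths/angles, chain construction
from (phi, psi) dihedrals, and dihedral extraction.

The chain model is backbone N/CA/C per residue plus one side-chain bead (SC)
rigidly attached to CA.  All bond lengths, bond angles and the peptide-bond
torsion (omega = 180 deg, trans) are fixed; only phi and psi vary.  Beads are
stored in a flat (4*n_res, 3) array ordered N, CA, C, SC per residue.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Ideal backbone geometry (Angstrom, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_SC = 2.0

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_SC = 110.0
TORSION_C_N_CA_SC = -122.0  # improper fixing the side-chain bead off CA
OMEGA = 180.0

BEADS_PER_RESIDUE = 4
ATOM_NAMES = ("N", "CA", "C", "SC")


@njit(cache=True)
def _place(a, b, c, bond, angle_rad, torsion_rad, out):
    """NeRF placement of atom d given reference atoms a-b-c."""
    bc0 = c[0] - b[0]
    bc1 = c[1] - b[1]
    bc2 = c[2] - b[2]
    nbc = np.sqrt(bc0 * bc0 + bc1 * bc1 + bc2 * bc2)
    bc0 /= nbc
    bc1 /= nbc
    bc2 /= nbc
    ab0 = b[0] - a[0]
    ab1 = b[1] - a[1]
    ab2 = b[2] - a[2]
    # n = ab x bc (normal of the a-b-c plane)
    n0 = ab1 * bc2 - ab2 * bc1
    n1 = ab2 * bc0 - ab0 * bc2
    n2 = ab0 * bc1 - ab1 * bc0
    nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
    n0 /= nn
    n1 /= nn
    n2 /= nn
    # m = n x bc
    m0 = n1 * bc2 - n2 * bc1
    m1 = n2 * bc0 - n0 * bc2
    m2 = n0 * bc1 - n1 * bc0
    d0 = -bond * np.cos(angle_rad)
    s = bond * np.sin(angle_rad)
    d1 = s * np.cos(torsion_rad)
    d2 = -s * np.sin(torsion_rad)
    out[0] = c[0] + bc0 * d0 + m0 * d1 + n0 * d2
    out[1] = c[1] + bc1 * d0 + m1 * d1 + n1 * d2
    out[2] = c[2] + bc2 * d0 + m2 * d1 + n2 * d2


@njit(cache=True)
def build_chain(phi_deg, psi_deg, coords):
    """Fill ``coords`` ((4*n_res, 3) float64) from per-residue dihedrals.

    phi of residue 0 and psi of the last residue do not affect any
    coordinate (no preceding C / following N exists).
    """
    n_res = phi_deg.shape[0]
    deg = np.pi / 180.0
    a_ncac = ANGLE_N_CA_C * deg
    a_cacn = ANGLE_CA_C_N * deg
    a_cnca = ANGLE_C_N_CA * deg
    a_sc = ANGLE_N_CA_SC * deg
    t_sc = TORSION_C_N_CA_SC * deg
    omega = OMEGA * deg

    # first residue: N at origin, CA on +x, C in the xy-plane
    coords[0, 0] = 0.0
    coords[0, 1] = 0.0
    coords[0, 2] = 0.0
    coords[1, 0] = BOND_N_CA
    coords[1, 1] = 0.0
    coords[1, 2] = 0.0
    alpha = np.pi - a_ncac
    coords[2, 0] = BOND_N_CA + BOND_CA_C * np.cos(alpha)
    coords[2, 1] = BOND_CA_C * np.sin(alpha)
    coords[2, 2] = 0.0
    for i in range(1, n_res):
        p = (i - 1) * 4
        q = i * 4
        # N_i from psi_{i-1}; CA_i from omega; C_i from phi_i
        _place(coords[p], coords[p + 1], coords[p + 2], BOND_C_N, a_cacn,
               psi_deg[i - 1] * deg, coords[q])
        _place(coords[p + 1], coords[p + 2], coords[q], BOND_N_CA, a_cnca,
               omega, coords[q + 1])
        _place(coords[p + 2], coords[q], coords[q + 1], BOND_CA_C, a_ncac,
               phi_deg[i] * deg, coords[q + 2])
    for i in range(n_res):
        q = i * 4
        _place(coords[q + 2], coords[q], coords[q + 1], BOND_CA_SC, a_sc,
               t_sc, coords[q + 3])


@njit(cache=True)
def build_many(phi_deg, psi_deg, out):
    """Build chains for a (n_conf, n_res) dihedral stack into (n_conf, 4*n_res, 3)."""
    for k in range(phi_deg.shape[0]):
        build_chain(phi_deg[k], psi_deg[k], out[k])


def torsion(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def extract_dihedrals(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recover (phi, psi) in degrees from a (4*n_res, 3) bead array.

    phi[0] and psi[-1] are not encoded in the coordinates and are returned
    as NaN.
    """
    n_res = coords.shape[0] // BEADS_PER_RESIDUE
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    N = coords[0::4]
    CA = coords[1::4]
    C = coords[2::4]
    for i in range(n_res):
        if i > 0:
            phi[i] = torsion(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            psi[i] = torsion(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def bond_separation_matrix(n_res: int) -> np.ndarray:
    """Graph distance (number of bonds) between all beads of an n_res chain."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import shortest_path

    n = n_res * BEADS_PER_RESIDUE
    adj = lil_matrix((n, n))
    for i in range(n_res):
        q = i * 4
        adj[q, q + 1] = 1       # N-CA
        adj[q + 1, q + 2] = 1   # CA-C
        adj[q + 1, q + 3] = 1   # CA-SC
        if i < n_res - 1:
            adj[q + 2, q + 4] = 1  # C-N(i+1)
    dist = shortest_path(adj.tocsr(), directed=False, unweighted=True)
    return dist.astype(np.int64)
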