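"""Backbone geometry primitives shared by every stage.

Conventions: coordinates are float64 numpy arrays in Angstrom. A backbone
residue is the 5-atom tuple (N, CA, C, O, CB) stored in that order; a chain
is an (L, 5, 3) array. Residue positions are 1-based everywhere in the
public API; raw array indices are 0-based.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

ATOM_ORDER = ("N", "CA", "C", "O", "CB")
ATOM_INDEX = {name: i for i, name in enumerate(ATOM_ORDER)}

#: ideal consecutive CA-CA distance (trans peptide), Angstrom
CA_CA = 3.8


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of point set ``P`` onto ``Q``.

    Least-squares fit with a proper rotation (det = +1). Returns
    ``(R, t, rmsd)`` such that ``P @ R.T + t`` approximates ``Q``.

    Parameters
    ----------
    P, Q : (n, 3) arrays, n >= 3, equal length.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValidationError("need two (n, 3) arrays with n >= 3")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return R, t, rmsd


def is_degenerate(P: np.ndarray, tol: float = 1e-8) -> bool:
    """True when the centered point set is rank-deficient (collinear/planar)."""
    P = np.asarray(P, dtype=float)
    c = P - P.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[-1] <= tol * max(s[0], 1.0))


def apply_rigid(X: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply rotation ``R`` and translation ``t`` to coordinates of any shape (..., 3)."""
    return np.asarray(X, dtype=float) @ R.T + t


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Reconstruct an idealized CB position from backbone N, CA, C.

    Uses the standard tetrahedral construction (1.52 A bond); applied
    uniformly so glycine carries a virtual CB for CA->CB vector work.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    a = ca - n
    b = c - ca
    cr = np.cross(a, b)
    return -0.58273431 * cr + 0.56802827 * a - 0.54067466 * b + ca


def virtual_dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees defined by four points (IUPAC sign)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def ca_virtual_dihedrals(ca: np.ndarray) -> np.ndarray:
    """Vectorized CA(i-1, i, i+1, i+2) virtual dihedrals, degrees.

    Returns an array of length L with NaN at positions lacking the full
    four-point window (the first and last two residues).
    """
    ca = np.asarray(ca, dtype=float)
    L = len(ca)
    out = np.full(L, np.nan)
    if L < 4:
        return out
    b0 = ca[:-3] - ca[1:-2]
    b1 = ca[2:-1] - ca[1:-2]
    b2 = ca[3:] - ca[2:-1]
    nrm = np.linalg.norm(b1, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1n = b1 / np.where(nrm == 0, np.nan, nrm)
    v = b0 - (b0 * b1n).sum(axis=1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(axis=1, keepdims=True) * b1n
    x = (v * w).sum(axis=1)
    y = (np.cross(b1n, v) * w).sum(axis=1)
    out[1 : L - 2] = np.degrees(np.arctan2(y, x))
    return out


def classify_ss_codes(ca: np.ndarray) -> np.ndarray:
    """Per-residue secondary-structure classes as a '<U1' array.

    Uses the virtual dihedral of consecutive CA quadruplets: right-handed
    alpha geometry (~50 deg) is 'H', extended geometry (|tau| >= 140 deg)
    is 'E', everything else (and windows too short to measure) is 'L'.
    """
    tau = ca_virtual_dihedrals(ca)
    out = np.full(len(tau), "L", dtype="<U1")
    with np.errstate(invalid="ignore"):
        out[(tau > 20.0) & (tau < 100.0)] = "H"
        out[np.abs(tau) >= 140.0] = "E"
    return out


def classify_ss(ca: np.ndarray) -> str:
    """String form of :func:`classify_ss_codes`."""
    return "".join(classify_ss_codes(ca))


def backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Build a pseudo-backbone (L, 5, 3) from a CA trace.

    N and C are placed on the virtual bonds to the neighbouring CA atoms,
    O off the C atom, CB by the ideal tetrahedral construction. Adequate
    for CA-level modeling and CA->CB vector diagnostics; not an all-atom
    reconstruction.
    """
    ca = np.asarray(ca, dtype=float)
    L = len(ca)
    if L < 2:
        raise ValidationError("need at least 2 CA positions")
    prev_dir = np.empty_like(ca)
    next_dir = np.empty_like(ca)
    prev_dir[1:] = ca[:-1] - ca[1:]
    prev_dir[0] = -(ca[1] - ca[0])
    next_dir[:-1] = ca[1:] - ca[:-1]
    next_dir[-1] = -(ca[-2] - ca[-1])
    bb = np.empty((L, 5, 3))
    bb[:, ATOM_INDEX["CA"]] = ca
    bb[:, ATOM_INDEX["N"]] = ca + 0.38 * prev_dir
    bb[:, ATOM_INDEX["C"]] = ca + 0.38 * next_dir
    # O roughly perpendicular to the local chain plane
    perp = np.cross(next_dir, prev_dir)
    nrm = np.linalg.norm(perp, axis=1, keepdims=True)
    fallback = np.zeros_like(perp)
    fallback[:, 2] = 1.0
    perp = np.where(nrm > 1e-6, perp / np.where(nrm == 0, 1, nrm), fallback)
    bb[:, ATOM_INDEX["O"]] = bb[:, ATOM_INDEX["C"]] + 1.23 * perp
    bb[:, ATOM_INDEX["CB"]] = ideal_cb_array(
        bb[:, ATOM_INDEX["N"]], ca, bb[:, ATOM_INDEX["C"]]
    )
    return bb


def ideal_cb_array(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized :func:`ideal_cb` over (L, 3) arrays."""
    a = ca - n
    b = c - ca
    cr = np.cross(a, b)
    return -0.58273431 * cr + 0.56802827 * a - 0.54067466 * b + ca


def ideal_helix_ca(n_res: int, rise: float = 1.5, twist_deg: float = 100.0,
                   radius: float = 2.3) -> np.ndarray:
    """CA trace of an ideal alpha helix along +z starting at the origin."""
    k = np.arange(n_res)
    ang = np.radians(twist_deg) * k
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * k], axis=1
    )


def arc_points(start: np.ndarray, end: np.ndarray, n_points: int,
               bulge_dir: np.ndarray, spacing: float = CA_CA) -> np.ndarray:
    """``n_points`` interior points on a circular arc from start to end.

    The arc lies in the plane spanned by the chord and ``bulge_dir`` and its
    length is ``(n_points + 1) * spacing`` so consecutive points (including
    the endpoints) are ~``spacing`` apart. Raises if the chord is already
    longer than the required path.
    """
    from scipy.optimize import brentq

    start = np.asarray(start, float)
    end = np.asarray(end, float)
    chord = end - start
    D = float(np.linalg.norm(chord))
    target_len = (n_points + 1) * spacing
    if target_len < D - 1e-9:
        raise ValidationError(
            f"loop of {n_points} residues cannot span {D:.1f} A "
            f"(path budget {target_len:.1f} A)"
        )
    u = chord / D
    b = np.asarray(bulge_dir, float)
    b = b - np.dot(b, u) * u
    nb = np.linalg.norm(b)
    if nb < 1e-8:  # bulge direction parallel to chord: pick any perpendicular
        b = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(b) < 1e-8:
            b = np.cross(u, [0.0, 1.0, 0.0])
        nb = np.linalg.norm(b)
    b = b / nb

    if target_len / D < 1.0 + 1e-9:
        ts = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
        return start + np.outer(ts, chord)

    # choose the total subtended angle so that the chord between
    # consecutive sampled points equals ``spacing`` exactly:
    #   sin(phi/2) / sin(phi / (2 (n+1))) = D / spacing
    steps = n_points + 1

    def f(phi):
        return np.sin(phi / 2.0) / np.sin(phi / (2.0 * steps)) - D / spacing

    phi = brentq(f, 1e-9, 2.0 * np.pi - 1e-9)
    theta = phi / 2.0
    r = D / (2.0 * np.sin(theta))
    mid = (start + end) / 2.0
    center = mid - b * r * np.cos(theta)
    # sweep in [-theta, theta]: point = center + r (sin(t) u + cos(t) b)
    # passes start -> apex (bulge side) -> end
    phis = np.linspace(-theta, theta, n_points + 2)[1:-1]
    return center + r * (np.outer(np.sin(phis), u) + np.outer(np.cos(phis), b))


def radius_of_gyration(ca: np.ndarray) -> float:
    ca = np.asarray(ca, float)
    c = ca - ca.mean(axis=0)
    return float(np.sqrt((c * c).sum() / len(ca)))
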