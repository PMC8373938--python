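"""Coarse-grained chain geometry.

A protein is represented by its Cα trace.  Side-chain positions enter only
through a *virtual* Cβ constructed from three consecutive Cα atoms with
ideal geometry; glycine and chain termini fall back to the Cα position.
Local backbone state is described by pseudo bond angles θ_i (three
consecutive Cα) and pseudo torsions τ_i (four consecutive Cα), the
standard internal coordinates of Cα-only models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ideal Cα virtual-bond geometry
CA_BOND = 3.8          # Å, consecutive Cα distance
CA_BOND_MIN = 3.4      # Å, hard lower bound after any accepted move
CA_BOND_MAX = 4.2      # Å, hard upper bound
CB_LENGTH = 1.53       # Å, Cα–Cβ distance for the virtual Cβ
CB_ELEVATION = 0.66    # rad, out-of-plane tilt of the virtual Cβ

# ideal SSE geometry shared by the energy bias, the chain initialiser and
# the synthetic-fold generator (all three must agree on what "helix" means)
HELIX_RISE = 1.5      # Å per residue along the helix axis
HELIX_TURN = np.deg2rad(100.0)
HELIX_RADIUS = np.sqrt(CA_BOND ** 2 - HELIX_RISE ** 2) / (2 * np.sin(HELIX_TURN / 2))
STRAND_RISE = 3.3     # Å per residue along the strand axis
STRAND_OFFSET = np.sqrt(CA_BOND ** 2 - STRAND_RISE ** 2) / 2.0


def _ideal_sse_angles():
    """Pseudo bond angle / torsion of the ideal helix and strand, measured
    from the parametrisations above so every module shares one convention."""
    idx = np.arange(6, dtype=float)
    helix = np.column_stack([HELIX_RADIUS * np.cos(HELIX_TURN * idx),
                             HELIX_RADIUS * np.sin(HELIX_TURN * idx),
                             HELIX_RISE * idx])
    strand = np.column_stack([STRAND_OFFSET * (-1.0) ** idx,
                              np.zeros(6), STRAND_RISE * idx])
    th_h, ta_h = pseudo_angles(helix)
    th_e, ta_e = pseudo_angles(strand)
    return (float(th_h[1]), float(ta_h[1])), (float(th_e[1]), float(ta_e[1]))


# populated below once pseudo_angles is defined
IDEAL_THETA: dict = {}
IDEAL_TAU: dict = {}


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without numpy's axis-juggling overhead."""
    c = np.empty_like(a)
    c[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    c[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    c[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return c


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def pseudo_angles(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo bond angles and torsions of a Cα trace.

    Returns ``(theta, tau)`` where ``theta[i]`` is the angle at residue
    ``i+1`` (length L−2) and ``tau[i]`` the dihedral of residues
    ``i..i+3`` (length L−3), both in radians.
    """
    b = coords[1:] - coords[:-1]
    nb = b / _row_norms(b)[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", -nb[:-1], nb[1:]), -1.0, 1.0)
    theta = np.pi - np.arccos(cos_t)
    # dihedral via atan2 of cross products
    b0, b1, b2 = b[:-2], b[1:-1], b[2:]
    n1 = cross3(b0, b1)
    n2 = cross3(b1, b2)
    m1 = cross3(n1, b1 / _row_norms(b1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    tau = np.arctan2(y, x)
    return theta, tau


(_H_ANGLES, _E_ANGLES) = _ideal_sse_angles()
IDEAL_THETA.update({"H": _H_ANGLES[0], "E": _E_ANGLES[0], "C": _E_ANGLES[0]})
IDEAL_TAU.update({"H": _H_ANGLES[1], "E": _E_ANGLES[1], "C": np.pi})


def virtual_cbeta(coords: np.ndarray, sequence: str | None = None) -> np.ndarray:
    """Virtual Cβ positions from a Cα trace.

    The Cβ of residue i sits CB_LENGTH Å from Cα_i, opposite the bisector
    of the two virtual bonds, tilted out of the Cα_{i−1}/Cα_i/Cα_{i+1}
    plane by CB_ELEVATION (fixing chirality).  Termini, and glycine when a
    sequence is given, use the Cα position itself.
    """
    L = len(coords)
    cb = coords.copy()
    if L < 3:
        return cb
    b1 = coords[:-2] - coords[1:-1]
    b2 = coords[2:] - coords[1:-1]
    e1 = b1 / _row_norms(b1)[:, None]
    e2 = b2 / _row_norms(b2)[:, None]
    u = e1 + e2
    v = cross3(e1, e2)
    vn = _row_norms(v)
    # exactly collinear triple: no defined plane, fall back to Cα
    ok = vn > 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        u = u / _row_norms(u)[:, None]
        v = v / vn[:, None]
    direction = -np.cos(CB_ELEVATION) * u + np.sin(CB_ELEVATION) * v
    cb[1:-1][ok] = coords[1:-1][ok] + CB_LENGTH * direction[ok]
    if sequence is not None:
        gly = np.array([aa == "G" for aa in sequence], dtype=bool)
        cb[gly] = coords[gly]
    return cb


def virtual_cbeta_at(coords: np.ndarray, idx: np.ndarray,
                     gly_mask: np.ndarray | None = None) -> np.ndarray:
    """Virtual Cβ for the residues in ``idx`` only (same construction as
    :func:`virtual_cbeta`), returned aligned with ``idx``."""
    L = len(coords)
    cb = coords[idx].copy()
    interior = (idx > 0) & (idx < L - 1)
    if gly_mask is not None:
        interior &= ~gly_mask[idx]
    ii = idx[interior]
    if len(ii) == 0:
        return cb
    b1 = coords[ii - 1] - coords[ii]
    b2 = coords[ii + 1] - coords[ii]
    e1 = b1 / _row_norms(b1)[:, None]
    e2 = b2 / _row_norms(b2)[:, None]
    u = e1 + e2
    v = cross3(e1, e2)
    vn = _row_norms(v)
    ok = vn > 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        u = u / _row_norms(u)[:, None]
        v = v / vn[:, None]
    direction = -np.cos(CB_ELEVATION) * u + np.sin(CB_ELEVATION) * v
    out = coords[ii] + CB_LENGTH * direction
    out[~ok] = coords[ii][~ok]
    cb[interior] = out
    return cb


@dataclass
class CoarseStructure:
    """A single-chain Cα-trace structure.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence (length L).
    coords : (L, 3) ndarray
        Cα coordinates in Å.
    ss : str, optional
        Per-residue 3-state secondary structure (H/E/C).
    resnums : (L,) ndarray, optional
        Residue numbers as found in the source file (defaults to 1..L).
    cb_coords : (L, 3) ndarray, optional
        Experimental Cβ coordinates when read from a file; otherwise the
        virtual construction is used.
    """

    sequence: str
    coords: np.ndarray
    ss: str | None = None
    resnums: np.ndarray | None = None
    cb_coords: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.resnums is None:
            self.resnums = np.arange(1, len(self.sequence) + 1)
        if self.ss is not None and len(self.ss) != len(self.sequence):
            raise ValueError("secondary-structure string length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    def cbeta(self) -> np.ndarray:
        """Cβ coordinates: experimental if stored, else virtual."""
        if self.cb_coords is not None:
            return self.cb_coords
        return virtual_cbeta(self.coords, self.sequence)

    def pseudo_angles(self) -> tuple[np.ndarray, np.ndarray]:
        return pseudo_angles(self.coords)

    def copy(self) -> "CoarseStructure":
        return CoarseStructure(
            self.sequence,
            self.coords.copy(),
            ss=self.ss,
            resnums=None if self.resnums is None else self.resnums.copy(),
            cb_coords=None if self.cb_coords is None else self.cb_coords.copy(),
            name=self.name,
        )


def build_from_internal(
    theta: np.ndarray, tau: np.ndarray, bond: float = CA_BOND
) -> np.ndarray:
    """Build a Cα trace from internal coordinates (NeRF chain extension).

    ``theta`` has length L−2 and ``tau`` length L−3 for a chain of L
    residues; all virtual bonds have length ``bond``.
    """
    L = len(theta) + 2
    coords = np.zeros((L, 3))
    coords[1] = [bond, 0.0, 0.0]
    if L < 3:
        return coords[:L]
    # place third atom in the xy-plane (theta is the bond deflection angle)
    coords[2] = coords[1] + bond * np.array(
        [np.cos(theta[0]), np.sin(theta[0]), 0.0])
    for i in range(3, L):
        coords[i] = _extend(
            coords[i - 3], coords[i - 2], coords[i - 1], bond, theta[i - 2], tau[i - 3]
        )
    return coords


def _extend(a, b, c, bond, theta, tau):
    # inverse of pseudo_angles: theta = deflection angle, tau = dihedral
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    return (c + bond * np.cos(theta) * bc
            + bond * np.sin(theta) * np.cos(tau) * m
            - bond * np.sin(theta) * np.sin(tau) * n)


def extended_chain(sequence: str, ss: str | None = None,
                   ss_conf: np.ndarray | None = None,
                   conf_threshold: float = 0.7) -> CoarseStructure:
    """Initial conformation: extended chain with ideal torsions where the
    secondary structure is confidently predicted, extended-strand values
    elsewhere."""
    L = len(sequence)
    theta = np.full(max(L - 2, 0), IDEAL_THETA["C"])
    tau = np.full(max(L - 3, 0), IDEAL_TAU["C"])
    if ss is not None:
        for i in range(L):
            s = ss[i]
            if s not in ("H", "E"):
                continue
            if ss_conf is not None and ss_conf[i] < conf_threshold:
                continue
            if 1 <= i <= L - 2:
                theta[i - 1] = IDEAL_THETA[s]
            if 1 <= i <= L - 3:
                tau[i - 1] = IDEAL_TAU[s]
    coords = build_from_internal(theta, tau) if L >= 2 else np.zeros((L, 3))
    return CoarseStructure(sequence, coords, ss=ss)


def rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate points about an arbitrary axis through ``origin`` (Rodrigues)."""
    k = axis / np.linalg.norm(axis)
    p = points - origin
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    rotated = (p * cos_a
               + np.cross(k, p) * sin_a
               + np.outer(p @ k, k) * (1.0 - cos_a))
    return rotated + origin


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``;
    returns the transformed copy of ``mobile``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (mobile - mc) @ R.T + tc
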