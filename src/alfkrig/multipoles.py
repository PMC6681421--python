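"""Real spherical-tensor atomic multipole moments and their rotation.

Atomic multipole moments are stored as real spherical-tensor components
Q_lm, rank l = 0..4 (monopole through hexadecapole), component m = -l..l,
i.e. 1 + 3 + 5 + 7 + 9 = 25 values per atom, all in atomic units.  Q_00 is
the atomic charge.  Moments integrated in a fixed global frame are rotated
into each atom's local frame (ALF) with the orthogonal rank-l rotation
matrices D_l built by the standard recursion on rank from the rank-1
matrix (Ivanic-Ruedenberg style), so that a model sees moments that are
independent of the molecule's orientation.

Conventions: components are ordered m = -l..+l everywhere; the real
harmonics carry the Condon-Shortley phase folded in, so the rank-1 basis
(m = -1, 0, +1) corresponds to the Cartesian directions (y, z, x) --
analogous to the p-orbitals (p_y, p_z, p_x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import ALFFrame

__all__ = [
    "N_COMPONENTS",
    "MAX_RANK",
    "component_index",
    "component_labels",
    "MultipoleSet",
    "MomentError",
    "real_sh_rotation",
    "rotate_to_alf",
    "moment_error",
    "read_moments_csv",
    "write_moments_csv",
]

MAX_RANK = 4
N_COMPONENTS = sum(2 * l + 1 for l in range(MAX_RANK + 1))  # 25

# Cartesian axis carried by each rank-1 real harmonic, in m = -1, 0, 1 order.
_RANK1_AXES = (1, 2, 0)  # y, z, x


def component_index(l: int, m: int) -> int:
    """Flat index of component (l, m) in the 25-vector (m = -l..l per rank)."""
    if not 0 <= l <= MAX_RANK or abs(m) > l:
        raise ValueError(f"invalid multipole component (l={l}, m={m})")
    return l * l + (m + l)


def component_labels() -> list[str]:
    """Column labels q{l}m{m} for all 25 components in storage order."""
    return [f"q{l}m{m}" for l in range(MAX_RANK + 1) for m in range(-l, l + 1)]


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper (det +1)")
    return R


def _rank1(R: np.ndarray) -> np.ndarray:
    """Rank-1 rotation: R re-expressed in the (y, z, x) harmonic ordering."""
    D1 = np.empty((3, 3))
    for i, ci in enumerate(_RANK1_AXES):
        for j, cj in enumerate(_RANK1_AXES):
            D1[i, j] = R[ci, cj]
    return D1


def _next_rank(l: int, D1: np.ndarray, Dprev: np.ndarray) -> np.ndarray:
    """Build D_l from D_1 and D_{l-1} by the rank recursion."""

    def r1(i: int, j: int) -> float:
        return D1[i + 1, j + 1]

    def rp(i: int, j: int) -> float:
        return Dprev[i + l - 1, j + l - 1]

    def P(i: int, mu: int, m2: int) -> float:
        if m2 == l:
            return r1(i, 1) * rp(mu, l - 1) - r1(i, -1) * rp(mu, -(l - 1))
        if m2 == -l:
            return r1(i, 1) * rp(mu, -(l - 1)) + r1(i, -1) * rp(mu, l - 1)
        return r1(i, 0) * rp(mu, m2)

    D = np.empty((2 * l + 1, 2 * l + 1))
    for m1 in range(-l, l + 1):
        d0 = 1.0 if m1 == 0 else 0.0
        am = abs(m1)
        for m2 in range(-l, l + 1):
            denom = ((l + m2) * (l - m2)) if abs(m2) < l else (2 * l) * (2 * l - 1)
            u = math.sqrt((l + m1) * (l - m1) / denom)
            v = 0.5 * math.sqrt((1 + d0) * (l + am - 1) * (l + am) / denom) \
                * (1 - 2 * d0)
            w = -0.5 * math.sqrt((l - am - 1) * (l - am) / denom) * (1 - d0)
            val = 0.0
            if u != 0.0:
                val += u * P(0, m1, m2)
            if v != 0.0:
                if m1 == 0:
                    V = P(1, 1, m2) + P(-1, -1, m2)
                elif m1 > 0:
                    V = P(1, m1 - 1, m2) * math.sqrt(1 + (1 if m1 == 1 else 0))
                    if m1 != 1:
                        V -= P(-1, -m1 + 1, m2)
                else:
                    V = P(-1, -m1 - 1, m2) * math.sqrt(1 + (1 if m1 == -1 else 0))
                    if m1 != -1:
                        V += P(1, m1 + 1, m2)
                val += v * V
            if w != 0.0:
                if m1 > 0:
                    W = P(1, m1 + 1, m2) + P(-1, -m1 - 1, m2)
                else:
                    W = P(1, m1 - 1, m2) - P(-1, -m1 + 1, m2)
                val += w * W
            D[m1 + l, m2 + l] = val
    return D


def real_sh_rotation(l: int, R: np.ndarray) -> np.ndarray:
    """Orthogonal (2l+1)x(2l+1) rotation of real spherical components.

    Satisfies S_lm(R u) = sum_m' D[m, m'] S_lm'(u) for the real harmonics
    S_lm, so local-frame moments are ``D @ global_moments`` when ``R`` maps
    global into local coordinates.  D_0 = [1]; D_1 is ``R`` itself up to the
    (y, z, x) component permutation; higher ranks follow by recursion.
    """
    if not 0 <= l <= MAX_RANK:
        raise ValueError(f"rank must be 0..{MAX_RANK}, got {l}")
    R = _check_rotation(R)
    if l == 0:
        return np.ones((1, 1))
    D = _rank1(R)
    if l == 1:
        return D
    prev = D
    for rank in range(2, l + 1):
        prev = _next_rank(rank, _rank1(R), prev)
    return prev


@dataclass
class MultipoleSet:
    """Per-atom real spherical multipole components, rank 0..4.

    ``values`` is (n_atoms, 25) in m = -l..l storage order; ``frame`` records
    whether the components refer to the shared global axes or to each atom's
    own local frame.
    """

    values: np.ndarray
    frame: str = "global"
    atom_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_COMPONENTS:
            raise ValueError(
                f"expected {N_COMPONENTS} components per atom, got "
                f"{self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite multipole components")
        if self.frame not in ("global", "local"):
            raise ValueError("frame must be 'global' or 'local'")
        if not self.atom_labels:
            self.atom_labels = [f"atom{i}" for i in range(self.n_atoms)]

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    def get(self, atom: int, l: int, m: int) -> float:
        return float(self.values[atom, component_index(l, m)])

    @property
    def q00(self) -> np.ndarray:
        """Atomic charges (rank-0 moments) of all atoms."""
        return self.values[:, 0].copy()

    def rank_norms(self, atom: int) -> np.ndarray:
        """Euclidean norm of each rank's component block for one atom."""
        return np.array([
            np.linalg.norm(self.values[atom, l * l:(l + 1) * (l + 1)])
            for l in range(MAX_RANK + 1)
        ])


@dataclass
class MomentError:
    """Per-atom, per-component absolute prediction errors |Q_orig - Q_pred| (au)."""

    values: np.ndarray

    def get(self, atom: int, l: int, m: int) -> float:
        return float(self.values[atom, component_index(l, m)])

    @property
    def q00(self) -> np.ndarray:
        return self.values[:, 0].copy()


def rotate_to_alf(moments: MultipoleSet, alfs) -> MultipoleSet:
    """Rotate global-frame moments into each atom's local frame.

    ``alfs`` is one :class:`ALFFrame` applied to all atoms, or a sequence of
    one frame per atom.  Rank 0 (the charge) is untouched and per-rank norms
    are conserved because every D_l is orthogonal.
    """
    if moments.frame != "global":
        raise ValueError("moments are already in a local frame")
    if isinstance(alfs, ALFFrame):
        alfs = [alfs] * moments.n_atoms
    if len(alfs) != moments.n_atoms:
        raise ValueError("need one ALF per atom")
    out = np.empty_like(moments.values)
    for a, alf in enumerate(alfs):
        blocks = [real_sh_rotation(l, alf.rotation) for l in range(MAX_RANK + 1)]
        for l in range(MAX_RANK + 1):
            sl = slice(l * l, (l + 1) * (l + 1))
            out[a, sl] = blocks[l] @ moments.values[a, sl]
    return MultipoleSet(out, frame="local", atom_labels=list(moments.atom_labels))


def moment_error(orig: MultipoleSet, pred: MultipoleSet) -> MomentError:
    """Elementwise absolute moment error between original and predicted sets."""
    if orig.frame != pred.frame:
        raise ValueError(
            f"frame mismatch: original is {orig.frame!r}, predicted is "
            f"{pred.frame!r}")
    if orig.n_atoms != pred.n_atoms:
        raise ValueError("atom count mismatch")
    return MomentError(np.abs(orig.values - pred.values))


_META_COLS = ["frame_id", "atom_index", "atom_label"]
_FRAME_COLS = ["net_charge", "l_omega"]


def write_moments_csv(path, sets: list[MultipoleSet],
                      net_charges=None, l_omegas=None) -> None:
    """Write per-frame multipole sets to the package's CSV schema.

    One row per (frame, atom); 25 moment columns labeled q{l}m{m}; the
    per-frame molecular net charge and basin integration-error diagnostic
    L(Omega) are repeated on each of the frame's rows.
    """
    n_frames = len(sets)
    net_charges = np.zeros(n_frames) if net_charges is None else np.asarray(net_charges, float)
    l_omegas = np.zeros(n_frames) if l_omegas is None else np.asarray(l_omegas, float)
    rows = []
    for f, ms in enumerate(sets):
        for a in range(ms.n_atoms):
            row = {"frame_id": f, "atom_index": a,
                   "atom_label": ms.atom_labels[a]}
            row.update(dict(zip(component_labels(), ms.values[a])))
            row["net_charge"] = net_charges[f]
            row["l_omega"] = l_omegas[f]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_moments_csv(path, frame: str = "global"):
    """Read the moments CSV back into per-frame MultipoleSets plus frame metadata.

    Returns ``(sets, meta)`` where ``meta`` is a DataFrame indexed by
    frame_id with net_charge and l_omega columns.
    """
    df = pd.read_csv(path)
    required = _META_COLS + component_labels() + _FRAME_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    sets = []
    meta_rows = []
    for fid, grp in df.groupby("frame_id", sort=True):
        grp = grp.sort_values("atom_index")
        sets.append(MultipoleSet(grp[component_labels()].to_numpy(),
                                 frame=frame,
                                 atom_labels=list(grp["atom_label"])))
        meta_rows.append({"frame_id": fid,
                          "net_charge": grp["net_charge"].iloc[0],
                          "l_omega": grp["l_omega"].iloc[0]})
    meta = pd.DataFrame(meta_rows).set_index("frame_id")
    return sets, meta
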