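"""Molecular geometries, bond inference, atomic local frames and features.

A conformation is turned into a set of 3N-6 non-redundant internal
descriptors ("features") seen from one atom's local axis system (ALF), so
that the description is invariant under rigid motion of the molecule.  The
ALF is spanned by the atom and its two highest-priority bonded neighbors;
priorities follow a simplified Cahn-Ingold-Prelog rule (atomic number, then
the sum of atomic numbers one bond out, then lowest atom index).

Fragment features restrict the same construction to a conserved sub-molecule
(for instance the 10-atom unit around a peptide's alpha carbon), giving
3n-6 descriptors that are identical for every molecule containing that
fragment -- the basis of model transferability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConnectivityError, DegenerateFrameError, ParseError

__all__ = [
    "ATOMIC_NUMBERS",
    "COVALENT_RADII",
    "Geometry",
    "BondGraph",
    "ALFFrame",
    "FeatureVector",
    "ALFFeaturizer",
    "read_xyz",
    "write_xyz",
    "infer_bonds",
    "neighbor_priorities",
    "build_alf",
    "compute_features",
    "fragment_features",
]

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Zn": 30,
    "Se": 34, "Br": 35, "I": 53,
}

# Single-bond covalent radii (Angstrom), Cordero et al. consensus values.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}


@dataclass
class Geometry:
    """One molecular conformation: element symbols plus Cartesian coordinates (Angstrom)."""

    elements: list[str]
    coords: np.ndarray
    frame_id: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) < 1:
            raise ValueError("a geometry needs at least one atom")
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        unknown = [e for e in self.elements if e not in ATOMIC_NUMBERS]
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(set(unknown))}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[e] for e in self.elements], dtype=int)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Geometry":
        """Return a copy under the rigid motion x -> R x + t."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return Geometry(list(self.elements), coords, self.frame_id, self.name)


@dataclass(frozen=True)
class BondGraph:
    """Undirected molecular connectivity as a set of atom-index pairs."""

    edges: frozenset
    n_atoms: int
    method: str = "covalent-radii"

    def neighbors(self, atom: int) -> list[int]:
        out = []
        for i, j in self.edges:
            if i == atom:
                out.append(j)
            elif j == atom:
                out.append(i)
        return sorted(out)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return frozenset((i, j)) in self.edges


@dataclass(frozen=True)
class ALFFrame:
    """Right-handed local axis system anchored on one atom.

    ``rotation`` maps *global* displacement vectors into the local frame:
    ``v_local = rotation @ (x_global - origin)``.
    """

    origin_atom: int
    x_axis_atom: int
    xy_plane_atom: int
    rotation: np.ndarray

    def to_local(self, geometry: Geometry) -> np.ndarray:
        origin = geometry.coords[self.origin_atom]
        return (geometry.coords - origin) @ self.rotation.T


@dataclass
class FeatureVector:
    """The 3N-6 internal descriptors of one conformation from one atom's ALF."""

    values: np.ndarray
    schema: list[tuple] = field(default_factory=list)
    origin_atom: int = 0

    def __len__(self) -> int:
        return len(self.values)


def read_xyz(path) -> list[Geometry]:
    """Read a (multi-frame) XYZ file into a list of :class:`Geometry`.

    Each frame is a count line, a free-text comment line (kept as ``name``)
    and one ``element x y z`` line per atom.  Malformed counts, non-numeric
    coordinates and unknown elements raise :class:`ParseError` naming the
    offending line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Geometry] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got "
                             f"{lines[i]!r}") from None
        if n < 1:
            raise ParseError(f"{path}: line {i + 1}: atom count must be >= 1")
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ParseError(
                f"{path}: line {i + 1}: frame declares {n} atoms but the file "
                f"ends after {len(lines) - i - 2} atom lines")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        elements: list[str] = []
        coords = np.empty((n, 3))
        for k in range(n):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise ParseError(
                    f"{path}: line {i + 1}: frame declares {n} atoms but the "
                    f"file ends after {k} atom lines")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno + 1}: expected 'element x y z', got "
                    f"{lines[lineno]!r}")
            sym = parts[0].capitalize()
            if sym not in ATOMIC_NUMBERS:
                raise ParseError(
                    f"{path}: line {lineno + 1}: unknown element {parts[0]!r}")
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno + 1}: non-numeric coordinate in "
                    f"{lines[lineno]!r}") from None
            elements.append(sym)
        frames.append(Geometry(elements, coords, frame_id=len(frames),
                               name=comment))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return frames


def write_xyz(path, geometries: Iterable[Geometry]) -> None:
    """Write geometries as multi-frame XYZ with 8 decimal places."""
    with open(path, "w") as fh:
        for g in geometries:
            fh.write(f"{g.n_atoms}\n{g.name}\n")
            for sym, (x, y, z) in zip(g.elements, g.coords):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


def infer_bonds(geometry: Geometry, scale: float = 1.2) -> BondGraph:
    """Infer covalent bonds from interatomic distances.

    Atoms i and j are bonded iff ``dist(i, j) <= scale * (r_cov(i) + r_cov(j))``.
    A disconnected result (or coincident atoms) raises
    :class:`ConnectivityError` because a single molecule is expected.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    coords = geometry.coords
    n = geometry.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    if n > 1 and np.any(dist[iu] < 1e-6):
        bad = np.argwhere(dist < 1e-6)
        bad = [(int(i), int(j)) for i, j in bad if i < j]
        raise ConnectivityError(f"coincident atoms: {bad}")
    radii = np.array([COVALENT_RADII[e] for e in geometry.elements])
    cutoff = scale * (radii[:, None] + radii[None, :])
    edges = frozenset(
        frozenset((int(i), int(j)))
        for i, j in zip(*iu)
        if dist[i, j] <= cutoff[i, j]
    )
    if n > 1:
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        graph.add_edges_from(tuple(e) for e in edges)
        comps = list(nx.connected_components(graph))
        if len(comps) > 1:
            raise ConnectivityError(
                f"geometry is not a single connected molecule; components: "
                f"{[sorted(c) for c in comps]}")
    return BondGraph(edges=edges, n_atoms=n, method="covalent-radii")


def neighbor_priorities(geometry: Geometry, bonds: BondGraph,
                        atom: int) -> list[int]:
    """Bonded neighbors of ``atom`` in decreasing simplified-CIP priority.

    Priority key: atomic number, then the sum of atomic numbers of the
    candidate's own bonded neighbors (one bond out), then lowest atom index
    as a total tie-break.
    """
    z = geometry.atomic_numbers

    def key(j: int):
        one_out = sum(int(z[k]) for k in bonds.neighbors(j))
        return (-int(z[j]), -one_out, j)

    return sorted(bonds.neighbors(atom), key=key)


def _alf_atoms(geometry: Geometry, bonds: BondGraph, atom: int) -> tuple[int, int]:
    nbrs = neighbor_priorities(geometry, bonds, atom)
    if not nbrs:
        raise DegenerateFrameError(f"atom {atom} has no bonded neighbors")
    x_axis = nbrs[0]
    if len(nbrs) >= 2:
        xy_plane = nbrs[1]
    else:
        # Terminal atom (e.g. amide H): borrow the best neighbor of the
        # x-axis atom, excluding the origin itself.
        second = [j for j in neighbor_priorities(geometry, bonds, x_axis)
                  if j != atom]
        if not second:
            raise DegenerateFrameError(
                f"atom {atom}: cannot find a second reference atom")
        xy_plane = second[0]
    return x_axis, xy_plane


def build_alf(geometry: Geometry, bonds: BondGraph, atom: int,
              x_axis_atom: int | None = None,
              xy_plane_atom: int | None = None) -> ALFFrame:
    """Construct the atomic local frame of ``atom``.

    Local x points from the atom to its highest-priority bonded neighbor,
    local y lies in the plane of the three defining atoms, and z = x cross y
    completes a right-handed orthonormal triad.  The two reference atoms may
    be supplied explicitly to freeze a frame choice across a trajectory.
    """
    if geometry.n_atoms < 3:
        raise DegenerateFrameError("an ALF needs at least 3 atoms")
    if x_axis_atom is None or xy_plane_atom is None:
        x_axis_atom, xy_plane_atom = _alf_atoms(geometry, bonds, atom)
    if len({atom, x_axis_atom, xy_plane_atom}) != 3:
        raise DegenerateFrameError("ALF-defining atoms must be distinct")
    origin = geometry.coords[atom]
    v1 = geometry.coords[x_axis_atom] - origin
    v2 = geometry.coords[xy_plane_atom] - origin
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise DegenerateFrameError("coincident ALF-defining atoms")
    ex = v1 / n1
    perp = v2 - (v2 @ ex) * ex
    if np.linalg.norm(perp) < 1e-6 * n2:
        raise DegenerateFrameError(
            f"ALF atoms {atom}, {x_axis_atom}, {xy_plane_atom} are collinear")
    ey = perp / np.linalg.norm(perp)
    ez = np.cross(ex, ey)
    rotation = np.vstack([ex, ey, ez])
    return ALFFrame(atom, x_axis_atom, xy_plane_atom, rotation)


def _features_from_local(local: np.ndarray, order: Sequence[int],
                         alf: ALFFrame) -> FeatureVector:
    """Assemble the feature vector given local coordinates of all atoms.

    ``local`` is indexed by original atom index; ``order`` lists the atoms
    the vector describes (ascending original index), which must contain the
    three ALF atoms.
    """
    o, xa, pa = alf.origin_atom, alf.x_axis_atom, alf.xy_plane_atom
    v1, v2 = local[xa], local[pa]
    r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
    cosang = np.clip((v1 @ v2) / (r1 * r2), -1.0, 1.0)
    values = [r1, r2, float(np.arccos(cosang))]
    schema: list[tuple] = [
        ("bond-distance", o, xa),
        ("bond-distance", o, pa),
        ("valence-angle", xa, o, pa),
    ]
    for j in order:
        if j in (o, xa, pa):
            continue
        x, y, z = local[j]
        r = float(np.linalg.norm(local[j]))
        if r < 1e-10:
            raise DegenerateFrameError(f"atom {j} coincides with the ALF origin")
        theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))
        phi = float(np.arctan2(y, x))
        values.extend([r, theta, phi])
        schema.extend([("spherical-r", o, j), ("spherical-theta", o, j),
                       ("spherical-phi", o, j)])
    return FeatureVector(np.array(values), schema, origin_atom=o)


def compute_features(geometry: Geometry, atom: int, bonds: BondGraph,
                     alf: ALFFrame | None = None) -> FeatureVector:
    """Compute the 3N-6 features of a conformation from ``atom``'s ALF.

    The first three entries are the two ALF bond distances and the enclosed
    valence angle; each remaining atom (ascending index) contributes its
    spherical polar coordinates (r, theta, phi) in the local frame.
    """
    n = geometry.n_atoms
    if n < 3:
        raise DegenerateFrameError("features need at least 3 atoms (3N-6 >= 3)")
    if alf is None:
        alf = build_alf(geometry, bonds, atom)
    local = alf.to_local(geometry)
    return _features_from_local(local, range(n), alf)


def fragment_features(geometry: Geometry, atom: int,
                      fragment: Sequence[int], bonds: BondGraph,
                      alf: ALFFrame | None = None) -> FeatureVector:
    """Features restricted to a fragment: 3n-6 values for n fragment atoms.

    The ALF of ``atom`` must lie entirely inside the fragment, otherwise the
    fragment does not contain the atom's local environment and an error is
    raised.
    """
    frag = sorted(set(int(i) for i in fragment))
    if len(frag) < 3:
        raise ValueError("a fragment needs at least 3 atoms")
    if atom not in frag:
        raise ValueError(f"origin atom {atom} is not in the fragment")
    if alf is None:
        alf = build_alf(geometry, bonds, atom)
    missing = {alf.x_axis_atom, alf.xy_plane_atom} - set(frag)
    if missing:
        raise ValueError(
            f"ALF atoms {sorted(missing)} fall outside the fragment; the "
            f"fragment must contain the atom's local environment")
    local = alf.to_local(geometry)
    return _features_from_local(local, frag, alf)


class ALFFeaturizer(BaseEstimator, TransformerMixin):
    """Transform conformations of one system into an (n_frames, 3n-6) matrix.

    Bonding and the ALF reference atoms are inferred once, on the template
    frame seen by :meth:`fit`, and then frozen, so every row of the output
    shares one feature schema -- a requirement for kriging on trajectories.

    Parameters
    ----------
    origin_atom : int
        Atom whose local frame defines the features.
    fragment : sequence of int, optional
        Restrict features to these atoms (3n-6 columns); ``None`` uses the
        whole molecule (3N-6 columns).
    bond_scale : float
        Covalent-radius scale factor for bond inference.
    """

    def __init__(self, origin_atom: int = 0, fragment=None,
                 bond_scale: float = 1.2):
        self.origin_atom = origin_atom
        self.fragment = fragment
        self.bond_scale = bond_scale

    def fit(self, X: Sequence[Geometry], y=None):
        template = X[0]
        self.bonds_ = infer_bonds(template, scale=self.bond_scale)
        alf = build_alf(template, self.bonds_, self.origin_atom)
        self.x_axis_atom_ = alf.x_axis_atom
        self.xy_plane_atom_ = alf.xy_plane_atom
        first = self._featurize(template)
        self.schema_ = first.schema
        self.n_features_out_ = len(first)
        return self

    def _featurize(self, g: Geometry) -> FeatureVector:
        alf = build_alf(g, self.bonds_, self.origin_atom,
                        x_axis_atom=self.x_axis_atom_,
                        xy_plane_atom=self.xy_plane_atom_)
        if self.fragment is None:
            return compute_features(g, self.origin_atom, self.bonds_, alf=alf)
        return fragment_features(g, self.origin_atom, self.fragment,
                                 self.bonds_, alf=alf)

    def transform(self, X: Sequence[Geometry]) -> np.ndarray:
        if not hasattr(self, "bonds_"):
            raise RuntimeError("ALFFeaturizer must be fitted first")
        return np.vstack([self._featurize(g).values for g in X])
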