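"""Synthetic peptide conformers and ground-truth property surfaces.

Everything here exists so the full featurize/train/predict pipeline can run
without any electronic-structure input.  Capped peptide chains
(Ace-...-NMe) are built from idealized internal coordinates; distorted
conformers are generated by perturbing bond lengths, valence angles and
dihedrals with uniform draws, under the hard guarantee that no bond length
or valence angle ever moves beyond a stated fraction (default +/-15%) of
its template value.  Smooth analytic "moment surfaces" over feature vectors
supply targets with known ground truth for parameter-recovery tests.

True vibrational (normal-mode) sampling needs a Hessian and is deliberately
out of scope; the per-coordinate uniform scheme keeps the same hard
distortion guardrail while staying Hessian-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConnectivityError
from .geometry import BondGraph, Geometry, infer_bonds

__all__ = [
    "DistortionSpec",
    "SurfaceSpec",
    "build_template",
    "central_fragment",
    "distort",
    "evaluate_surface",
    "make_paired_systems",
]


# --------------------------------------------------------------------------
# internal-coordinate machinery

@dataclass
class _ZEntry:
    """One atom of a Z-matrix: bond/angle/dihedral references plus values."""

    name: str
    element: str
    refs: tuple[str, ...]      # (bond, angle, dihedral) reference names
    r: float = 0.0             # Angstrom
    theta: float = 0.0         # radians
    phi: float = 0.0           # radians


def _place(p1, p2, p3, r, theta, phi):
    """NeRF placement: bond to p1, valence angle at p1 vs p2, dihedral vs p3."""
    bc = p1 - p2
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p2 - p3, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear dihedral reference atoms")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta),
                  r * math.sin(theta) * math.cos(phi),
                  r * math.sin(theta) * math.sin(phi)])
    return p1 + d[0] * bc + d[1] * m + d[2] * n


def _build_cartesians(entries: list[_ZEntry]) -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for e in entries:
        if len(e.refs) == 0:
            pos[e.name] = np.zeros(3)
        elif len(e.refs) == 1:
            pos[e.name] = pos[e.refs[0]] + np.array([e.r, 0.0, 0.0])
        elif len(e.refs) == 2:
            p1, p2 = pos[e.refs[0]], pos[e.refs[1]]
            w = (p2 - p1) / np.linalg.norm(p2 - p1)
            v = np.cross(w, [0.0, 0.0, 1.0])
            if np.linalg.norm(v) < 1e-8:
                v = np.cross(w, [0.0, 1.0, 0.0])
            v = v / np.linalg.norm(v)
            pos[e.name] = p1 + e.r * (math.cos(e.theta) * w
                                      + math.sin(e.theta) * v)
        else:
            p1, p2, p3 = (pos[r] for r in e.refs)
            pos[e.name] = _place(p1, p2, p3, e.r, e.theta, e.phi)
    return pos


def _angle(p0, p1, p2) -> float:
    v1, v2 = p0 - p1, p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(min(1.0, max(-1.0, c)))


def _dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(np.dot(m, n2), np.dot(n1, n2))


# --------------------------------------------------------------------------
# residue library (idealized internal coordinates)

_PHI = -135.0   # backbone dihedral C-CA-N-C(prev), degrees
_PSI = 135.0    # backbone dihedral N(next)-C-CA-N, degrees

_B = {"CC": 1.52, "CB": 1.53, "C=O": 1.23, "CN": 1.33, "NCA": 1.46,
      "NH": 1.01, "CH": 1.09}


def _deg(entry_name, element, refs, r, theta=0.0, phi=0.0) -> _ZEntry:
    return _ZEntry(entry_name, element, tuple(refs), r,
                   math.radians(theta), math.radians(phi))


def _ace(u: str) -> list[_ZEntry]:
    c = f"{u}:"
    return [
        _deg(c + "CH3", "C", (), 0.0),
        _deg(c + "C", "C", (c + "CH3",), _B["CC"]),
        _deg(c + "O", "O", (c + "C", c + "CH3"), _B["C=O"], 121.0),
        _deg(c + "H1", "H", (c + "CH3", c + "C", c + "O"), _B["CH"], 109.5, 60),
        _deg(c + "H2", "H", (c + "CH3", c + "C", c + "O"), _B["CH"], 109.5, 180),
        _deg(c + "H3", "H", (c + "CH3", c + "C", c + "O"), _B["CH"], 109.5, 300),
    ]


def _backbone(u: str, pc: str, po: str) -> list[_ZEntry]:
    """Shared N, H(N), CA block; pc/po are the previous unit's C and O."""
    c = f"{u}:"
    return [
        _deg(c + "N", "N", (pc, po, _grandref(pc)), _B["CN"], 123.0, 180.0),
        _deg(c + "H", "H", (c + "N", pc, po), _B["NH"], 119.0, 180.0),
        _deg(c + "CA", "C", (c + "N", pc, po), _B["NCA"], 121.7, 0.0),
    ]


_GRANDREF: dict[str, str] = {}


def _grandref(pc: str) -> str:
    # dihedral anchor for the amide N: the previous unit's alpha carbon
    return _GRANDREF[pc]


def _residue(u: str, code: str, pc: str, po: str) -> list[_ZEntry]:
    c = f"{u}:"
    out = _backbone(u, pc, po)
    ca, n = c + "CA", c + "N"
    if code == "G":
        out += [
            _deg(c + "HA2", "H", (ca, n, pc), _B["CH"], 109.5, _PHI + 120),
            _deg(c + "HA3", "H", (ca, n, pc), _B["CH"], 109.5, _PHI - 120),
        ]
    elif code == "A":
        out += [
            _deg(c + "HA", "H", (ca, n, pc), _B["CH"], 109.5, _PHI + 120),
            _deg(c + "CB", "C", (ca, n, pc), _B["CB"], 110.5, _PHI - 120),
            _deg(c + "HB1", "H", (c + "CB", ca, n), _B["CH"], 109.5, 60),
            _deg(c + "HB2", "H", (c + "CB", ca, n), _B["CH"], 109.5, 180),
            _deg(c + "HB3", "H", (c + "CB", ca, n), _B["CH"], 109.5, 300),
        ]
    elif code == "V":
        cb = c + "CB"
        out += [
            _deg(c + "HA", "H", (ca, n, pc), _B["CH"], 109.5, _PHI + 120),
            _deg(cb, "C", (ca, n, pc), _B["CB"], 110.5, _PHI - 120),
            _deg(c + "HB", "H", (cb, ca, n), _B["CH"], 108.0, 300),
            _deg(c + "CG1", "C", (cb, ca, n), _B["CB"], 110.5, 60),
            _deg(c + "HG11", "H", (c + "CG1", cb, ca), _B["CH"], 109.5, 60),
            _deg(c + "HG12", "H", (c + "CG1", cb, ca), _B["CH"], 109.5, 180),
            _deg(c + "HG13", "H", (c + "CG1", cb, ca), _B["CH"], 109.5, 300),
            _deg(c + "CG2", "C", (cb, ca, n), _B["CB"], 110.5, 180),
            _deg(c + "HG21", "H", (c + "CG2", cb, ca), _B["CH"], 109.5, 60),
            _deg(c + "HG22", "H", (c + "CG2", cb, ca), _B["CH"], 109.5, 180),
            _deg(c + "HG23", "H", (c + "CG2", cb, ca), _B["CH"], 109.5, 300),
        ]
    else:
        raise ValueError(f"unsupported residue {code!r} (library has G, A, V)")
    out += [
        _deg(c + "C", "C", (ca, n, pc), _B["CC"], 111.0, _PHI),
        _deg(c + "O", "O", (c + "C", ca, n), _B["C=O"], 120.5, _PSI - 180),
    ]
    return out


def _nme(u: str, pc: str, po: str) -> list[_ZEntry]:
    c = f"{u}:"
    return [
        _deg(c + "N", "N", (pc, po, _grandref(pc)), _B["CN"], 123.0, 180.0),
        _deg(c + "H", "H", (c + "N", pc, po), _B["NH"], 119.0, 180.0),
        _deg(c + "CH3", "C", (c + "N", pc, po), _B["NCA"], 121.7, 0.0),
        _deg(c + "HH1", "H", (c + "CH3", c + "N", pc), _B["CH"], 109.5, 60),
        _deg(c + "HH2", "H", (c + "CH3", c + "N", pc), _B["CH"], 109.5, 180),
        _deg(c + "HH3", "H", (c + "CH3", c + "N", pc), _B["CH"], 109.5, 300),
    ]


_RESIDUE_ATOMS = {"G": 7, "A": 10, "V": 16}


def _chain_zmatrix(sequence: str) -> list[_ZEntry]:
    """Z-matrix of the capped chain Ace-(residues)-NMe."""
    entries = _ace("u0")
    _GRANDREF["u0:C"] = "u0:CH3"
    pc, po = "u0:C", "u0:O"
    for i, code in enumerate(sequence):
        u = f"u{i + 1}"
        entries += _residue(u, code, pc, po)
        _GRANDREF[f"{u}:C"] = f"{u}:CA"
        pc, po = f"{u}:C", f"{u}:O"
    entries += _nme(f"u{len(sequence) + 1}", pc, po)
    return entries


def _geometry_from_entries(entries: list[_ZEntry], name: str,
                           frame_id: int = 0) -> Geometry:
    pos = _build_cartesians(entries)
    coords = np.array([pos[e.name] for e in entries])
    return Geometry([e.element for e in entries], coords,
                    frame_id=frame_id, name=name)


def _normalize_name(name: str) -> str:
    if name.upper() == "ALA":
        return "A"
    seq = name.upper()
    if not seq or any(c not in _RESIDUE_ATOMS for c in seq):
        raise ValueError(
            f"unknown template {name!r}: use 'ALA' or a chain over G/A/V "
            f"such as 'AAA', 'GAG', 'VAV'")
    return seq


def build_template(name: str) -> tuple[Geometry, BondGraph]:
    """Idealized capped-peptide template by name ('ALA', 'AAA', 'GAG', ...).

    Chains are built as Ace-(residues)-NMe from standard equilibrium bond
    lengths and angles, so 'AAA' has 6 + 3x10 + 6 = 42 atoms.
    """
    seq = _normalize_name(name)
    entries = _chain_zmatrix(seq)
    g = _geometry_from_entries(entries, name=seq)
    bonds = infer_bonds(g)
    if len(bonds.edges) != g.n_atoms - 1:
        raise ConnectivityError(
            f"template {name!r} produced {len(bonds.edges)} bonds for "
            f"{g.n_atoms} atoms (expected an acyclic chain)")
    return g, bonds


def central_fragment(name: str) -> list[int]:
    """Atom indices of the alpha-carbon-centered fragment of the middle residue.

    For an odd-length chain this is the complete central residue (N, H(N),
    CA, HA, sidechain, C, O): 10 atoms when the center is alanine.
    """
    seq = _normalize_name(name)
    if len(seq) % 2 == 0:
        raise ValueError("central fragment needs an odd-length chain")
    mid = len(seq) // 2
    start = 6 + sum(_RESIDUE_ATOMS[c] for c in seq[:mid])
    return list(range(start, start + _RESIDUE_ATOMS[seq[mid]]))


# --------------------------------------------------------------------------
# distortion

@dataclass
class DistortionSpec:
    """Bounds and bookkeeping for conformer generation.

    No emitted frame has any bond length outside +/-``max_bond_frac`` or
    any valence angle outside +/-``max_angle_frac`` of its template value;
    violating draws are rejected and redrawn.  Dihedrals are perturbed by
    up to ``max_dihedral_deg`` degrees (they carry no fractional guardrail).
    """

    max_bond_frac: float = 0.15
    max_angle_frac: float = 0.15
    n_frames: int = 100
    seed: int = 0
    mode: str = "per-coordinate-uniform"
    max_dihedral_deg: float = 8.0
    clash_cutoff: float = 0.5  # Angstrom, non-bonded pairs

    def __post_init__(self) -> None:
        for f in (self.max_bond_frac, self.max_angle_frac):
            if not 0.0 < f < 0.5:
                raise ValueError("distortion fractions must lie in (0, 0.5)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mode != "per-coordinate-uniform":
            raise ValueError(f"unknown distortion mode {self.mode!r}")


# primary valence angles are drawn inside a margin of the bound so that
# secondary angles (between two dihedral-placed substituents) stay inside it
_ANGLE_DRAW_MARGIN = 0.6


def _valence_angles(bonds: BondGraph):
    for j in range(bonds.n_atoms):
        nbrs = bonds.neighbors(j)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                yield nbrs[a], j, nbrs[b]


def _frame_ok(template: Geometry, bonds: BondGraph, cand: Geometry,
              spec: DistortionSpec) -> bool:
    tc, cc = template.coords, cand.coords
    for e in bonds.edges:
        i, j = tuple(e)
        r0 = np.linalg.norm(tc[i] - tc[j])
        r1 = np.linalg.norm(cc[i] - cc[j])
        if abs(r1 - r0) > spec.max_bond_frac * r0 + 1e-9:
            return False
    for i, j, k in _valence_angles(bonds):
        a0 = _angle(tc[i], tc[j], tc[k])
        a1 = _angle(cc[i], cc[j], cc[k])
        if abs(a1 - a0) > spec.max_angle_frac * a0 + 1e-9:
            return False
    n = cand.n_atoms
    dist = np.linalg.norm(cc[:, None, :] - cc[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    nonbonded = np.array([(i, j) not in bonds for i, j in zip(*iu)])
    if np.any(dist[iu][nonbonded] < spec.clash_cutoff):
        return False
    try:
        newbonds = infer_bonds(cand)
    except ConnectivityError:
        return False
    return newbonds.edges == bonds.edges


def _perturb_entries(entries: list[_ZEntry], draws: dict[str, np.ndarray],
                     spec: DistortionSpec) -> list[_ZEntry]:
    out = []
    dmax = math.radians(spec.max_dihedral_deg)
    for e in entries:
        u = draws[e.name]
        r = e.r * (1.0 + u[0] * spec.max_bond_frac) if len(e.refs) >= 1 else e.r
        theta = e.theta
        if len(e.refs) >= 2:
            theta = e.theta * (1.0 + u[1] * _ANGLE_DRAW_MARGIN
                               * spec.max_angle_frac)
            theta = min(math.pi - 0.01, max(0.01, theta))
        phi = e.phi + u[2] * dmax if len(e.refs) == 3 else e.phi
        out.append(_ZEntry(e.name, e.element, e.refs, r, theta, phi))
    return out


def _draw(entries: list[_ZEntry], rng) -> dict[str, np.ndarray]:
    return {e.name: rng.uniform(-1.0, 1.0, 3) for e in entries}


def _zmatrix_from_geometry(g: Geometry, bonds: BondGraph) -> list[_ZEntry]:
    """Measure a Z-matrix off an existing geometry along a BFS spanning tree."""
    import networkx as nx
    graph = nx.Graph()
    graph.add_nodes_from(range(g.n_atoms))
    graph.add_edges_from(tuple(e) for e in bonds.edges)
    order = list(nx.bfs_tree(graph, 0))
    parent = dict(nx.bfs_predecessors(graph, 0))
    placed: list[int] = []
    entries: list[_ZEntry] = []
    c = g.coords
    for idx, atom in enumerate(order):
        name = str(atom)
        el = g.elements[atom]
        if idx == 0:
            entries.append(_ZEntry(name, el, ()))
        elif idx == 1:
            p = parent[atom]
            entries.append(_ZEntry(name, el, (str(p),),
                                   float(np.linalg.norm(c[atom] - c[p]))))
        elif idx == 2:
            p = parent[atom]
            q = next(a for a in placed if a != p)
            entries.append(_ZEntry(name, el, (str(p), str(q)),
                                   float(np.linalg.norm(c[atom] - c[p])),
                                   _angle(c[atom], c[p], c[q])))
        else:
            p = parent[atom]
            q = parent.get(p)
            if q is None or q == atom:
                q = next(a for a in placed
                         if a != p and a in graph.adj[p])
            s = None
            for cand in placed:
                if cand in (p, q):
                    continue
                n = np.cross(c[q] - c[cand], c[p] - c[q])
                if np.linalg.norm(n) > 1e-6:
                    s = cand
                    break
            if s is None:
                raise ValueError("cannot find a non-collinear dihedral anchor")
            entries.append(_ZEntry(name, el, (str(p), str(q), str(s)),
                                   float(np.linalg.norm(c[atom] - c[p])),
                                   _angle(c[atom], c[p], c[q]),
                                   _dihedral(c[atom], c[p], c[q], c[s])))
        placed.append(atom)
    return entries


def _geometry_from_measured(entries: list[_ZEntry], template: Geometry,
                            frame_id: int) -> Geometry:
    pos = _build_cartesians(entries)
    coords = np.empty((template.n_atoms, 3))
    for e in entries:
        coords[int(e.name)] = pos[e.name]
    return Geometry(list(template.elements), coords, frame_id=frame_id,
                    name=f"{template.name} distorted frame {frame_id}")


def distort(template: Geometry, bonds: BondGraph,
            spec: DistortionSpec) -> list[Geometry]:
    """Generate seeded conformers of a template under hard distortion bounds.

    Internal coordinates along a spanning tree of the bond graph are
    perturbed with per-coordinate uniform draws and the Cartesians rebuilt;
    frames with atom clashes, altered connectivity, or any bond/angle
    outside the bounds are rejected and redrawn (up to 100 retries each).
    """
    zm = _zmatrix_from_geometry(template, bonds)
    frames = []
    for f in range(spec.n_frames):
        for attempt in range(100):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, f, attempt]))
            cand = _geometry_from_measured(
                _perturb_entries(zm, _draw(zm, rng), spec), template, f)
            if _frame_ok(template, bonds, cand, spec):
                frames.append(cand)
                break
        else:
            raise RuntimeError(
                f"frame {f}: no acceptable conformer in 100 attempts; "
                f"loosen the clash cutoff or reduce the distortion bounds")
    return frames


def make_paired_systems(center: str, flank_sets, spec: DistortionSpec,
                        bond_scale: float = 1.2):
    """Families of tripeptides sharing the central residue's geometry per frame.

    ``flank_sets`` is a list of (left, right) residue pairs; each requested
    system ``left+center+right`` is distorted with its own flank draws but
    one shared per-frame draw for every central-residue internal coordinate,
    so the central-fragment features of corresponding frames agree across
    systems.  Returns ``(frames_by_system, fragment_by_system)``.
    """
    center = center.upper()
    systems = {}
    for left, right in flank_sets:
        seq = (left + center + right).upper()
        systems[seq] = _chain_zmatrix(seq)
    frames_by_system: dict[str, list[Geometry]] = {s: [] for s in systems}
    fragment_by_system = {s: central_fragment(s) for s in systems}
    templates = {s: _geometry_from_entries(zm, name=s)
                 for s, zm in systems.items()}
    bonds_by_system = {s: infer_bonds(g, scale=bond_scale)
                       for s, g in templates.items()}
    ref_name = sorted(systems)[0]
    ref_zm = systems[ref_name]
    ref_prefix = f"u{len(ref_name) // 2 + 1}:"
    ref_central_names = [e.name.split(":", 1)[1] for e in ref_zm
                         if e.name.startswith(ref_prefix)]
    ref_template = templates[ref_name]
    ref_bonds = bonds_by_system[ref_name]
    ref_index = {e.name: i for i, e in enumerate(ref_zm)}
    central_idx = {ref_index[ref_prefix + nm] for nm in ref_central_names}
    central_angles = [t for t in _valence_angles(ref_bonds)
                      if set(t) <= central_idx]

    def _central_draws_ok(draws: dict[str, np.ndarray]) -> bool:
        # flanks at template values; check angles internal to the center
        full = {e.name: np.zeros(3) for e in ref_zm}
        for nm, u in draws.items():
            full[ref_prefix + nm] = u
        pos = _build_cartesians(_perturb_entries(ref_zm, full, spec))
        cc = np.array([pos[e.name] for e in ref_zm])
        tc = ref_template.coords
        for i, j, k in central_angles:
            a0 = _angle(tc[i], tc[j], tc[k])
            if abs(_angle(cc[i], cc[j], cc[k]) - a0) \
                    > spec.max_angle_frac * a0 + 1e-9:
                return False
        return True

    for f in range(spec.n_frames):
        # one draw per central-residue coordinate, shared across systems;
        # redrawn until the center's own internal angles respect the bounds
        # (flank retries cannot repair those)
        central_draws: dict[str, np.ndarray] = {}
        for attempt_c in range(100):
            rng_c = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7, f, attempt_c]))
            central_draws = {nm: rng_c.uniform(-1.0, 1.0, 3)
                             for nm in ref_central_names}
            if _central_draws_ok(central_draws):
                break
        else:
            raise RuntimeError(
                f"frame {f}: no acceptable central-residue draw in 100 "
                f"attempts")
        for si, (s, zm) in enumerate(sorted(systems.items())):
            prefix = f"u{len(s) // 2 + 1}:"
            template = templates[s]
            bonds = bonds_by_system[s]
            ok = False
            for attempt in range(100):
                rng_s = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 11, f, si, attempt]))
                draws = {}
                for e in zm:
                    if e.name.startswith(prefix):
                        draws[e.name] = central_draws[e.name.split(":", 1)[1]]
                    else:
                        draws[e.name] = rng_s.uniform(-1.0, 1.0, 3)
                pos = _build_cartesians(_perturb_entries(zm, draws, spec))
                coords = np.array([pos[e.name] for e in zm])
                cand = Geometry(list(template.elements), coords, frame_id=f,
                                name=f"{s} paired frame {f}")
                if _frame_ok(template, bonds, cand, spec):
                    frames_by_system[s].append(cand)
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"system {s}, frame {f}: no acceptable conformer in "
                    f"100 attempts")
    return frames_by_system, fragment_by_system


# --------------------------------------------------------------------------
# analytic property surfaces

@dataclass
class SurfaceSpec:
    """Analytic ground-truth surface over feature vectors, plus noise.

    Forms: ``linear`` (intercept + w.x), ``gaussian-bump`` (base + amp *
    exp(-|x-c|^2 / 2w^2)) and ``sum-of-cosines``.  ``noise_sd`` (au) is the
    standard deviation of seeded Gaussian noise added to the observation;
    the ground truth is always returned separately.
    """

    form: str
    coefficients: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    _FORMS = ("linear", "gaussian-bump", "sum-of-cosines")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown surface form {self.form!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def default(cls, form: str, n_features: int, seed: int = 0,
                noise_sd: float = 0.0) -> "SurfaceSpec":
        """Reasonable seeded coefficients for a given feature count."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        if form == "linear":
            coeff = {"intercept": 0.55,
                     "weights": rng.normal(0, 0.02, n_features)}
        elif form == "gaussian-bump":
            coeff = {"base": 0.55, "amplitude": 0.08,
                     "center": rng.uniform(0.3, 0.7, n_features),
                     "width": 0.8 * math.sqrt(n_features)}
        else:
            coeff = {"base": 0.55,
                     "amplitudes": rng.uniform(0.005, 0.02, n_features),
                     "frequencies": rng.uniform(0.5, 2.0, n_features),
                     "phases": rng.uniform(-math.pi, math.pi, n_features)}
        return cls(form=form, coefficients=coeff, noise_sd=noise_sd, seed=seed)

    @classmethod
    def from_features(cls, form: str, X, seed: int = 0,
                      noise_sd: float = 0.0) -> "SurfaceSpec":
        """Coefficients calibrated to an observed feature sample.

        The bump center sits inside the sampled cloud and length scales
        follow the per-column spread, so the surface varies meaningfully
        over the sampled conformations whatever the feature units.
        """
        X = np.atleast_2d(np.asarray(X, float))
        n_features = X.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        lo, hi = np.percentile(X, 25, axis=0), np.percentile(X, 75, axis=0)
        spread = np.maximum(X.std(axis=0), 1e-9)
        if form == "linear":
            coeff = {"intercept": 0.55,
                     "weights": rng.normal(0.0, 0.02, n_features) / spread}
        elif form == "gaussian-bump":
            center = rng.uniform(lo, hi)
            d = np.linalg.norm(X - center, axis=1)
            coeff = {"base": 0.55, "amplitude": 0.08,
                     "center": center,
                     "width": 0.6 * float(np.median(d))}
        else:
            coeff = {"base": 0.55,
                     "amplitudes": rng.uniform(0.005, 0.02, n_features),
                     "frequencies": rng.uniform(0.5, 2.0, n_features)
                     * math.pi / (np.maximum(X.max(axis=0) - X.min(axis=0),
                                             1e-9)),
                     "phases": rng.uniform(-math.pi, math.pi, n_features)}
        return cls(form=form, coefficients=coeff, noise_sd=noise_sd, seed=seed)


def evaluate_surface(X, spec: SurfaceSpec):
    """Evaluate a surface on feature rows; returns (ground_truth, observed).

    The observation is ground truth plus seeded Gaussian noise of standard
    deviation ``spec.noise_sd``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    c = spec.coefficients
    try:
        if spec.form == "linear":
            w = np.asarray(c["weights"], float)
            if w.shape[0] != X.shape[1]:
                raise ValueError(
                    f"surface expects {w.shape[0]} features, got {X.shape[1]}")
            truth = c["intercept"] + X @ w
        elif spec.form == "gaussian-bump":
            center = np.asarray(c["center"], float)
            if center.shape[0] != X.shape[1]:
                raise ValueError(
                    f"surface expects {center.shape[0]} features, got "
                    f"{X.shape[1]}")
            d2 = np.sum((X - center) ** 2, axis=1)
            truth = c["base"] + c["amplitude"] * np.exp(
                -d2 / (2.0 * c["width"] ** 2))
        else:
            amp = np.asarray(c["amplitudes"], float)
            if amp.shape[0] != X.shape[1]:
                raise ValueError(
                    f"surface expects {amp.shape[0]} features, got {X.shape[1]}")
            freq = np.asarray(c["frequencies"], float)
            phase = np.asarray(c["phases"], float)
            truth = c["base"] + np.sum(
                amp * np.cos(freq * X + phase), axis=1)
    except KeyError as exc:
        raise ValueError(f"surface coefficients missing {exc}") from None
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    observed = truth + rng.normal(0.0, spec.noise_sd, truth.shape) \
        if spec.noise_sd > 0 else truth.copy()
    return truth, observed
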