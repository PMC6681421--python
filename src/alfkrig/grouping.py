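"""Neighbor-residue grouping and model routing for tripeptides.

A central amino acid's atomic properties respond to the identity of its
neighboring residues.  Comparing each AAX tripeptide (alanine-alanine-X) to
the unsubstituted AAA gives per-residue evidence -- the shift in the
central alpha-carbon's charge (dQ00, au) and kinetic energy (dT,
kJ/mol) -- from which each residue X is assigned a neighbor-influence group:

    dQ00 < 0.005 au and dT < 10 kJ/mol  -> A
    dQ00 < 0.005 au and dT >= 10 kJ/mol -> B
    dQ00 >= 0.005 au and dT < 10 kJ/mol -> C
    dQ00 >= 0.005 au and dT >= 10 kJ/mol -> D
    proline -> E unconditionally (its ring forces unique backbone behavior)

Kriging models are then shared between tripeptides whose flanking residues
fall in the same groups, shrinking the 20^3 = 8000 tripeptide space to
5 x 20 x 5 = 500 routing keys.  The package ships the reference evidence
table for the 20 canonical residues (charges and kinetic energies of the
central alpha carbon in the AAX series) as a CSV fixture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import RoutingError

__all__ = [
    "CANONICAL_RESIDUES",
    "GROUP_LABELS",
    "ResidueObservation",
    "GroupAssignment",
    "load_reference_table",
    "deltas_vs_reference",
    "assign_group",
    "group_table",
    "enumerate_tripeptides",
    "route_model",
    "ModelRegistry",
]

CANONICAL_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
GROUP_LABELS = ("A", "B", "C", "D", "E")

DEFAULT_CHARGE_CUT = 0.005   # au
DEFAULT_T_CUT = 10.0         # kJ/mol


@dataclass
class ResidueObservation:
    """Evidence row for one residue X of the AAX series.

    ``q00`` and ``T`` are the central alpha-carbon charge (au) and atomic
    kinetic energy (kJ/mol); ``dq00``/``dT`` are absolute differences
    against the reference residue (may be pre-tabulated or computed by
    :func:`deltas_vs_reference`).
    """

    residue: str
    q00: float
    T: float
    dq00: float | None = None
    dT: float | None = None

    def __post_init__(self) -> None:
        self.residue = self.residue.upper()
        if self.residue not in CANONICAL_RESIDUES:
            raise ValueError(f"unknown residue code {self.residue!r}")
        for d in (self.dq00, self.dT):
            if d is not None and d < 0:
                raise ValueError("deltas must be non-negative")


@dataclass
class GroupAssignment:
    """Residue -> group label map plus the thresholds and evidence used."""

    labels: dict[str, str]
    charge_cut: float = DEFAULT_CHARGE_CUT
    T_cut: float = DEFAULT_T_CUT
    evidence: list[ResidueObservation] = field(default_factory=list)

    def __getitem__(self, residue: str) -> str:
        return self.labels[residue.upper()]

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))


def load_reference_table() -> pd.DataFrame:
    """Packaged AAX evidence table (20 canonical residues, printed deltas)."""
    with resources.files("alfkrig.data").joinpath("aax_reference.csv").open() as fh:
        return pd.read_csv(fh)


def deltas_vs_reference(rows: list[ResidueObservation],
                        reference: str = "A") -> list[ResidueObservation]:
    """Fill dq00 = |q00 - q00_ref| and dT = |T - T_ref| for every row."""
    reference = reference.upper()
    ref = next((r for r in rows if r.residue == reference), None)
    if ref is None:
        raise ValueError(f"reference residue {reference!r} not in table")
    return [
        ResidueObservation(r.residue, r.q00, r.T,
                           dq00=abs(r.q00 - ref.q00), dT=abs(r.T - ref.T))
        for r in rows
    ]


def assign_group(dq00: float, dT: float, residue: str,
                 charge_cut: float = DEFAULT_CHARGE_CUT,
                 T_cut: float = DEFAULT_T_CUT) -> str:
    """Assign one residue's neighbor-influence group from its deltas.

    Boundary handling: strict ``<`` on the low side, ``>=`` on the high
    side, so the criteria partition the (dq00, dT) plane.
    """
    if dq00 < 0 or dT < 0:
        raise ValueError("deltas must be non-negative")
    if residue.upper() == "P":
        return "E"
    low_q = dq00 < charge_cut
    low_t = dT < T_cut
    if low_q and low_t:
        return "A"
    if low_q:
        return "B"
    if low_t:
        return "C"
    return "D"


def group_table(rows: list[ResidueObservation],
                charge_cut: float = DEFAULT_CHARGE_CUT,
                T_cut: float = DEFAULT_T_CUT,
                reference: str = "A",
                require_complete: bool = True) -> GroupAssignment:
    """Group every residue of an evidence table.

    Rows whose deltas are missing are completed with
    :func:`deltas_vs_reference` first; rows carrying pre-tabulated deltas
    (such as the packaged reference table, whose printed deltas come from
    unrounded source values) are used as-is.
    """
    seen = [r.residue for r in rows]
    if len(set(seen)) != len(seen):
        dupes = sorted({r for r in seen if seen.count(r) > 1})
        raise ValueError(f"duplicate residues: {dupes}")
    if require_complete and set(seen) != set(CANONICAL_RESIDUES):
        missing = sorted(set(CANONICAL_RESIDUES) - set(seen))
        raise ValueError(f"missing residues: {missing}")
    if any(r.dq00 is None or r.dT is None for r in rows):
        rows = deltas_vs_reference(rows, reference=reference)
    labels = {r.residue: assign_group(r.dq00, r.dT, r.residue,
                                      charge_cut=charge_cut, T_cut=T_cut)
              for r in rows}
    return GroupAssignment(labels=labels, charge_cut=charge_cut, T_cut=T_cut,
                           evidence=list(rows))


def reference_assignment(charge_cut: float = DEFAULT_CHARGE_CUT,
                         T_cut: float = DEFAULT_T_CUT) -> GroupAssignment:
    """Group assignment computed from the packaged reference evidence."""
    df = load_reference_table()
    rows = [ResidueObservation(r.residue, r.q00, r.T, dq00=r.dq00, dT=r.dT)
            for r in df.itertuples()]
    return group_table(rows, charge_cut=charge_cut, T_cut=T_cut)


def enumerate_tripeptides():
    """All 20^3 = 8000 ordered tripeptides, lexicographic by 1-letter code."""
    combos = ["".join(t) for t in
              itertools.product(CANONICAL_RESIDUES, repeat=3)]
    return len(combos), iter(combos)


@dataclass
class ModelRegistry:
    """Map (left_group, center_residue, right_group) -> model identifier.

    With ``side_symmetric`` (the default) a missing key falls back to the
    same key with the flanking groups swapped, reflecting that the side of
    a flank substitution has little effect on the central residue.
    """

    models: dict[tuple[str, str, str], str]
    side_symmetric: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ModelRegistry":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        models = {}
        for key, mid in doc.get("models", {}).items():
            left, center, right = key.split("-")
            models[(left, center, right)] = str(mid)
        return cls(models=models,
                   side_symmetric=bool(doc.get("side_symmetric", True)))

    def to_yaml(self, path) -> None:
        import yaml
        doc = {
            "side_symmetric": self.side_symmetric,
            "models": {f"{l}-{c}-{r}": m
                       for (l, c, r), m in sorted(self.models.items())},
        }
        Path(path).write_text(yaml.safe_dump(doc))


def route_model(tripeptide: str, assignment: GroupAssignment,
                registry: ModelRegistry) -> str:
    """Route a tripeptide XYZ to the model trained for its routing key.

    The key is (group(X), Y, group(Z)); if absent and the registry is
    side-symmetric, (group(Z), Y, group(X)) is tried before raising
    :class:`RoutingError`.
    """
    trip = tripeptide.upper()
    if len(trip) != 3 or any(c not in CANONICAL_RESIDUES for c in trip):
        raise ValueError(f"invalid tripeptide {tripeptide!r}")
    left, center, right = trip
    key = (assignment[left], center, assignment[right])
    if key in registry.models:
        return registry.models[key]
    if registry.side_symmetric:
        swapped = (key[2], key[1], key[0])
        if swapped in registry.models:
            return registry.models[swapped]
    raise RoutingError(
        f"no model registered for {trip} (key {key}"
        + (", side-swapped fallback tried" if registry.side_symmetric else "")
        + ")")
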