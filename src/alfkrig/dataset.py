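"""Training-database assembly: filtering, normalization, splitting, fragments.

A training set pairs feature vectors (rows = conformations) with one target
moment component for one atom.  Raw frames are first screened for
data-quality violations -- a molecular net charge off the expected value by
more than a tolerance, or a large basin integration error L(Omega) -- then
feature columns are min-max normalized to [0, 1] (the stored scaler is
reused verbatim for test rows, which may therefore fall outside [0, 1]),
and finally rows are split into training and test partitions.

Fragment reduction builds the same structure over a conserved sub-molecule,
so that sets generated from different parent molecules share one column
schema and can be pooled or cross-predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .errors import SchemaError
from .geometry import ALFFeaturizer, Geometry, build_alf
from .multipoles import MultipoleSet, component_index, real_sh_rotation

logger = logging.getLogger(__name__)

__all__ = ["TrainingSet", "FilterReport", "filter_frames", "normalize",
           "split", "reduce_to_fragment"]

DEFAULT_CHARGE_TOL = 0.001   # au
DEFAULT_L_OMEGA_MAX = 0.001  # au


@dataclass
class TrainingSet:
    """Feature matrix X, target vector y, plus schema and provenance."""

    X: np.ndarray
    y: np.ndarray
    schema: list = field(default_factory=list)
    scaler: MinMaxScaler | None = None
    provenance: list[str] = field(default_factory=list)
    fragment: list[int] | None = None
    target: tuple | None = None  # (atom, l, m)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.y = np.asarray(self.y, float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in training data")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FilterReport:
    """Bookkeeping for the data-quality filter; counts always conserve."""

    n_input: int
    n_removed_charge: int
    n_removed_integration: int
    n_remaining: int
    reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != (self.n_remaining + self.n_removed_charge
                            + self.n_removed_integration):
            raise ValueError("filter counts do not conserve")


def filter_frames(meta: pd.DataFrame, charge_tol: float = DEFAULT_CHARGE_TOL,
                  target_charge: float = 0.0,
                  l_omega_max: float = DEFAULT_L_OMEGA_MAX):
    """Screen frames on net charge and integration error.

    ``meta`` needs ``net_charge`` and ``l_omega`` columns (one row per
    frame, as produced by :func:`alfkrig.multipoles.read_moments_csv`).
    A frame survives iff ``|net_charge - target_charge| <= charge_tol`` and
    ``l_omega <= l_omega_max``.  Returns ``(kept_index, FilterReport)``;
    a frame failing both checks is counted under the charge removal.
    """
    for col in ("net_charge", "l_omega"):
        if col not in meta.columns:
            raise SchemaError(f"frame metadata missing column {col!r}")
    bad_charge = (meta["net_charge"] - target_charge).abs() > charge_tol
    bad_int = meta["l_omega"] > l_omega_max
    reasons = {}
    for fid, (bc, bi) in zip(meta.index, zip(bad_charge, bad_int)):
        if bc:
            reasons[fid] = "net-charge"
        elif bi:
            reasons[fid] = "integration-error"
    kept = meta.index[~(bad_charge | bad_int)]
    report = FilterReport(
        n_input=len(meta),
        n_removed_charge=int(bad_charge.sum()),
        n_removed_integration=int((bad_int & ~bad_charge).sum()),
        n_remaining=len(kept),
        reasons=reasons,
    )
    return kept, report


def normalize(ts: TrainingSet) -> TrainingSet:
    """Min-max scale every feature column to [0, 1]; store the scaler.

    Constant columns keep a unit scale (sklearn's zero-range handling) and
    are logged, not rejected.  The transform is exactly invertible via the
    stored scaler.
    """
    scaler = MinMaxScaler().fit(ts.X)
    constant = np.nonzero(scaler.data_range_ == 0)[0]
    if constant.size:
        logger.warning("constant feature columns %s: scale left at 1",
                       constant.tolist())
    Xs = scaler.transform(ts.X)
    return replace(ts, X=Xs, scaler=scaler,
                   provenance=ts.provenance + ["normalize: min-max [0,1]"])


def split(ts: TrainingSet, n_train: int = 800, seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible train/test row partition."""
    n = ts.n_rows
    if n < n_train:
        raise ValueError(f"cannot reserve {n_train} training rows from {n}")
    if n == n_train:
        logger.warning("split leaves an empty test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    prov = ts.provenance + [f"split: {n_train}/{n - n_train} seed={seed}"]
    return (replace(ts, X=ts.X[tr], y=ts.y[tr], provenance=prov),
            replace(ts, X=ts.X[te], y=ts.y[te], provenance=prov))


def reduce_to_fragment(geometries: list[Geometry], atom: int,
                       fragment, moments: list[MultipoleSet],
                       target: tuple = (0, 0),
                       bond_scale: float = 1.2) -> TrainingSet:
    """Build a fragment training set: 3n-6 feature columns, local-frame target.

    ``target`` is the (l, m) moment component of ``atom``; global-frame
    moments are rotated into the atom's per-frame ALF before the component
    is extracted, so the target is orientation-independent like the
    features.  ``fragment=None`` uses the whole molecule (3N-6 columns).
    """
    if len(geometries) != len(moments):
        raise ValueError("need one MultipoleSet per geometry")
    l, m = target
    feat = ALFFeaturizer(origin_atom=atom, fragment=fragment,
                         bond_scale=bond_scale).fit(geometries)
    X = feat.transform(geometries)
    y = np.empty(len(geometries))
    sl = slice(l * l, (l + 1) * (l + 1))
    for i, (g, ms) in enumerate(zip(geometries, moments)):
        if ms.frame == "local":
            y[i] = ms.values[atom, component_index(l, m)]
            continue
        alf = build_alf(g, feat.bonds_, atom,
                        x_axis_atom=feat.x_axis_atom_,
                        xy_plane_atom=feat.xy_plane_atom_)
        D = real_sh_rotation(l, alf.rotation)
        y[i] = (D @ ms.values[atom, sl])[m + l]
    frag = None if fragment is None else sorted(int(i) for i in fragment)
    return TrainingSet(
        X=X, y=y, schema=list(feat.schema_),
        fragment=frag, target=(atom, l, m),
        provenance=[f"reduce_to_fragment: atom={atom} "
                    f"fragment={'all' if frag is None else len(frag)} "
                    f"target=(l={l}, m={m})"])
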