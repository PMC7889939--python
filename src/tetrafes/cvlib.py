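"""Collective variables for a four-nucleosome array.

A tetra-nucleosome configuration is reduced to the ordered vector of the six
inter-nucleosome centre-centre distances

    d = (d12, d13, d14, d23, d24, d34)   [nm]

in lexicographic pair order.  Because a free energy over internal coordinates
cannot depend on which end of the array is called nucleosome 1, reversing the
nucleosome indices (1,2,3,4) -> (4,3,2,1) permutes the distance vector to

    d~ = (d34, d24, d14, d23, d13, d12)

and any learned surface should satisfy A(d) = A(d~).  This module provides the
structure container, the distance/Q/Rg collective variables, the reversal
permutation, and the symmetric feature map that makes the invariance exact by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

#: Lexicographic pair order of the six distances.
PAIR_ORDER: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))

#: Index permutation realising the nucleosome index reversal on a distance
#: vector: component i of the reversed vector is component REVERSAL_PERM[i]
#: of the original, i.e. d~ = d[REVERSAL_PERM].
REVERSAL_PERM: np.ndarray = np.array([5, 4, 2, 3, 1, 0])

#: Allowed bead group labels.
GROUPS = ("core", "flexible")


@dataclass
class BeadModel:
    """A bead-resolution structure with per-bead nucleosome labels.

    positions      (N, 3) float array, nm
    nucleosome_id  (N,) int array, contiguous ids starting at 1
    group          (N,) array of 'core' / 'flexible' labels
    """

    positions: np.ndarray
    nucleosome_id: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.nucleosome_id = np.asarray(self.nucleosome_id, dtype=int)
        self.group = np.asarray(self.group, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InputError(f"positions must be (N, 3), got {self.positions.shape}")
        n = len(self.positions)
        if len(self.nucleosome_id) != n or len(self.group) != n:
            raise InputError("positions, nucleosome_id and group must have equal length")
        if n == 0:
            raise InputError("empty bead model")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions contain non-finite values")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")
        ids = np.unique(self.nucleosome_id)
        if ids[0] != 1 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise InputError(f"nucleosome ids must be contiguous from 1, got {ids}")
        for i in ids:
            if not np.any((self.nucleosome_id == i) & (self.group == "core")):
                raise InputError(f"nucleosome {i} has no core bead")

    @property
    def n_nucleosomes(self) -> int:
        return int(self.nucleosome_id.max())


@dataclass
class DistanceVector:
    """Ordered six-vector of inter-nucleosome distances (nm)."""

    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float).reshape(-1)
        if self.d.shape != (6,):
            raise InputError(f"distance vector must have 6 components, got {self.d.shape}")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise InputError("distances must be finite and non-negative")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.d, dtype=dtype)


@dataclass
class ReferenceDistances:
    """Reference (native) distances and the Gaussian width used by Q."""

    d_ref: DistanceVector
    sigma: float = 2.0  # nm

    def __post_init__(self):
        if not isinstance(self.d_ref, DistanceVector):
            self.d_ref = DistanceVector(np.asarray(self.d_ref, dtype=float))
        if self.sigma <= 0:
            raise InputError(f"sigma must be positive, got {self.sigma}")


def nucleosome_centers(model: BeadModel) -> np.ndarray:
    """Centres of the four nucleosomes: unweighted centroids of core beads.

    Returns a (4, 3) array ordered by nucleosome id.
    """
    if model.n_nucleosomes != 4:
        raise InputError(f"expected exactly 4 nucleosomes, got {model.n_nucleosomes}")
    centers = np.empty((4, 3))
    for i in range(1, 5):
        mask = (model.nucleosome_id == i) & (model.group == "core")
        centers[i - 1] = model.positions[mask].mean(axis=0)
    return centers


def distance_vector(centers: np.ndarray) -> DistanceVector:
    """Six pairwise distances of four centres, in lexicographic pair order."""
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (4, 3):
        raise InputError(f"expected 4 three-dimensional centres, got shape {centers.shape}")
    if not np.all(np.isfinite(centers)):
        raise InputError("centres contain non-finite values")
    d = np.array([np.linalg.norm(centers[i - 1] - centers[j - 1]) for i, j in PAIR_ORDER])
    if np.any(d == 0.0):
        logger.warning("coincident nucleosome centres produced a zero distance")
    return DistanceVector(d)


def fraction_native_contacts(d: DistanceVector | np.ndarray, ref: ReferenceDistances) -> float:
    """Fraction of native contacts Q in (0, 1].

    Q = (1/6) * sum over the 6 pairs of exp(-(d_ij - d_ij_ref)^2 / (2 sigma^2)).
    Q = 1 exactly when d matches the reference componentwise.
    """
    d = np.asarray(d, dtype=float)
    ref_d = np.asarray(ref.d_ref, dtype=float)
    return float(np.mean(np.exp(-((d - ref_d) ** 2) / (2.0 * ref.sigma**2))))


def radius_of_gyration(model: BeadModel) -> float:
    """Unweighted radius of gyration over all beads (nm)."""
    pos = model.positions
    centroid = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=1))))


def reverse_order(d: DistanceVector | np.ndarray) -> DistanceVector:
    """Distance vector after reversing the nucleosome index order.

    (d12, d13, d14, d23, d24, d34) -> (d34, d24, d14, d23, d13, d12).
    An involution: applying it twice returns the input.
    """
    arr = np.asarray(d, dtype=float)
    return DistanceVector(arr[..., REVERSAL_PERM])


def symmetric_features(d: DistanceVector | np.ndarray) -> np.ndarray:
    """Reversal-invariant features of a distance vector.

    s(d) = (d12 + d34, d12*d34, d13 + d24, d13*d24, d14, d23).  The (sum,
    product) encoding of the swapped pairs determines the unordered pair
    uniquely for positive distances, so no information is lost beyond the
    intended index-reversal identification; s(d) = s(d~) exactly.

    Accepts a single vector or an (..., 6) batch.
    """
    a = np.asarray(d, dtype=float)
    d12, d13, d14, d23, d24, d34 = (a[..., i] for i in range(6))
    return np.stack(
        [d12 + d34, d12 * d34, d13 + d24, d13 * d24, d14, d23], axis=-1
    )


def symmetric_features_jacobian(d: DistanceVector | np.ndarray) -> np.ndarray:
    """Jacobian ds/dd of the symmetric feature map, shape (..., 6, 6).

    J[..., i, j] = d s_i / d d_j.  Needed to chain network input gradients
    back to distance space.
    """
    a = np.asarray(d, dtype=float)
    batch = a.shape[:-1]
    J = np.zeros(batch + (6, 6))
    d12, d13, d24, d34 = a[..., 0], a[..., 1], a[..., 4], a[..., 5]
    J[..., 0, 0] = 1.0
    J[..., 0, 5] = 1.0
    J[..., 1, 0] = d34
    J[..., 1, 5] = d12
    J[..., 2, 1] = 1.0
    J[..., 2, 4] = 1.0
    J[..., 3, 1] = d24
    J[..., 3, 4] = d13
    J[..., 4, 2] = 1.0
    J[..., 5, 3] = 1.0
    return J


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("x", "y", "z", "nucleosome_id", "group")


def read_bead_structure(path, format: str = "csv", chain_map: dict[str, int] | None = None) -> BeadModel:
    """Read a bead structure from a CSV dialect or a PDB file.

    CSV columns: x, y, z, nucleosome_id, group (header required; nm).
    PDB: ATOM records; ``chain_map`` maps chain ids to nucleosome ids
    (default: chains in order of first appearance -> 1, 2, ...).  Beads with
    B-factor >= 0.5 are labelled flexible, others core; this matches the
    convention of :func:`write_bead_structure`.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "pdb":
        return _read_pdb(path, chain_map)
    raise InputError(f"unknown structure format {format!r}; expected 'csv' or 'pdb'")


def _read_csv(path) -> BeadModel:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse CSV structure {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ParseError(f"{path}: unknown group label {df['group'][bad].iloc[0]!r}", line=line)
    if df[["x", "y", "z"]].isna().any().any():
        line = int(df[["x", "y", "z"]].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}: non-numeric coordinates", line=line)
    return BeadModel(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        nucleosome_id=df["nucleosome_id"].to_numpy(dtype=int),
        group=df["group"].to_numpy(dtype=object),
    )


def _read_pdb(path, chain_map: dict[str, int] | None) -> BeadModel:
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise ParseError(f"could not parse PDB structure {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise ParseError(f"{path}: no ATOM records")
    chains = atoms.chain_id
    if chain_map is None:
        order = list(dict.fromkeys(chains))
        chain_map = {c: i + 1 for i, c in enumerate(order)}
    unknown = set(chains) - set(chain_map)
    if unknown:
        raise ParseError(f"{path}: chains {sorted(unknown)} missing from chain map")
    nuc_id = np.array([chain_map[c] for c in chains], dtype=int)
    bfac = atoms.get_annotation("b_factor") if "b_factor" in atoms.get_annotation_categories() else np.zeros(len(chains))
    group = np.where(np.asarray(bfac) >= 0.5, "flexible", "core").astype(object)
    # PDB coordinates are Angstrom by convention; package units are nm.
    return BeadModel(positions=atoms.coord * 0.1, nucleosome_id=nuc_id, group=group)


def write_bead_structure(model: BeadModel, path, format: str = "csv") -> None:
    """Write a bead structure in the CSV dialect or as a PDB file.

    The PDB writer assigns chains A.. by nucleosome id and encodes the group
    in the B-factor column (flexible -> 1.0, core -> 0.0), the inverse of the
    reader's convention.
    """
    if format == "csv":
        df = pd.DataFrame(
            {
                "x": model.positions[:, 0],
                "y": model.positions[:, 1],
                "z": model.positions[:, 2],
                "nucleosome_id": model.nucleosome_id,
                "group": model.group,
            }
        )
        df.to_csv(path, index=False)
        return
    if format == "pdb":
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = len(model.positions)
        atoms = struc.AtomArray(n)
        atoms.coord = model.positions * 10.0  # nm -> Angstrom
        atoms.chain_id = np.array(
            [chr(ord("A") + i - 1) for i in model.nucleosome_id], dtype="U4"
        )
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.full(n, "BEA", dtype="U5")
        atoms.atom_name = np.full(n, "CA", dtype="U6")
        atoms.element = np.full(n, "C", dtype="U2")
        atoms.set_annotation(
            "b_factor", np.where(model.group == "flexible", 1.0, 0.0)
        )
        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(atoms)
        pdb_file.write(str(path))
        return
    raise InputError(f"unknown structure format {format!r}; expected 'csv' or 'pdb'")
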