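"""Distance maps, the mutual distance filter, and difference maps.

A structural model of an L-residue protein is reduced to the L x L matrix of
pairwise distances between representative residue atoms (C-beta, falling back
to C-alpha for glycine or when C-beta is missing).  The same protein has a
sequence-predicted distance map produced by an external real-valued distance
predictor and read here from a plain-text matrix file.  Distances above a
cutoff (16 Angstrom by default) carry little information about the fold, so
the two maps are filtered *mutually*: wherever either map exceeds the cutoff,
both entries are zeroed.  The element-wise residual of the filtered maps,
restricted to its upper triangle, is the single-channel image the quality
network consumes.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: Default mutual-filter cutoff in Angstrom.
DEFAULT_THRESHOLD = 16.0

#: Distance written into rows/columns of residues absent from a model, chosen
#: far above any sensible cutoff so the mutual filter zeroes those pairs.
MISSING_RESIDUE_DISTANCE = 999.0

#: Maximum |M - M.T| tolerated in a predicted-map file before it is rejected
#: as corrupt rather than symmetrized.
SYMMETRY_TOLERANCE = 0.5


class MapError(ValueError):
    """Malformed map or structural-model input."""


class MapSource(str, enum.Enum):
    PREDICTED = "predicted"
    MODEL = "model"


def _check_square_symmetric(values: np.ndarray, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MapError(f"{what}: expected a square matrix, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=1e-8):
        raise MapError(f"{what}: matrix is not symmetric")


@dataclass
class DistanceMap:
    """Symmetric, non-negative L x L matrix of inter-residue distances (A)."""

    values: np.ndarray
    source: MapSource
    atom_convention: str = "CB"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_square_symmetric(self.values, "distance map")
        if np.any(self.values < 0):
            raise MapError("distance map has negative entries")
        if np.any(np.diag(self.values) != 0):
            raise MapError("distance map diagonal must be exactly 0")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class FilteredMapPair:
    """Predicted/model maps after the mutual above-threshold zeroing."""

    a_star: np.ndarray
    b_star: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.a_star = np.asarray(self.a_star, dtype=np.float64)
        self.b_star = np.asarray(self.b_star, dtype=np.float64)
        _check_square_symmetric(self.a_star, "filtered predicted map")
        _check_square_symmetric(self.b_star, "filtered model map")
        if self.a_star.shape != self.b_star.shape:
            raise MapError("filtered maps differ in shape")


@dataclass
class DifferenceMap:
    """Upper-triangular residual U between filtered predicted and model maps.

    Entries with row index >= column index are exactly zero; the informative
    signal lives strictly above the diagonal.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MapError(f"difference map must be square, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise MapError("difference map has non-finite entries")
        if np.any(np.tril(self.values) != 0):
            raise MapError("difference map lower triangle / diagonal must be 0")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelRecord:
    """One decoy: identifiers, its difference map, and an optional true score."""

    target_id: str
    model_id: str
    difference_map: DifferenceMap
    true_gdtts: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_gdtts is not None and not (0.0 <= self.true_gdtts <= 1.0):
            raise MapError(
                f"true GDT-TS of {self.target_id}/{self.model_id} must lie in "
                f"[0, 1], got {self.true_gdtts}"
            )

    @property
    def length(self) -> int:
        return self.difference_map.length


# ---------------------------------------------------------------------------
# PDB -> model distance map
# ---------------------------------------------------------------------------

def _prescan_pdb(path: str) -> None:
    """Reject coordinate records whose numeric fields do not parse.

    Bio.PDB is permissive; this scan guarantees that a corrupt ATOM line is
    reported with its line number instead of being silently dropped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise MapError(f"{path}:{lineno}: truncated coordinate record")
            for lo, hi, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise MapError(
                        f"{path}:{lineno}: unparseable {name} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None


def _representative_atom(residue, atom_convention: str):
    """Pick the distance atom for a residue; None when unusable."""
    if atom_convention == "CA":
        order = ("CA",)
    else:  # CB with CA fallback (glycine has no CB)
        order = ("CB", "CA")
    for name in order:
        if name in residue:
            atom = residue[name]
            if atom.is_disordered():
                atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
            return atom
    return None


def read_model_coordinates(
    pdb_path: str, atom_convention: str = "CB"
) -> tuple[np.ndarray, np.ndarray]:
    """Representative-atom coordinates from the first model/chain of a PDB file.

    Returns ``(positions, resseqs)`` where ``positions`` is (n, 3) and
    ``resseqs`` carries the author residue numbers in file order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    _prescan_pdb(pdb_path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("model", pdb_path)
    except (PDBConstructionException, ValueError) as exc:
        raise MapError(f"{pdb_path}: unparseable PDB file: {exc}") from exc

    models = list(structure)
    if not models:
        raise MapError(f"{pdb_path}: no coordinate model found")
    chains = list(models[0])
    if not chains:
        raise MapError(f"{pdb_path}: first model contains no chain")
    chain = chains[0]

    positions, resseqs, bad = [], [], []
    for residue in chain:
        hetflag, resseq, _icode = residue.get_id()
        if hetflag.strip():
            continue
        atom = _representative_atom(residue, atom_convention)
        if atom is None:
            bad.append(resseq)
            continue
        positions.append(atom.get_coord())
        resseqs.append(resseq)
    if bad:
        raise MapError(
            f"{pdb_path}: residues {bad} have no usable "
            f"{atom_convention}/CA atom"
        )
    if len(positions) < 2:
        raise MapError(
            f"{pdb_path}: needs at least 2 residues with coordinates, "
            f"found {len(positions)}"
        )
    return np.asarray(positions, dtype=np.float64), np.asarray(resseqs, dtype=int)


def coords_to_distance_map(coords: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distances of an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=np.float64)
    delta = coords[:, None, :] - coords[None, :, :]
    values = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    np.fill_diagonal(values, 0.0)
    return np.maximum(values, values.T)  # enforce exact symmetry


def model_distance_map(
    pdb_path: str,
    atom_convention: str = "CB",
    expected_length: Optional[int] = None,
) -> DistanceMap:
    """Distance map of a structural model read from a PDB file.

    Residues are indexed by their author residue number mapped onto
    ``1..expected_length`` (or onto the observed numbering range when no
    length is given).  Rows and columns of residues absent from the model are
    filled with a far-above-cutoff distance so the mutual filter removes
    those pairs downstream.
    """
    coords, resseqs = read_model_coordinates(pdb_path, atom_convention)
    offset = int(resseqs.min()) - 1
    idx = resseqs - offset - 1  # zero-based sequence positions
    span = int(idx.max()) + 1
    if expected_length is not None and span != expected_length:
        raise MapError(
            f"{pdb_path}: alignment error: model covers {span} sequence "
            f"positions but the predicted map is {expected_length}x"
            f"{expected_length}"
        )
    length = expected_length if expected_length is not None else span
    dense = coords_to_distance_map(coords)
    if len(idx) == length:
        values = dense
    else:
        missing = sorted(set(range(length)) - set(idx.tolist()))
        logger.warning(
            "%s: %d of %d residues missing from model (positions %s); their "
            "pairs will be removed by the distance filter",
            pdb_path, len(missing), length, [m + 1 for m in missing],
        )
        values = np.full((length, length), MISSING_RESIDUE_DISTANCE, float)
        values[np.ix_(idx, idx)] = dense
        np.fill_diagonal(values, 0.0)
    return DistanceMap(values, MapSource.MODEL, atom_convention)


def read_predicted_map(path: str, expected_length: Optional[int] = None) -> DistanceMap:
    """Read a sequence-predicted distance map from a whitespace-separated file.

    Mild asymmetry (below ``SYMMETRY_TOLERANCE``) is averaged away as
    (M + M.T) / 2; anything larger is treated as file corruption.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for col, tok in enumerate(tokens, start=1):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise MapError(
                        f"{path}: non-numeric token {tok!r} at row {lineno}, "
                        f"column {col}"
                    ) from None
            rows.append(row)
    if not rows:
        raise MapError(f"{path}: empty predicted-map file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise MapError(f"{path}: ragged rows (column counts {sorted(ncols)})")
    values = np.asarray(rows, dtype=np.float64)
    n = values.shape[0]
    if values.shape[0] != values.shape[1]:
        raise MapError(
            f"{path}: expected a square matrix, got {values.shape[0]}x"
            f"{values.shape[1]}"
        )
    if expected_length is not None and n != expected_length:
        raise MapError(
            f"{path}: matrix side {n} does not match expected length "
            f"{expected_length}"
        )
    asym = float(np.max(np.abs(values - values.T))) if n else 0.0
    if asym > SYMMETRY_TOLERANCE:
        raise MapError(
            f"{path}: asymmetry {asym:.3f} A exceeds tolerance "
            f"{SYMMETRY_TOLERANCE} A; file looks corrupt"
        )
    values = (values + values.T) / 2.0
    values = np.maximum(values, 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMap(values, MapSource.PREDICTED)


# ---------------------------------------------------------------------------
# Filter + difference
# ---------------------------------------------------------------------------

def apply_threshold_filter(
    a: DistanceMap, b: DistanceMap, threshold: float = DEFAULT_THRESHOLD
) -> FilteredMapPair:
    """Mutual cutoff filter: where either map exceeds it, zero both entries."""
    if threshold <= 0:
        raise MapError(f"threshold must be positive, got {threshold}")
    if a.length != b.length:
        raise MapError(
            f"map length mismatch: predicted {a.length} vs model {b.length}"
        )
    drop = (a.values > threshold) | (b.values > threshold)
    a_star = np.where(drop, 0.0, a.values)
    b_star = np.where(drop, 0.0, b.values)
    return FilteredMapPair(a_star, b_star, threshold)


def difference_map(pair: FilteredMapPair) -> DifferenceMap:
    """U = upper triangle (excluding the diagonal) of a_star - b_star."""
    d = pair.a_star - pair.b_star
    u = np.triu(d, k=1)
    return DifferenceMap(u)


def featurize_model(
    pdb_path: str,
    predicted_map_path: str,
    threshold: float = DEFAULT_THRESHOLD,
    atom_convention: str = "CB",
    target_id: str = "",
    model_id: str = "",
    true_gdtts: Optional[float] = None,
) -> ModelRecord:
    """PDB + predicted map -> ModelRecord carrying the network input U."""
    a = read_predicted_map(predicted_map_path)
    b = model_distance_map(pdb_path, atom_convention, expected_length=a.length)
    pair = apply_threshold_filter(a, b, threshold)
    u = difference_map(pair)
    return ModelRecord(
        target_id=target_id or "target",
        model_id=model_id or "model",
        difference_map=u,
        true_gdtts=true_gdtts,
        meta={"threshold": threshold, "atom_convention": atom_convention},
    )
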