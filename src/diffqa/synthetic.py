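"""Synthetic targets, decoys, and predictor-noise distance maps.

The generator emulates the three inputs of the real pipeline at desk scale:

* a native-like chain — a self-avoiding random walk with a fixed 3.8 A
  virtual bond between consecutive residues and a 4 A excluded-volume
  radius between non-consecutive ones (no secondary structure or
  Ramachandran realism is attempted);
* decoys — copies of the native chain with isotropic Gaussian coordinate
  noise, spanning low to high quality across a ladder of noise scales;
* a "sequence-predicted" distance map — the native representative-atom map
  plus symmetric Gaussian noise, mimicking an imperfect real-valued distance
  predictor.

The quality label is a superposition-free GDT-TS surrogate: the mean, over
the canonical cutoffs {1, 2, 4, 8} A, of the fraction of residue pairs
(native distance below the working threshold) whose decoy-vs-native distance
error stays below the cutoff.  It is a deterministic function of the native
and decoy distance maps — exactly the information the difference map exposes
— so the regression task is learnable in principle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maps import (
    DEFAULT_THRESHOLD,
    DistanceMap,
    MapSource,
    ModelRecord,
    apply_threshold_filter,
    coords_to_distance_map,
    difference_map,
)

logger = logging.getLogger(__name__)

#: Residue types cycled along synthetic chains; glycine is included so the
#: C-beta -> C-alpha fallback of the featurizer is exercised.
RESIDUE_CYCLE = ("ALA", "GLY", "SER", "LEU", "VAL")

#: Idealized C-alpha -> C-beta offset length in Angstrom.
CB_OFFSET = 1.53

#: GDT-TS-style distance-error cutoffs (A).
QUALITY_CUTOFFS = (1.0, 2.0, 4.0, 8.0)

MIN_SEPARATION = 4.0  # excluded-volume radius between non-consecutive residues


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generation conditions for one synthetic benchmark."""

    n_targets: int = 30
    length_range: tuple[int, int] = (30, 60)
    decoys_per_target: int = 20
    decoy_noise_sigmas: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    predictor_noise_sigma: float = 0.5
    bond_length: float = 3.8
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        self.length_range = (int(self.length_range[0]), int(self.length_range[1]))
        self.decoy_noise_sigmas = tuple(float(s) for s in self.decoy_noise_sigmas)
        if self.n_targets < 1:
            raise SyntheticError("n_targets must be >= 1")
        if self.length_range[0] < 5 or self.length_range[1] < self.length_range[0]:
            raise SyntheticError("length_range must satisfy 5 <= L_min <= L_max")
        if self.decoys_per_target < 2:
            raise SyntheticError("decoys_per_target must be >= 2")
        if any(s < 0 for s in self.decoy_noise_sigmas) or self.predictor_noise_sigma < 0:
            raise SyntheticError("noise sigmas must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class SyntheticTarget:
    target_id: str
    native_coordinates: np.ndarray          # (L, 3) C-alpha positions
    residue_names: list[str]
    predicted_map: DistanceMap
    decoys: list[tuple[str, np.ndarray, float]]  # (model_id, coords, quality)

    @property
    def length(self) -> int:
        return self.native_coordinates.shape[0]


# ---------------------------------------------------------------------------
# Chain geometry
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ZeroDivisionError("zero-length vector")
    return v / n


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = float(np.linalg.norm(v))
        if n > 1e-6:
            return v / n


def generate_chain(length: int, bond_length: float = 3.8,
                   seed: int = 0) -> np.ndarray:
    """Self-avoiding random walk with a fixed step length.

    Consecutive residues sit exactly ``bond_length`` apart; every
    non-consecutive pair is at least 4 A apart.  Deterministic under seed.
    """
    if length < 5:
        raise SyntheticError("chain length must be >= 5")
    rng = np.random.default_rng(seed)
    max_restarts, max_tries = 200, 120
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        failed = False
        while len(coords) < length:
            placed = False
            for _ in range(max_tries):
                cand = coords[-1] + bond_length * _random_unit(rng)
                if len(coords) >= 2:
                    prev = np.asarray(coords[:-1])
                    if np.min(np.linalg.norm(prev - cand, axis=1)) < MIN_SEPARATION:
                        continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                # back up a few residues and try a different direction
                del coords[-min(5, len(coords) - 1):]
                if len(coords) <= 1:
                    failed = True
                    break
        if not failed and len(coords) == length:
            return np.asarray(coords)
    raise SyntheticError(
        f"could not place a self-avoiding chain of length {length}; "
        "try a smaller length"
    )


def pseudo_cb(ca: np.ndarray) -> np.ndarray:
    """Deterministic idealized C-beta positions from a C-alpha trace.

    The offset points along the bisector of the two backbone bonds (a
    perpendicular direction at chain termini or collinear stretches).
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    cb = np.empty_like(ca)

    def perpendicular(u: np.ndarray) -> np.ndarray:
        axis = np.zeros(3)
        axis[int(np.argmin(np.abs(u)))] = 1.0
        return _unit(np.cross(u, axis))

    if n == 1:
        return ca + np.array([CB_OFFSET, 0.0, 0.0])
    for i in range(n):
        if 0 < i < n - 1:
            u = _unit(ca[i] - ca[i - 1])
            v = _unit(ca[i] - ca[i + 1])
            bis = u + v
            if np.linalg.norm(bis) > 1e-6:
                d = _unit(bis)
            else:
                d = perpendicular(u)
        else:
            u = _unit(ca[i] - ca[i + 1 if i == 0 else i - 1])
            d = perpendicular(u)
        cb[i] = ca[i] + CB_OFFSET * d
    return cb


def representative_coordinates(ca: np.ndarray,
                               residue_names: Sequence[str]) -> np.ndarray:
    """C-beta positions, C-alpha for glycine — the featurizer's convention."""
    cb = pseudo_cb(ca)
    rep = cb.copy()
    for i, name in enumerate(residue_names):
        if name == "GLY":
            rep[i] = ca[i]
    return rep


# ---------------------------------------------------------------------------
# Decoys and labels
# ---------------------------------------------------------------------------

def quality_score(native: np.ndarray, decoy: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD) -> float:
    """GDT-TS surrogate from distance-map agreement, in [0, 1].

    Mean over cutoffs {1,2,4,8} A of the fraction of pairs i<j with native
    distance <= threshold whose |decoy distance - native distance| is below
    the cutoff.
    """
    dn = coords_to_distance_map(native)
    dd = coords_to_distance_map(decoy)
    iu = np.triu_indices(dn.shape[0], k=1)
    mask = dn[iu] <= threshold
    if not np.any(mask):
        return 1.0
    err = np.abs(dd[iu][mask] - dn[iu][mask])
    return float(np.mean([np.mean(err < c) for c in QUALITY_CUTOFFS]))


def make_decoy(native: np.ndarray, sigma: float, seed: int = 0,
               threshold: float = DEFAULT_THRESHOLD) -> tuple[np.ndarray, float]:
    """Perturb the native chain with isotropic Gaussian noise; label it."""
    if sigma < 0:
        raise SyntheticError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    decoy = native + (sigma * rng.standard_normal(native.shape)
                      if sigma > 0 else 0.0)
    decoy = np.asarray(decoy, dtype=float)
    return decoy, quality_score(native, decoy, threshold)


def _noisy_predicted_map(rep_native: np.ndarray, sigma: float,
                         rng: np.random.Generator) -> DistanceMap:
    values = coords_to_distance_map(rep_native)
    if sigma > 0:
        n = values.shape[0]
        noise = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        noise[iu] = rng.normal(0.0, sigma, size=len(iu[0]))
        noise = noise + noise.T
        values = values + noise
    values = np.maximum(values, 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMap(values, MapSource.PREDICTED)


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def write_pdb(path, ca: np.ndarray, residue_names: Sequence[str]) -> None:
    """Write a single-chain C-alpha + pseudo-C-beta model (no CB for GLY)."""
    cb = pseudo_cb(ca)
    lines = []
    serial = 0
    for i, name in enumerate(residue_names):
        atoms = [("CA", ca[i], "C")]
        if name != "GLY":
            atoms.append(("CB", cb[i], "C"))
        for atom_name, pos, element in atoms:
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  {atom_name:<3s}{name:>4s} A{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_target(target_id: str, length: int, spec: SyntheticSpec,
                    seed: int) -> SyntheticTarget:
    ss = np.random.SeedSequence(seed)
    chain_seed, pred_seed, decoy_root = ss.spawn(3)
    ca = generate_chain(length, spec.bond_length,
                        int(chain_seed.generate_state(1)[0] % (2**31)))
    residue_names = [RESIDUE_CYCLE[i % len(RESIDUE_CYCLE)] for i in range(length)]
    rep = representative_coordinates(ca, residue_names)
    pred_rng = np.random.default_rng(pred_seed)
    predicted = _noisy_predicted_map(rep, spec.predictor_noise_sigma, pred_rng)
    decoys = []
    decoy_seeds = decoy_root.spawn(spec.decoys_per_target)
    for d in range(spec.decoys_per_target):
        sigma = spec.decoy_noise_sigmas[d % len(spec.decoy_noise_sigmas)]
        coords, q = make_decoy(
            ca, sigma, int(decoy_seeds[d].generate_state(1)[0] % (2**31)),
            spec.threshold,
        )
        decoys.append((f"decoy_{d + 1:03d}", coords, q))
    return SyntheticTarget(target_id, ca, residue_names, predicted, decoys)


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: Optional[str] = None,
) -> tuple[list[SyntheticTarget], pd.DataFrame]:
    """Generate all targets; optionally write the on-disk dataset.

    When ``out_dir`` is given the function emits, per target, decoy PDB
    files and a plain-text predicted-map matrix, plus ``labels.tsv``
    (target_id, model_id, true_quality) and ``manifest.tsv`` listing every
    decoy with its file paths — byte-compatible with the featurizer and the
    evaluation reader.
    """
    root = np.random.SeedSequence(spec.seed)
    target_seeds = root.spawn(spec.n_targets)
    length_rng = np.random.default_rng(root.spawn(1)[0])
    lengths = length_rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1,
                                  size=spec.n_targets)
    targets = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "pdbs").mkdir(parents=True, exist_ok=True)
        (out / "maps").mkdir(parents=True, exist_ok=True)
    for t in range(spec.n_targets):
        target_id = f"SYN{t + 1:04d}"
        tgt = generate_target(
            target_id, int(lengths[t]), spec,
            int(target_seeds[t].generate_state(1)[0] % (2**31)),
        )
        targets.append(tgt)
        map_path = ""
        if out is not None:
            map_path = str(out / "maps" / f"{target_id}.map")
            np.savetxt(map_path, tgt.predicted_map.values, fmt="%.4f")
        for model_id, coords, q in tgt.decoys:
            pdb_path = ""
            if out is not None:
                pdb_path = str(out / "pdbs" / f"{target_id}_{model_id}.pdb")
                write_pdb(pdb_path, coords, tgt.residue_names)
            rows.append({
                "target_id": target_id, "model_id": model_id,
                "length": tgt.length, "pdb_path": pdb_path,
                "map_path": map_path, "true_quality": round(q, 6),
            })
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        manifest[["target_id", "model_id", "true_quality"]].to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        logger.info("wrote %d decoys for %d targets under %s",
                    len(rows), spec.n_targets, out)
    return targets, manifest


def records_from_targets(
    targets: Sequence[SyntheticTarget],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ModelRecord]:
    """Featurize generated targets in memory (no file round-trip).

    Applies the same representative-atom convention, mutual filter, and
    upper-triangle subtraction as the file-based featurizer.
    """
    records = []
    for tgt in targets:
        a = tgt.predicted_map
        for model_id, coords, q in tgt.decoys:
            rep = representative_coordinates(coords, tgt.residue_names)
            b = DistanceMap(coords_to_distance_map(rep), MapSource.MODEL)
            pair = apply_threshold_filter(a, b, threshold)
            u = difference_map(pair)
            records.append(ModelRecord(tgt.target_id, model_id, u,
                                       true_gdtts=q))
    return records
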