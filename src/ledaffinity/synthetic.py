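"""Deterministic generators for every input class the pipeline consumes.

Three generators cover the three pipeline stages:

* :func:`make_toy_structure` — a PDB-format protein-ligand complex in which
  each residue's minimum any-atom distance to the ligand is planted exactly,
  so contact selection has a known ground truth.
* :func:`make_led_fixture` — LED-output text with internally consistent
  energy sections (an inconsistency can be planted deliberately).
* :func:`make_linear_dataset` — affinity datasets that are exactly linear in
  the descriptors up to additive Gaussian noise, with the true coefficients
  returned alongside.

All generators are pure functions of their spec (including the seed):
identical inputs yield byte-identical output.

Geometry note: PDB coordinate columns carry three decimals, so planted
distances are realized on the 0.001 Å grid. Residues are laid out along
coordinate axes starting from the ligand atom with the extreme coordinate in
that direction; every other ligand atom then has a non-negative projection
onto the axis, which makes the contact atom provably the nearest residue
atom and its planted distance the exact residue-ligand minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import AffinityDataset, AffinityRecord, PREDICTOR_COLUMNS
from .errors import PlacementError
from .led import LedComponents, RawLedRecord
from .structure import Atom, StructureModel, write_structure

#: Descriptor ranges (kcal/mol) spanning the reference TcAChE dataset, so
#: synthetic datasets are scale-realistic by default.
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "binding_energy": (19.6, 243.6),
    "e_elstat": (12.8, 154.1),
    "e_exch": (3.0, 38.9),
    "e_ct": (3.0, 23.3),
    "e_disp": (3.6, 46.2),
}

_AXES = [
    np.array([1.0, 0.0, 0.0]),
    np.array([-1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, -1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 0.0, -1.0]),
]

#: Backbone-like offsets (Å) of the residue atoms along the placement axis;
#: the first atom (offset 0) is the planted contact atom.
_RESIDUE_OFFSETS = (0.0, 1.2, 2.4, 3.6)
_RESIDUE_ATOM_NAMES = ("N", "CA", "C", "O")

_MIN_SEPARATION = 1.0
_MAX_RETRIES = 50


@dataclass(frozen=True)
class ToyComplexSpec:
    """Specification of a toy complex with planted contact distances."""

    n_residues: int
    planted_min_distances: tuple[float, ...]
    ligand_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues != len(self.planted_min_distances):
            raise ValueError("need one planted distance per residue")
        if any(d <= 0 for d in self.planted_min_distances):
            raise ValueError("planted distances must be positive")
        if self.ligand_size < 1:
            raise ValueError("ligand needs at least one atom")


@dataclass(frozen=True)
class LinearDatasetSpec:
    """Specification of a linear-response affinity dataset.

    ``coefficients`` maps predictor names (and optionally ``intercept``) to
    the true values; unmentioned predictors enter the table with coefficient
    zero but realistic magnitudes, so they act as pure-noise columns.
    """

    n: int
    coefficients: Mapping[str, float]
    predictor_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_RANGES)
    )
    noise_sd: float = 0.0
    seed: int = 0
    outlier_index: int | None = None
    outlier_offset: float = 5.0

    def __post_init__(self) -> None:
        unknown = [
            k for k in self.coefficients if k != "intercept" and k not in PREDICTOR_COLUMNS
        ]
        if unknown:
            raise ValueError(f"unknown coefficient name(s): {', '.join(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("need more points than coefficients")


def _grid(values: np.ndarray) -> np.ndarray:
    """Snap coordinates to the 0.001 Å grid of PDB coordinate columns."""
    return np.round(values, 3)


def _sample_ligand(rng: np.random.Generator, size: int) -> np.ndarray:
    radius = max(1.6, 0.9 * size ** (1 / 3) + 1.0)
    coords: list[np.ndarray] = [np.zeros(3)]
    attempts = 0
    while len(coords) < size:
        candidate = _grid(rng.uniform(-radius, radius, 3))
        if all(np.linalg.norm(candidate - c) >= _MIN_SEPARATION for c in coords):
            coords.append(candidate)
        attempts += 1
        if attempts > 2000 * size:
            raise PlacementError(
                f"could not place {size} ligand atoms at ≥{_MIN_SEPARATION} Å separation"
            )
    return np.array(coords)


def make_toy_structure(spec: ToyComplexSpec) -> str:
    """Emit PDB text for a toy complex with exact planted contact distances."""
    rng = np.random.default_rng(spec.seed)
    distances = [round(d, 3) for d in spec.planted_min_distances]
    for attempt in range(_MAX_RETRIES):
        ligand_xyz = _sample_ligand(rng, spec.ligand_size)
        residue_xyz: list[np.ndarray] = []
        ok = True
        for i, d in enumerate(distances):
            axis = _AXES[i % len(_AXES)]
            anchor = ligand_xyz[np.argmax(ligand_xyz @ axis)]
            atoms = np.array([anchor + (d + off) * axis for off in _RESIDUE_OFFSETS])
            residue_xyz.append(_grid(atoms))
        placed = np.vstack([ligand_xyz] + residue_xyz) if residue_xyz else ligand_xyz
        # Planted distances are exact by construction; the separation check
        # guards residue-residue and residue-ligand clashes.
        diffs = placed[:, None, :] - placed[None, :, :]
        dist = np.linalg.norm(diffs, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < _MIN_SEPARATION - 1e-9:
            ok = False
        if ok:
            break
    else:
        raise PlacementError(
            "could not satisfy the minimum atom separation after "
            f"{_MAX_RETRIES} attempts"
        )

    atoms: list[Atom] = []
    serial = 1
    for i, res_atoms in enumerate(residue_xyz):
        for name, pos in zip(_RESIDUE_ATOM_NAMES, res_atoms):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    alt_loc="",
                    residue_name="GLY",
                    chain="A",
                    residue_seq=10 + i,
                    icode="",
                    x=float(pos[0]),
                    y=float(pos[1]),
                    z=float(pos[2]),
                    occupancy=1.0,
                    is_hetero=False,
                )
            )
            serial += 1
    for j, pos in enumerate(ligand_xyz):
        atoms.append(
            Atom(
                serial=serial,
                name=f"C{j + 1}",
                element="C",
                alt_loc="",
                residue_name="LIG",
                chain="A",
                residue_seq=900,
                icode="",
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                occupancy=1.0,
                is_hetero=True,
            )
        )
        serial += 1
    return write_structure(StructureModel(atoms=tuple(atoms), source_id="TOY"))


def make_led_fixture(
    intra_fragment_energies: tuple[float, float],
    inter_fragment_sum: float,
    elstat: float,
    exch: float,
    ct_1_to_2: float,
    ct_2_to_1: float,
    disp_strong: float,
    disp_weak: float,
    inconsistency: float = 0.0,
) -> str:
    """Emit LED-dialect output text with the given Hartree quantities.

    The total energy is set to Σ(intra) + inter so the bookkeeping check
    passes by construction; ``inconsistency`` shifts it to plant a defect.
    Values are printed at full precision so parsing recovers them exactly.
    """
    total = sum(intra_fragment_energies) + inter_fragment_sum + inconsistency

    def f(x: float) -> str:
        return format(float(x), ".17g")

    banner = "-" * 60
    lines = [
        banner,
        "INTER- vs INTRA-FRAGMENT TOTAL ENERGIES (Eh)",
        banner,
        f"Total energy                              = {f(total)}",
        f"Sum of INTER-fragment total energies      = {f(inter_fragment_sum)}",
        f"Intra fragment  1 (REF.)                  = {f(intra_fragment_energies[0])}",
        f"Intra fragment  2 (REF.)                  = {f(intra_fragment_energies[1])}",
        "",
        banner,
        "DECOMPOSITION OF CCSD STRONG PAIRS INTO DOUBLE EXCITATION TYPES (Eh)",
        banner,
        f"Charge Transfer 1 to 2                    = {f(ct_1_to_2)}",
        f"Charge Transfer 2 to 1                    = {f(ct_2_to_1)}",
        "",
        banner,
        "FINAL SUMMARY DLPNO-CCSD ENERGY DECOMPOSITION (Eh)",
        banner,
        f"Electrostatics (REF.)                     = {f(elstat)}",
        f"Exchange (REF.)                           = {f(exch)}",
        f"Dispersion (strong pairs)                 = {f(disp_strong)}",
        f"Dispersion (weak pairs)                   = {f(disp_weak)}",
        "",
    ]
    return "\n".join(lines)


def led_fixture_from_record(raw: RawLedRecord, inconsistency: float = 0.0) -> str:
    """Round-trip helper: fixture text whose parse recovers ``raw``.

    The record's own total energy is ignored in favour of the consistent sum
    (plus any planted ``inconsistency``).
    """
    return make_led_fixture(
        intra_fragment_energies=raw.intra_fragment_energies,
        inter_fragment_sum=raw.inter_fragment_sum,
        elstat=raw.elstat,
        exch=raw.exch,
        ct_1_to_2=raw.ct_1_to_2,
        ct_2_to_1=raw.ct_2_to_1,
        disp_strong=raw.disp_strong,
        disp_weak=raw.disp_weak,
        inconsistency=inconsistency,
    )


def make_linear_dataset(
    spec: LinearDatasetSpec,
) -> tuple[AffinityDataset, dict[str, float]]:
    """Draw predictors uniformly from their ranges and a linear response.

    log(K_i) = intercept + Σ β·x + N(0, noise_sd²); the returned ground truth
    maps ``intercept`` and every predictor to its true coefficient (zero for
    predictors not named in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    truth = {"intercept": float(spec.coefficients.get("intercept", 0.0))}
    for p in PREDICTOR_COLUMNS:
        truth[p] = float(spec.coefficients.get(p, 0.0))
    X = np.column_stack(
        [
            rng.uniform(*spec.predictor_ranges.get(p, REFERENCE_RANGES[p]), spec.n)
            for p in PREDICTOR_COLUMNS
        ]
    )
    y = truth["intercept"] + X @ np.array([truth[p] for p in PREDICTOR_COLUMNS])
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n)
    if spec.outlier_index is not None:
        y = y.copy()
        y[spec.outlier_index] += spec.outlier_offset
    records = tuple(
        AffinityRecord(
            complex_id=f"SYN{i + 1:03d}",
            ligand=f"L{i + 1:02d}",
            log_ki=float(y[i]),
            components=LedComponents(*X[i]),
        )
        for i in range(spec.n)
    )
    return AffinityDataset(records), truth
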