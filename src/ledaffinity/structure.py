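"""PDB parsing, contact-based active-site selection and QM-cluster emission.

The active-site model ("QM cluster") is built from a crystal structure of a
protein-ligand complex: every standard amino-acid residue with at least one
atom within a Euclidean cutoff (3.5 Å by default) of any ligand atom is kept
whole (backbone + sidechain, no capping), together with the ligand itself.
The two resulting fragments can be written as plain XYZ or as a two-fragment
coupled-cluster/LED input deck.

Parsing is deliberately strict: fixed PDB columns, first MODEL only,
alternate locations resolved to the highest-occupancy conformer, and any
malformed numeric field raises :class:`~ledaffinity.errors.PdbParseError`
naming the offending line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    EmptyClusterError,
    LigandNotFoundError,
    PdbParseError,
)

logger = logging.getLogger(__name__)

#: Default any-atom contact cutoff in Å used to define "active" residues.
DEFAULT_CUTOFF = 3.5

#: The twenty standard amino acids; only these are eligible active residues.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_TWO_LETTER_ELEMENTS = frozenset(
    "HE LI BE NE NA MG AL SI CL AR CA SC TI CR MN FE CO NI CU ZN SE BR KR"
    " MO RU RH PD AG CD SN SB TE XE PT AU HG PB BI".split()
)


@dataclass(frozen=True)
class Atom:
    """One coordinate record of a PDB file (ATOM or HETATM)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain: str
    residue_seq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    is_hetero: bool

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, residue number, insertion code) identifying the residue."""
        return (self.chain, self.residue_seq, self.icode)


@dataclass(frozen=True)
class StructureModel:
    """Ordered atom list of the first model of a coordinate file."""

    atoms: tuple[Atom, ...]
    source_id: str = ""

    @property
    def het_codes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            if a.is_hetero and a.residue_name != "HOH":
                seen.setdefault(a.residue_name, None)
        return tuple(seen)

    def protein_atoms(self) -> list[Atom]:
        """Polymer atoms of standard amino acids (waters/het groups excluded)."""
        return [
            a for a in self.atoms if not a.is_hetero and a.residue_name in STANDARD_AA
        ]

    def ligand_atoms(self, het_code: str, chain: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.is_hetero
            and a.residue_name == het_code
            and (chain is None or a.chain == chain)
        ]


@dataclass(frozen=True)
class Contact:
    """A ligand-atom/protein-atom pair within the contact cutoff."""

    ligand_atom: Atom
    protein_atom: Atom
    distance: float


@dataclass(frozen=True)
class ClusterGeometry:
    """Two-fragment (active-site residues | ligand) coordinate set."""

    fragment_protein: tuple[Atom, ...]
    fragment_ligand: tuple[Atom, ...]
    residue_roster: tuple[tuple[str, int], ...]
    cutoff_used: float

    @property
    def n_atoms(self) -> int:
        return len(self.fragment_protein) + len(self.fragment_ligand)


@dataclass(frozen=True)
class QmSettings:
    """Settings for the coupled-cluster/LED input deck.

    ``charge`` and ``multiplicity`` refer to the whole two-fragment cluster
    and must be supplied explicitly; crystal structures carry no protonation
    information, so no default is silently assumed.
    """

    method_keywords: tuple[str, ...] = ("DLPNO-CCSD(T)", "NormalPNO", "LED")
    basis: str = "def2-SVP"
    charge: int | None = None
    multiplicity: int | None = None


def _parse_float(text: str, what: str, line_no: int, line: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise PdbParseError(
            f"malformed {what} field {text.strip()!r} on line {line_no}: {line.rstrip()}"
        ) from None
    if not math.isfinite(value):
        raise PdbParseError(f"non-finite {what} on line {line_no}")
    return value


def _infer_element(name_field: str) -> str:
    letters = "".join(c for c in name_field if c.isalpha())
    if not letters:
        return ""
    # A name starting in column 13 (e.g. "FE  ") indicates a two-letter element.
    if not name_field.startswith(" ") and letters[:2].upper() in _TWO_LETTER_ELEMENTS:
        return letters[:2].capitalize()
    return letters[0].upper()


def parse_structure(text: str, source_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is read; alternate locations are resolved to the
    highest-occupancy conformer (ties keep the first listed).
    """
    raw: list[Atom] = []
    model_count = 0
    in_skipped_model = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            model_count += 1
            in_skipped_model = model_count > 1
            continue
        if record.startswith("ENDMDL"):
            continue
        if in_skipped_model or record not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PdbParseError(f"truncated coordinate record on line {line_no}")
        serial = int(_parse_float(line[6:11], "serial", line_no, line))
        name_field = line[12:16]
        alt_loc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip()
        residue_seq = int(_parse_float(line[22:26], "residue number", line_no, line))
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", line_no, line)
        y = _parse_float(line[38:46], "y coordinate", line_no, line)
        z = _parse_float(line[46:54], "z coordinate", line_no, line)
        occ_field = line[54:60]
        occupancy = (
            _parse_float(occ_field, "occupancy", line_no, line)
            if occ_field.strip()
            else 1.0
        )
        element_field = line[76:78].strip() if len(line) >= 78 else ""
        element = element_field.capitalize() or _infer_element(name_field)
        raw.append(
            Atom(
                serial=serial,
                name=name_field.strip(),
                element=element,
                alt_loc=alt_loc,
                residue_name=residue_name,
                chain=chain,
                residue_seq=residue_seq,
                icode=icode,
                x=x,
                y=y,
                z=z,
                occupancy=occupancy,
                is_hetero=record == "HETATM",
            )
        )
    if not raw:
        raise PdbParseError("no ATOM or HETATM records found")

    # Alt-loc resolution: keep the highest-occupancy conformer per atom site.
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for idx, atom in enumerate(raw):
        key = (atom.chain, atom.residue_seq, atom.icode, atom.residue_name, atom.name)
        if key not in best:
            best[key] = idx
            order.append(key)
        elif raw[idx].occupancy > raw[best[key]].occupancy:
            logger.info(
                "alt-loc %s of %s/%s%s dropped in favour of higher-occupancy %s",
                raw[best[key]].alt_loc,
                atom.residue_name,
                atom.residue_seq,
                atom.name,
                atom.alt_loc,
            )
            best[key] = idx
    atoms = tuple(raw[best[key]] for key in order)
    return StructureModel(atoms=atoms, source_id=source_id)


def write_structure(structure: StructureModel) -> str:
    """Write a :class:`StructureModel` back to fixed-column PDB text."""
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:>5d} {name}{a.alt_loc or ' '}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_seq:>4d}{a.icode or ' '}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def find_contacts(
    structure: StructureModel,
    ligand_selector: tuple[str, str | None] | str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[Contact]:
    """All (ligand atom, protein atom) pairs within ``cutoff`` Å, inclusive.

    The protein side is restricted to standard amino-acid polymer atoms:
    waters, ions and other het groups never count as contacts. Results are
    sorted by distance (ties by atom serials).
    """
    if isinstance(ligand_selector, str):
        het_code, chain = ligand_selector, None
    else:
        het_code, chain = ligand_selector
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    ligand = structure.ligand_atoms(het_code, chain)
    if not ligand:
        raise LigandNotFoundError(
            f"het code {het_code!r}"
            + (f" on chain {chain!r}" if chain else "")
            + f" not found; available het codes: {', '.join(structure.het_codes) or '(none)'}"
        )
    protein = structure.protein_atoms()
    if not protein:
        return []
    coords = np.array([[a.x, a.y, a.z] for a in protein])
    tree = cKDTree(coords)
    contacts: list[Contact] = []
    for latom in ligand:
        for j in tree.query_ball_point([latom.x, latom.y, latom.z], cutoff):
            patom = protein[j]
            d = float(np.linalg.norm(latom.position - patom.position))
            contacts.append(Contact(latom, patom, d))
    contacts.sort(key=lambda c: (c.distance, c.ligand_atom.serial, c.protein_atom.serial))
    return contacts


def build_cluster(
    structure: StructureModel,
    ligand_selector: tuple[str, str | None] | str,
    cutoff: float = DEFAULT_CUTOFF,
) -> ClusterGeometry:
    """Select whole contacting residues and assemble the two-fragment cluster."""
    contacts = find_contacts(structure, ligand_selector, cutoff)
    residue_keys = {c.protein_atom.residue_key for c in contacts}
    if not residue_keys:
        raise EmptyClusterError(
            f"no residue has an atom within {cutoff} Å of the ligand; "
            "check the cutoff and ligand selector"
        )
    members = sorted(
        residue_keys, key=lambda k: (k[1], k[2], k[0])
    )  # by residue number, icode, chain
    by_residue: dict[tuple, list[Atom]] = {k: [] for k in members}
    for a in structure.atoms:
        if not a.is_hetero and a.residue_key in by_residue:
            by_residue[a.residue_key].append(a)
    fragment_protein = tuple(a for k in members for a in by_residue[k])
    roster = tuple((by_residue[k][0].residue_name, k[1]) for k in members)
    if isinstance(ligand_selector, str):
        het_code, chain = ligand_selector, None
    else:
        het_code, chain = ligand_selector
    fragment_ligand = tuple(structure.ligand_atoms(het_code, chain))
    logger.info(
        "cluster: %d residues (%s), %d protein atoms, %d ligand atoms at cutoff %.2f Å",
        len(roster),
        ", ".join(f"{n}{s}" for n, s in roster),
        len(fragment_protein),
        len(fragment_ligand),
        cutoff,
    )
    return ClusterGeometry(
        fragment_protein=fragment_protein,
        fragment_ligand=fragment_ligand,
        residue_roster=roster,
        cutoff_used=cutoff,
    )


def _xyz_lines(atoms: Iterable[Atom], fragment: int | None = None) -> list[str]:
    out = []
    for a in atoms:
        tag = a.element if fragment is None else f"{a.element}({fragment})"
        out.append(f"{tag:<6s} {a.x:14.6f} {a.y:14.6f} {a.z:14.6f}")
    return out


def write_cluster(
    cluster: ClusterGeometry,
    dialect: str = "xyz",
    settings: QmSettings | None = None,
) -> str:
    """Serialize a cluster as ``xyz`` or as a ``qm-led-input`` deck.

    The deck declares the coupled-cluster method with LED and assigns
    fragment 1 to the protein residues and fragment 2 to the ligand.
    """
    if cluster.n_atoms == 0:
        raise EmptyClusterError("cannot write an empty cluster")
    if dialect == "xyz":
        comment = (
            f"active-site cluster, cutoff {cluster.cutoff_used:.2f} A, residues "
            + " ".join(f"{n}{s}" for n, s in cluster.residue_roster)
        )
        lines = [str(cluster.n_atoms), comment]
        lines += _xyz_lines(cluster.fragment_protein)
        lines += _xyz_lines(cluster.fragment_ligand)
        return "\n".join(lines) + "\n"
    if dialect == "qm-led-input":
        settings = settings or QmSettings()
        if settings.charge is None or settings.multiplicity is None:
            raise ConfigurationError(
                "charge and multiplicity must be set explicitly for a QM input "
                "deck (crystal structures carry no protonation information); "
                "a neutral singlet (0/1) is a common but unverified choice"
            )
        keywords = list(settings.method_keywords)
        if "LED" not in keywords:
            keywords.append("LED")
        lines = ["! " + " ".join(keywords + [settings.basis])]
        lines.append("%mdci")
        lines.append("  LED 1")
        lines.append("end")
        lines.append(f"* xyz {settings.charge} {settings.multiplicity}")
        lines += _xyz_lines(cluster.fragment_protein, fragment=1)
        lines += _xyz_lines(cluster.fragment_ligand, fragment=2)
        lines.append("*")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}; expected 'xyz' or 'qm-led-input'")


def parse_xyz(text: str) -> list[tuple[str, tuple[float, float, float]]]:
    """Parse XYZ text into (element, (x, y, z)) tuples."""
    lines = text.splitlines()
    if not lines:
        raise PdbParseError("empty xyz text")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise PdbParseError(f"bad xyz atom count: {lines[0]!r}") from None
    atoms = []
    for line in lines[2 : 2 + count]:
        parts = line.split()
        element = parts[0].split("(")[0]
        atoms.append((element, (float(parts[1]), float(parts[2]), float(parts[3]))))
    if len(atoms) != count:
        raise PdbParseError(f"xyz header promised {count} atoms, found {len(atoms)}")
    return atoms
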