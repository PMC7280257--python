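"""Parsing of local-energy-decomposition (LED) output and descriptor assembly.

A two-fragment DLPNO-CCSD(T)/LED calculation partitions the inter-fragment
interaction into electrostatic, exchange, charge-transfer and dispersion
contributions. This module extracts the labelled quantities from the output
text (all in Hartree) and converts them to the five kcal/mol descriptors used
by the regression stage:

* ``binding_energy`` — the inter-fragment total energy, i.e. the energy of
  the two-fragment cluster minus the intra-fragment energies at fixed
  geometry (E_PL − (E_P + E_L)).
* ``e_elstat``, ``e_exch`` — the reference-level electrostatic and exchange
  contributions.
* ``e_ct`` — the sum of both charge-transfer directions (1→2 and 2→1).
* ``e_disp`` — strong- plus weak-pair dispersion.

Stabilizing contributions are negative in Hartree; by convention they are
reported as positive kcal/mol values, so conversion negates the sign. The
five descriptors do not sum to the binding energy (preparation/residual LED
terms are parsed over, not modelled) and no such identity is asserted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

from .errors import LedParseError, UnsupportedTopologyError

#: kcal/mol per Hartree.
HARTREE_TO_KCAL = 627.509474

SECTION_INTER_INTRA = "INTER- vs INTRA-FRAGMENT TOTAL ENERGIES"
SECTION_STRONG_PAIRS = "DECOMPOSITION OF CCSD STRONG PAIRS INTO DOUBLE EXCITATION TYPES"
SECTION_FINAL_SUMMARY = "FINAL SUMMARY DLPNO-CCSD ENERGY DECOMPOSITION"


@dataclass(frozen=True)
class RawLedRecord:
    """The nine labelled Hartree quantities of a two-fragment LED output."""

    total_energy: float
    intra_fragment_energies: tuple[float, float]
    inter_fragment_sum: float
    elstat: float
    exch: float
    ct_1_to_2: float
    ct_2_to_1: float
    disp_strong: float
    disp_weak: float

    def __post_init__(self) -> None:
        values = (
            self.total_energy,
            *self.intra_fragment_energies,
            self.inter_fragment_sum,
            self.elstat,
            self.exch,
            self.ct_1_to_2,
            self.ct_2_to_1,
            self.disp_strong,
            self.disp_weak,
        )
        if not all(math.isfinite(v) for v in values):
            raise ValueError("all LED fields must be finite")
        if len(self.intra_fragment_energies) != 2:
            raise UnsupportedTopologyError(
                f"expected 2 fragments, got {len(self.intra_fragment_energies)}"
            )


@dataclass(frozen=True)
class LedComponents:
    """The five kcal/mol descriptors (stabilizing contributions positive)."""

    binding_energy: float
    e_elstat: float
    e_exch: float
    e_ct: float
    e_disp: float

    def as_dict(self) -> dict[str, float]:
        return {
            "binding_energy": self.binding_energy,
            "e_elstat": self.e_elstat,
            "e_exch": self.e_exch,
            "e_ct": self.e_ct,
            "e_disp": self.e_disp,
        }


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the inter- vs intra-fragment bookkeeping check."""

    deviation: float
    tol: float
    passed: bool


_NUM = r"([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)"


def _section(text: str, header: str) -> str:
    start = text.find(header)
    if start < 0:
        raise LedParseError(f"missing section {header!r} in LED output")
    # A section runs until the next all-caps banner line or end of text.
    rest = text[start + len(header):]
    m = re.search(r"\n(?=[A-Z][A-Z -]{20,})", rest)
    return rest[: m.start()] if m else rest


def _labelled(section: str, label: str, section_name: str) -> float:
    pattern = re.escape(label) + r"[^=\n]*=\s*" + _NUM
    m = re.search(pattern, section)
    if not m:
        raise LedParseError(
            f"missing labelled line {label!r} in section {section_name!r}"
        )
    return float(m.group(1))


def _intra_fragment_energies(section: str) -> list[float]:
    pattern = r"Intra fragment\s+\d+[^=\n]*=\s*" + _NUM
    return [float(v) for v in re.findall(pattern, section)]


def parse_led_output(text: str) -> RawLedRecord:
    """Extract the nine labelled quantities from LED output text.

    Raises :class:`LedParseError` naming the missing section or line, and
    :class:`UnsupportedTopologyError` if the fragment count is not two.
    """
    inter_intra = _section(text, SECTION_INTER_INTRA)
    strong = _section(text, SECTION_STRONG_PAIRS)
    summary = _section(text, SECTION_FINAL_SUMMARY)

    total = _labelled(inter_intra, "Total energy", SECTION_INTER_INTRA)
    intras = _intra_fragment_energies(inter_intra)
    if len(intras) != 2:
        raise UnsupportedTopologyError(
            f"expected 2 intra-fragment energies, found {len(intras)}"
        )
    inter = _labelled(
        inter_intra, "Sum of INTER-fragment total energies", SECTION_INTER_INTRA
    )
    return RawLedRecord(
        total_energy=total,
        intra_fragment_energies=(intras[0], intras[1]),
        inter_fragment_sum=inter,
        elstat=_labelled(summary, "Electrostatics (REF.)", SECTION_FINAL_SUMMARY),
        exch=_labelled(summary, "Exchange (REF.)", SECTION_FINAL_SUMMARY),
        ct_1_to_2=_labelled(strong, "Charge Transfer 1 to 2", SECTION_STRONG_PAIRS),
        ct_2_to_1=_labelled(strong, "Charge Transfer 2 to 1", SECTION_STRONG_PAIRS),
        disp_strong=_labelled(
            summary, "Dispersion (strong pairs)", SECTION_FINAL_SUMMARY
        ),
        disp_weak=_labelled(summary, "Dispersion (weak pairs)", SECTION_FINAL_SUMMARY),
    )


def derive_components(
    raw: RawLedRecord, conversion: float = HARTREE_TO_KCAL
) -> LedComponents:
    """Group, convert to kcal/mol and sign-flip the raw LED quantities.

    Stabilizing (negative Hartree) contributions come out positive.
    """
    def c(value_eh: float) -> float:
        return -value_eh * conversion

    return LedComponents(
        binding_energy=c(raw.inter_fragment_sum),
        e_elstat=c(raw.elstat),
        e_exch=c(raw.exch),
        e_ct=c(raw.ct_1_to_2 + raw.ct_2_to_1),
        e_disp=c(raw.disp_strong + raw.disp_weak),
    )


def check_consistency(raw: RawLedRecord, tol: float = 1e-6) -> ConsistencyReport:
    """Verify total − Σ(intra) equals the inter-fragment sum within ``tol`` Eh.

    Binding energies derived the two ways must agree; a failure indicates a
    corrupted or truncated output file.
    """
    derived = raw.total_energy - sum(raw.intra_fragment_energies)
    deviation = abs(raw.inter_fragment_sum - derived)
    return ConsistencyReport(deviation=deviation, tol=tol, passed=deviation <= tol)


def components_table(
    entries: list[tuple[str, str, LedComponents]]
) -> pd.DataFrame:
    """Tidy per-complex descriptor table (kcal/mol) from parsed LED outputs."""
    rows = [
        {"complex_id": cid, "ligand": lig, **comp.as_dict()}
        for cid, lig, comp in entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "complex_id",
            "ligand",
            "binding_energy",
            "e_elstat",
            "e_exch",
            "e_ct",
            "e_disp",
        ],
    )
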