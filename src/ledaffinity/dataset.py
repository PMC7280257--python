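"""The affinity dataset: per-complex log(K_i) joined with LED descriptors."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import math

import pandas as pd

from .errors import SchemaError
from .led import LedComponents

#: Descriptor columns in canonical order.
PREDICTOR_COLUMNS = ("binding_energy", "e_elstat", "e_exch", "e_ct", "e_disp")

REQUIRED_COLUMNS = ("complex_id", "ligand", "log_ki") + PREDICTOR_COLUMNS


@dataclass(frozen=True)
class AffinityRecord:
    """One complex: identity, measured log10(K_i/nM) and its descriptors."""

    complex_id: str
    ligand: str
    log_ki: float
    components: LedComponents

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_ki):
            raise ValueError(f"log_ki for {self.complex_id} is not finite")


@dataclass(frozen=True)
class AffinityDataset:
    """Ordered collection of :class:`AffinityRecord` with unique complex ids."""

    records: tuple[AffinityRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.complex_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate complex ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def complex_ids(self) -> tuple[str, ...]:
        return tuple(r.complex_id for r in self.records)

    def subset(self, keep_ids: Iterable[str]) -> "AffinityDataset":
        keep = set(keep_ids)
        return AffinityDataset(
            tuple(r for r in self.records if r.complex_id in keep)
        )

    def drop(self, drop_ids: Iterable[str]) -> "AffinityDataset":
        gone = set(drop_ids)
        return AffinityDataset(
            tuple(r for r in self.records if r.complex_id not in gone)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "complex_id": r.complex_id,
                "ligand": r.ligand,
                "log_ki": r.log_ki,
                **r.components.as_dict(),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AffinityDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = tuple(
            AffinityRecord(
                complex_id=str(row.complex_id),
                ligand=str(row.ligand),
                log_ki=float(row.log_ki),
                components=LedComponents(
                    binding_energy=float(row.binding_energy),
                    e_elstat=float(row.e_elstat),
                    e_exch=float(row.e_exch),
                    e_ct=float(row.e_ct),
                    e_disp=float(row.e_disp),
                ),
            )
            for row in frame.itertuples()
        )
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "AffinityDataset":
        return cls.from_frame(pd.read_csv(path, comment="#"))


def load_reference_dataset() -> AffinityDataset:
    """The packaged seven-complex Torpedo californica AChE dataset."""
    with resources.files("ledaffinity.data").joinpath(
        "tcache_led_table.csv"
    ).open() as fh:
        return AffinityDataset.from_frame(pd.read_csv(fh, comment="#"))
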