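"""Chemical records, dataset I/O and the lipid normalizations of the endpoint.

The modelled endpoint is the dietary biomagnification factor normalized by
the lipid content of both the fish and its diet (BMF_L), on a log10 scale.
Datasets are flat CSV/TSV tables with a CAS number, a SMILES string, a data
quality category (high/medium/low, taken as given input labels) and the
Log BMF_L value.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import pandas as pd

from .graph import MolecularGraph, SmilesParseError, canonicalize, from_smiles

logger = logging.getLogger(__name__)

#: (label, rank); higher rank = better quality
class Quality(IntEnum):
    low = 0
    medium = 1
    high = 2


def validate_cas(cas: str) -> bool:
    """Check the NNN...-NN-N format and its checksum digit.

    The checksum is sum(position * digit) % 10 over the digits right of the
    check digit, counted from the right starting at 1.
    """
    parts = str(cas).strip().split("-")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        return False
    if len(parts[1]) != 2 or len(parts[2]) != 1:
        return False
    digits = parts[0] + parts[1]
    check = int(parts[2])
    total = sum((i + 1) * int(d) for i, d in enumerate(reversed(digits)))
    return total % 10 == check


@dataclass
class ChemicalRecord:
    cas: str
    smiles: str
    canonical_smiles: str
    quality: Quality
    log_bmf_l: float
    graph: MolecularGraph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not math.isfinite(self.log_bmf_l):
            raise ValueError(f"non-finite Log BMF_L for {self.cas}")


@dataclass
class Dataset:
    records: list[ChemicalRecord]
    name: str = "custom"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def responses(self) -> list[float]:
        return [r.log_bmf_l for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CAS": [r.cas for r in self.records],
                "SMILES": [r.smiles for r in self.records],
                "canonical_SMILES": [r.canonical_smiles for r in self.records],
                "quality": [r.quality.name for r in self.records],
                "LogBMFL": [r.log_bmf_l for r in self.records],
            }
        )


def make_record(cas: str, smiles: str, quality: str | Quality, log_bmf_l: float) -> ChemicalRecord:
    """Parse + curate one row into a record (raises on bad structures)."""
    g = from_smiles(smiles)
    q = quality if isinstance(quality, Quality) else Quality[str(quality).strip().lower()]
    return ChemicalRecord(
        cas=str(cas).strip(),
        smiles=smiles,
        canonical_smiles=canonicalize(g),
        quality=q,
        log_bmf_l=float(log_bmf_l),
        graph=g,
    )


def load_dataset(
    path: str | Path,
    name: str = "custom",
    columns: dict | None = None,
) -> tuple[Dataset, list[dict]]:
    """Load a CSV/TSV table of chemical records.

    Expected columns (remappable via ``columns``): CAS, SMILES, quality,
    LogBMFL.  Every row is parsed and curated; rows with unparsable
    structures or non-finite responses are excluded and reported in the
    returned exclusion log (list of dicts with row index, CAS and reason).
    Rows sharing a CAS but resolving to different structures are excluded
    as conflicting; rows sharing a structure under different CAS numbers
    draw a warning (offline surrogate for an identifier-consistency check).

    Returns
    -------
    (Dataset, exclusions)
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    colmap = {"cas": "CAS", "smiles": "SMILES", "quality": "quality", "log_bmf_l": "LogBMFL"}
    if columns:
        colmap.update(columns)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}; found {list(df.columns)}")

    records: list[ChemicalRecord] = []
    exclusions: list[dict] = []
    for idx, row in df.iterrows():
        cas = str(row[colmap["cas"]]).strip()
        try:
            rec = make_record(cas, str(row[colmap["smiles"]]), str(row[colmap["quality"]]),
                              float(row[colmap["log_bmf_l"]]))
        except (SmilesParseError, ValueError, KeyError) as exc:
            exclusions.append({"row": int(idx), "cas": cas, "reason": str(exc)})
            logger.warning("excluded row %s (%s): %s", idx, cas, exc)
            continue
        if not validate_cas(rec.cas):
            warnings.warn(f"CAS {rec.cas!r} fails format/checksum validation", stacklevel=2)
        records.append(rec)

    # duplicate CAS with conflicting structures -> flag, do not silently merge
    by_cas: dict[str, str] = {}
    keep = []
    conflicted = set()
    for rec in records:
        prev = by_cas.setdefault(rec.cas, rec.canonical_smiles)
        if prev != rec.canonical_smiles:
            conflicted.add(rec.cas)
    for rec in records:
        if rec.cas in conflicted:
            exclusions.append(
                {"row": None, "cas": rec.cas, "reason": "duplicate CAS with conflicting structures"}
            )
        else:
            keep.append(rec)

    # same structure under different CAS numbers -> advisory warning
    by_struct: dict[str, str] = {}
    for rec in keep:
        prev = by_struct.setdefault(rec.canonical_smiles, rec.cas)
        if prev != rec.cas:
            warnings.warn(
                f"CAS {rec.cas} and {prev} share canonical structure {rec.canonical_smiles}",
                stacklevel=2,
            )
    return Dataset(records=keep, name=name), exclusions


def merge_replicates(ds: Dataset) -> Dataset:
    """Average replicate Log BMF_L values per canonical structure.

    The merged record keeps the arithmetic mean of the replicates and the
    best quality label among them; its CAS/SMILES come from the first
    occurrence.  The number of distinct structures never changes.
    """
    groups: dict[str, list[ChemicalRecord]] = {}
    order: list[str] = []
    for rec in ds.records:
        if rec.canonical_smiles not in groups:
            order.append(rec.canonical_smiles)
        groups.setdefault(rec.canonical_smiles, []).append(rec)
    merged = []
    for key in order:
        members = groups[key]
        first = members[0]
        if len(members) == 1:
            merged.append(first)
        else:
            merged.append(
                replace(
                    first,
                    log_bmf_l=sum(m.log_bmf_l for m in members) / len(members),
                    quality=max(m.quality for m in members),
                )
            )
    return Dataset(records=merged, name=ds.name)


def lipid_normalize(bmf: float, l_diet: float, l_fish: float) -> float:
    """BMF_L = BMF * L_diet / L_fish (lipid-normalized biomagnification factor)."""
    if l_diet <= 0 or l_fish <= 0:
        raise ValueError("lipid fractions must be positive")
    if bmf < 0:
        raise ValueError("BMF must be non-negative")
    return bmf * l_diet / l_fish


def bmf_five_percent(bmf: float, l_fish: float) -> float:
    """BMF_5% = (BMF / L_fish) * 0.05, i.e. standardized to 5% fish lipid."""
    if l_fish <= 0:
        raise ValueError("fish lipid fraction must be positive")
    if bmf < 0:
        raise ValueError("BMF must be non-negative")
    return bmf / l_fish * 0.05
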