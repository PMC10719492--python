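"""Residue encoding and feature-vector construction.

Each amino acid is encoded by four physical parameters: number of
side-chain non-hydrogen atoms, compactness (atoms on the shortest bond
path from C-beta to the most distal side-chain atom), formal charge
(with +0.5 for histidine) and Eisenberg consensus hydrophobicity.  The
values ship as a packaged TSV (``data/encoding.tsv``) so the table is
auditable and swappable; compactness values were derived from canonical
side-chain bond topologies.

Four feature schemas are supported:

========  =========  ============  ======
name      positions  loop lengths  length
========  =========  ============  ======
gbr1      13         no            52
gbr2      13         yes           55
gbr3      37         no            148
gbr4      37         yes           151
========  =========  ============  ======

Positions absent from a structure (short CDRs leave inserted positions
such as H100C unoccupied) encode as the all-zero gap vector; this
convention must be identical at training and prediction time.  Loop
lengths count occupied Chothia positions, insertion codes included, in
CDR-L1 (L24-L34), CDR-H2 (H50-H58) and CDR-H3 (H95-H102).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .structure_io import FvStructure, ResidueKey

ENCODING_CHANNELS = ("sidechain_atoms", "compactness", "charge", "hydrophobicity")

GAP_VECTOR = np.zeros(4)

_13_POSITIONS = (
    "L38", "L40", "L41", "L44", "L46", "L87",
    "H33", "H42", "H45", "H60", "H62", "H91", "H105",
)
_37_POSITIONS = (
    "L32", "L34", "L36", "L38", "L40", "L41", "L43", "L44", "L46", "L50",
    "L86", "L87", "L89", "L91", "L96", "L98",
    "H33", "H35", "H39", "H42", "H45", "H47", "H50", "H60", "H62", "H91",
    "H99", "H100", "H100A", "H100B", "H100C", "H100D", "H100E", "H100F",
    "H100G", "H103", "H105",
)

#: Inclusive Chothia number ranges of the three most length-variable CDRs.
CDR_RANGES = {
    "l1": ("L", 24, 34),
    "h2": ("H", 50, 58),
    "h3": ("H", 95, 102),
}


class UnknownResidueError(ValueError):
    """An amino-acid code outside the 20 standard one-letter codes."""


@dataclass(frozen=True)
class EncodingTable:
    """The four-parameter residue encoding, one row per amino acid."""

    values: Mapping[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"encoding table must have 20 entries, got {len(self.values)}")

    def encode(self, aa: str | None) -> np.ndarray:
        if aa is None or aa == "-":
            return GAP_VECTOR.copy()
        try:
            return np.asarray(self.values[aa], dtype=float)
        except KeyError:
            raise UnknownResidueError(f"unknown amino-acid code {aa!r}") from None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            dict(self.values), orient="index", columns=list(ENCODING_CHANNELS)
        ).rename_axis("aa")


@lru_cache(maxsize=1)
def load_encoding_table() -> EncodingTable:
    """Load the packaged encoding table."""
    with resources.files("abypap.data").joinpath("encoding.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="aa")
    return EncodingTable(
        values={aa: tuple(row[c] for c in ENCODING_CHANNELS) for aa, row in df.iterrows()}
    )


@dataclass(frozen=True)
class FeatureSchema:
    """An ordered residue-position set, optionally with CDR loop lengths."""

    name: str
    residue_positions: tuple[ResidueKey, ...]
    include_loop_lengths: bool

    @property
    def length(self) -> int:
        return 4 * len(self.residue_positions) + (3 if self.include_loop_lengths else 0)


def _keys(names: tuple[str, ...]) -> tuple[ResidueKey, ...]:
    return tuple(ResidueKey.parse(n) for n in names)


SCHEMAS = {
    "gbr1": FeatureSchema("gbr1", _keys(_13_POSITIONS), include_loop_lengths=False),
    "gbr2": FeatureSchema("gbr2", _keys(_13_POSITIONS), include_loop_lengths=True),
    "gbr3": FeatureSchema("gbr3", _keys(_37_POSITIONS), include_loop_lengths=False),
    "gbr4": FeatureSchema("gbr4", _keys(_37_POSITIONS), include_loop_lengths=True),
}


def get_schema(name: str | FeatureSchema) -> FeatureSchema:
    if isinstance(name, FeatureSchema):
        return name
    try:
        return SCHEMAS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown schema {name!r}; choose from {sorted(SCHEMAS)}") from None


@dataclass
class FeatureVector:
    """Encoded features for one antibody under one schema."""

    schema: str
    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = get_schema(self.schema).length
        if self.values.shape != (expected,):
            raise ValueError(
                f"schema {self.schema} expects {expected} values, got {self.values.shape}"
            )


def encode_residue(aa: str | None, table: EncodingTable | None = None) -> np.ndarray:
    """Four-parameter encoding of one amino acid; ``None`` gives the gap vector."""
    return (table or load_encoding_table()).encode(aa)


def _as_sequence_map(obj) -> Mapping[ResidueKey, str]:
    if isinstance(obj, FvStructure):
        return obj.sequence_map
    if isinstance(obj, Mapping):
        out = {}
        for k, v in obj.items():
            key = k if isinstance(k, ResidueKey) else ResidueKey.parse(str(k))
            out[key] = v
        return out
    raise TypeError(f"expected FvStructure or position->aa mapping, got {type(obj)!r}")


def loop_lengths(obj) -> tuple[int, int, int]:
    """Occupied-position counts of CDR-L1, CDR-H2 and CDR-H3.

    A position counts if its Chothia number falls in the CDR's inclusive
    range, whatever its insertion code (H100A counts for H95-H102).
    """
    seq = _as_sequence_map(obj)
    counts = []
    for chain, lo, hi in CDR_RANGES.values():
        counts.append(sum(1 for k in seq if k.chain_kind == chain and lo <= k.number <= hi))
    return tuple(counts)  # type: ignore[return-value]


def featurize(
    obj,
    schema: str | FeatureSchema = "gbr4",
    table: EncodingTable | None = None,
) -> FeatureVector:
    """Encode an Fv structure or numbered sequence under a feature schema.

    ``obj`` may be an :class:`FvStructure` or any mapping of positions
    (ResidueKey or strings like ``"H100A"``) to one-letter codes.
    """
    schema = get_schema(schema)
    table = table or load_encoding_table()
    seq = _as_sequence_map(obj)
    parts = [table.encode(seq.get(key)) for key in schema.residue_positions]
    if schema.include_loop_lengths:
        parts.append(np.asarray(loop_lengths(seq), dtype=float))
    source_id = obj.id if isinstance(obj, FvStructure) else ""
    return FeatureVector(schema=schema.name, values=np.concatenate(parts), source_id=source_id)


def feature_residue_string(obj, schema: str | FeatureSchema = "gbr4") -> str:
    """The amino acids at the schema positions, '-' marking absent ones."""
    schema = get_schema(schema)
    seq = _as_sequence_map(obj)
    return "".join(seq.get(key, "-") for key in schema.residue_positions)
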