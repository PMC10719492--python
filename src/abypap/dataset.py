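"""Dataset construction: quality filtering, non-redundantization, splitting.

The training data are built from a directory of Chothia-numbered Fv
structures.  Structures are kept only if they are genuine VL/VH
heterodimers solved by X-ray crystallography at 3.0 A or better with no
missing residues.  Records are then made non-redundant on the pair
(feature residues, packing angle rounded to 2 dp): identical pairs keep
only their first occurrence, while identical residues with genuinely
different angles all survive, preserving flexible antibodies whose angle
depends on binding status or crystal form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSchema, get_schema, feature_residue_string, loop_lengths
from .geometry import CONSERVED_HEAVY, CONSERVED_LIGHT, packing_angle
from .structure_io import FvStructure

logger = logging.getLogger(__name__)

MAX_RESOLUTION = 3.0

DATASET_COLUMNS = ("id", "residues", "l1", "h2", "h3", "angle_deg", "resolution")


@dataclass(frozen=True)
class AngleRecord:
    """One antibody: its feature residues, loop lengths and packing angle."""

    id: str
    feature_residues: str
    angle_deg: float
    loop_lengths: tuple[int, int, int] | None = None
    resolution: float | None = None

    def dedup_key(self) -> tuple[str, float]:
        # round-half-even at 2 dp, matching the reported angle precision
        return (self.feature_residues, round(self.angle_deg, 2))


@dataclass
class DatasetSplit:
    train: list[AngleRecord]
    test: list[AngleRecord]
    seed: int


def _has_internal_gap(chain: dict) -> bool:
    numbers = {k.number for k in chain}
    if not numbers:
        return True
    return bool(set(range(min(numbers), max(numbers) + 1)) - numbers)


def quality_filter(
    fvs: Iterable[FvStructure],
) -> tuple[list[FvStructure], list[tuple[str, str]]]:
    """Apply the structure-quality filters.

    Keeps a structure iff both chains are present, the experimental
    method is X-ray crystallography, resolution is 3.0 A or better, and
    no residues are missing.  "Missing residues" means an internal gap in
    either chain's numbering or any of the sixteen conserved geometry
    positions lacking a C-alpha; whole-chain completeness cannot be
    checked without reference sequences, so this numbering-based policy
    is the default and is recorded here.

    Returns ``(kept, rejected)`` where each rejection carries its first
    failing reason: ``chains``, ``method``, ``resolution`` or ``missing``.
    """
    kept: list[FvStructure] = []
    rejected: list[tuple[str, str]] = []
    geometry_keys = CONSERVED_LIGHT + CONSERVED_HEAVY
    for fv in fvs:
        if not fv.light or not fv.heavy:
            rejected.append((fv.id, "chains"))
            continue
        if not fv.method or "X-RAY" not in fv.method.upper():
            rejected.append((fv.id, "method"))
            continue
        if fv.resolution is None or fv.resolution > MAX_RESOLUTION:
            rejected.append((fv.id, "resolution"))
            continue
        missing_geom = any(
            fv.get(k) is None or fv.get(k).ca is None for k in geometry_keys
        )
        if missing_geom or _has_internal_gap(fv.light) or _has_internal_gap(fv.heavy):
            rejected.append((fv.id, "missing"))
            continue
        kept.append(fv)
    return kept, rejected


def build_records(
    fvs: Iterable[FvStructure],
    schema: str | FeatureSchema = "gbr4",
) -> list[AngleRecord]:
    """Summarise each structure as (feature residues, loop lengths, angle)."""
    schema = get_schema(schema)
    records = []
    for fv in fvs:
        records.append(
            AngleRecord(
                id=fv.id,
                feature_residues=feature_residue_string(fv, schema),
                angle_deg=packing_angle(fv).degrees,
                loop_lengths=loop_lengths(fv),
                resolution=fv.resolution,
            )
        )
    return records


def deduplicate(records: Sequence[AngleRecord]) -> list[AngleRecord]:
    """Non-redundantize on (feature residues, angle rounded to 2 dp).

    The first occurrence of each key survives; input order is preserved.
    Loop lengths are deliberately not part of the key.  Records with
    identical residues but different rounded angles all survive.
    """
    seen: set[tuple[str, float]] = set()
    out: list[AngleRecord] = []
    for rec in records:
        key = rec.dedup_key()
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def split(
    records: Sequence[AngleRecord],
    test_fraction: float = 0.1,
    seed: int = 100,
) -> DatasetSplit:
    """Random train/test partition (default: 10% test), reproducible by seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least two records to split")
    n_test = min(n - 1, max(1, round(n * test_fraction)))
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


def temporal_holdout(
    old: Sequence[AngleRecord], new: Sequence[AngleRecord]
) -> list[AngleRecord]:
    """Records of ``new`` absent from ``old``, by non-redundantization key.

    Used to build an independent validation set from structures deposited
    after the training snapshot.
    """
    old_keys = {r.dedup_key() for r in old}
    return [r for r in new if r.dedup_key() not in old_keys]


def to_frame(records: Sequence[AngleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        l1, h2, h3 = r.loop_lengths if r.loop_lengths is not None else ("", "", "")
        rows.append((r.id, r.feature_residues, l1, h2, h3, r.angle_deg, r.resolution))
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS))


def write_dataset(records: Sequence[AngleRecord], path: str | Path) -> None:
    to_frame(records).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> list[AngleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"residues": str})
    records = []
    for row in df.itertuples(index=False):
        lengths = None
        if not (pd.isna(row.l1) or row.l1 == ""):
            lengths = (int(row.l1), int(row.h2), int(row.h3))
        resolution = None if pd.isna(row.resolution) else float(row.resolution)
        records.append(
            AngleRecord(
                id=str(row.id),
                feature_residues=row.residues,
                angle_deg=float(row.angle_deg),
                loop_lengths=lengths,
                resolution=resolution,
            )
        )
    return records


def prepare_dataset(
    pdb_dir: str | Path,
    schema: str | FeatureSchema = "gbr4",
    light_chain: str = "L",
    heavy_chain: str = "H",
) -> tuple[list[AngleRecord], list[tuple[str, str]]]:
    """Directory of Fv PDB files -> filtered, non-redundant angle records."""
    from .structure_io import read_fv

    fvs = []
    rejected: list[tuple[str, str]] = []
    for path in sorted(Path(pdb_dir).glob("*.pdb")):
        try:
            fvs.append(read_fv(path, light_chain=light_chain, heavy_chain=heavy_chain))
        except (OSError, ValueError) as exc:
            logger.warning("unreadable %s: %s", path.name, exc)
            rejected.append((path.stem, "unreadable"))
    kept, filtered = quality_filter(fvs)
    rejected.extend(filtered)
    records = deduplicate(build_records(kept, schema))
    return records, rejected
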