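"""Reading and writing Chothia-numbered antibody Fv structures.

Input files are AbDb-style PDB files: one Fv per file, already split and
renumbered, with the light and heavy chains conventionally labelled ``L``
and ``H``.  Only residue identity and the C-alpha coordinate are retained;
that is all the packing-angle geometry and the sequence features need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Common non-standard residues mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "M",  # selenomethionine, by far the most frequent in X-ray entries
    "HYP": "P",
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "CSO": "C",
    "MLY": "K",
    "PCA": "E",
}

_THREE_LETTER = {one: three for three, one in protein_letters_3to1.items()}


class FvParseError(ValueError):
    """The file could not be interpreted as a single light/heavy Fv pair."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Chothia position of one residue: chain kind, number, insertion code.

    Ordering is (chain_kind, number, insertion) with the empty insertion
    code sorting before 'A', so H100 < H100A < H100B.
    """

    chain_kind: str  # 'L' or 'H'
    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.chain_kind not in ("L", "H"):
            raise ValueError(f"chain_kind must be 'L' or 'H', got {self.chain_kind!r}")
        if self.number <= 0:
            raise ValueError(f"residue number must be positive, got {self.number}")

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        """Parse a position written like ``L38`` or ``H100A``."""
        text = text.strip().upper()
        if len(text) < 2 or text[0] not in "LH":
            raise ValueError(f"cannot parse residue key {text!r}")
        body = text[1:]
        insertion = ""
        if body and body[-1].isalpha():
            insertion = body[-1]
            body = body[:-1]
        return cls(text[0], int(body), insertion)

    def __str__(self) -> str:
        return f"{self.chain_kind}{self.number}{self.insertion}"


@dataclass
class NumberedResidue:
    """One residue: its position key, one-letter identity and optional C-alpha."""

    key: ResidueKey
    aa: str
    ca: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA:
            raise ValueError(f"{self.key}: non-standard amino acid {self.aa!r}")
        if self.ca is not None:
            self.ca = np.asarray(self.ca, dtype=float)
            if self.ca.shape != (3,) or not np.all(np.isfinite(self.ca)):
                raise ValueError(f"{self.key}: C-alpha must be a finite 3-vector")


@dataclass
class FvStructure:
    """One Fv: ordered light- and heavy-chain residue maps plus metadata."""

    id: str
    light: dict[ResidueKey, NumberedResidue] = field(default_factory=dict)
    heavy: dict[ResidueKey, NumberedResidue] = field(default_factory=dict)
    resolution: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        self.light = dict(sorted(self.light.items()))
        self.heavy = dict(sorted(self.heavy.items()))

    def get(self, key: ResidueKey | str) -> NumberedResidue | None:
        """Look up a residue by position; absence is a normal value.

        Short CDR loops legitimately leave inserted positions (e.g. H100C)
        unoccupied, so a missing key returns ``None`` rather than raising.
        """
        if isinstance(key, str):
            key = ResidueKey.parse(key)
        chain = self.light if key.chain_kind == "L" else self.heavy
        return chain.get(key)

    def residues(self) -> Iterator[NumberedResidue]:
        yield from self.light.values()
        yield from self.heavy.values()

    @property
    def sequence_map(self) -> Mapping[ResidueKey, str]:
        return {r.key: r.aa for r in self.residues()}


def get_residue(fv: FvStructure, key: ResidueKey | str) -> NumberedResidue | None:
    """Functional alias for :meth:`FvStructure.get`."""
    return fv.get(key)


def _one_letter(resname: str, label: str) -> str | None:
    resname = resname.strip().upper()
    if resname in protein_letters_3to1:
        return protein_letters_3to1[resname]
    if resname in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[resname]
    warnings.warn(f"{label}: no standard mapping for residue {resname}; skipped")
    return None


def read_fv(
    path: str | Path,
    light_chain: str = "L",
    heavy_chain: str = "H",
) -> FvStructure:
    """Read one Chothia-numbered Fv from a PDB file.

    Parameters
    ----------
    path
        PDB file with exactly one light and one heavy chain.  Header
        records (EXPDTA, REMARK 2) are used when present; files without
        headers are accepted with unknown method/resolution.
    light_chain, heavy_chain
        Chain identifiers to treat as VL and VH.  AbDb labels them
        ``L``/``H``; override for files using other labels.

    Only altloc ' ' or 'A' atoms are kept (single-conformer convention).
    Residue numbers and insertion codes are taken verbatim -- no
    renumbering is attempted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    header = parser.get_header() or {}

    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if light_chain not in chains or heavy_chain not in chains:
        raise FvParseError(
            f"{path.name}: need chains {light_chain!r} (light) and "
            f"{heavy_chain!r} (heavy); found {sorted(chains)}"
        )
    extra = set(chains) - {light_chain, heavy_chain}
    if extra:
        raise FvParseError(
            f"{path.name}: expected exactly one light/heavy pair, "
            f"found extra chains {sorted(extra)}"
        )

    fv = FvStructure(
        id=path.stem,
        resolution=header.get("resolution"),
        method=(header.get("structure_method") or None),
    )
    for kind, chain_id in (("L", light_chain), ("H", heavy_chain)):
        target = fv.light if kind == "L" else fv.heavy
        for residue in chains[chain_id]:
            resseq = residue.id[1]
            icode = residue.id[2].strip()
            if resseq <= 0:
                continue
            aa = _one_letter(residue.get_resname(), f"{path.name} {kind}{resseq}{icode}")
            if aa is None:
                continue
            ca = None
            if "CA" in residue:
                atom = residue["CA"]
                if atom.is_disordered():
                    picked = None
                    for child in atom.disordered_get_list():
                        if child.get_altloc() in (" ", "A"):
                            picked = child
                            break
                    atom = picked
                if atom is not None:
                    ca = np.asarray(atom.get_coord(), dtype=float)
            key = ResidueKey(kind, resseq, icode)
            target[key] = NumberedResidue(key=key, aa=aa, ca=ca)

    if not fv.light or not fv.heavy:
        raise FvParseError(f"{path.name}: empty light or heavy chain")
    fv.__post_init__()  # re-sort after population
    return fv


def write_fv(fv: FvStructure, path: str | Path) -> None:
    """Write an Fv back to a minimal PDB file (C-alpha trace only).

    Emits EXPDTA and REMARK 2 headers when method/resolution are known, so
    a round trip preserves (keys, aa, ca) plus the quality metadata.
    """
    path = Path(path)
    lines: list[str] = []
    if fv.method:
        lines.append(f"EXPDTA    {fv.method.upper()}")
    if fv.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {fv.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain_id, chain in (("L", fv.light), ("H", fv.heavy)):
        for res in chain.values():
            if res.ca is None:
                continue
            x, y, z = res.ca
            resname = _THREE_LETTER[res.aa]
            icode = res.key.insertion or " "
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {chain_id}{res.key.number:4d}"
                f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_numbered_sequence(path: str | Path) -> dict[ResidueKey, str]:
    """Read a numbered-sequence file: one ``<position> <aa>`` pair per line.

    Example lines: ``L38 Q`` or ``H100A Y``.  Blank lines and lines
    starting with ``#`` are ignored.
    """
    out: dict[ResidueKey, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"bad numbered-sequence line: {raw!r}")
        key = ResidueKey.parse(parts[0])
        aa = parts[1].upper()
        if aa not in STANDARD_AA:
            raise ValueError(f"{key}: unknown amino acid {aa!r}")
        out[key] = aa
    return dict(sorted(out.items()))
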