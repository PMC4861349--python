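"""PDB coordinate I/O for C-alpha traces.

Reads multi-model PDB files into per-model :class:`CalphaStructure` objects
(each MODEL is treated as a separate conformer), resolves alternate locations
to the highest-occupancy copy, and writes fixed-width PDB back out.  Residue
identity is keyed by ``(residue_number, insertion_code)``; only C-alpha atoms
are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ExperimentalMethod",
    "CalphaStructure",
    "Correspondence",
    "ChainNotFoundError",
    "EmptyTraceError",
    "DisjointNumberingError",
    "read_structures",
    "write_structures",
    "build_correspondence",
    "coverage",
]


class ChainNotFoundError(ValueError):
    """Requested chain identifier is absent from the file."""


class EmptyTraceError(ValueError):
    """No C-alpha atoms found for the requested selection."""


class DisjointNumberingError(ValueError):
    """Two structures share no residue numbers; no correspondence exists."""


class ExperimentalMethod(str, Enum):
    XRD = "XRD"
    NMR = "NMR"
    MODEL = "MODEL"
    SYNTHETIC = "SYNTHETIC"


def _one_letter(res_name: str) -> str:
    try:
        code = ProteinSequence.convert_letter_3to1(res_name.strip())
    except KeyError:
        return "X"
    return code if len(code) == 1 else "X"


@dataclass
class CalphaStructure:
    """An ordered C-alpha trace of one conformer, decoy, or model.

    Residues are stored as parallel arrays sorted by
    ``(residue_number, insertion_code)``.
    """

    structure_id: str
    model_number: int
    chain_id: str
    res_nums: np.ndarray  # (n,) int
    coords: np.ndarray  # (n, 3) float, Angstrom
    amino_acids: tuple[str, ...] = ()
    icodes: tuple[str, ...] = ()
    method: ExperimentalMethod = ExperimentalMethod.MODEL

    def __post_init__(self) -> None:
        self.res_nums = np.asarray(self.res_nums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_nums)
        if n < 1:
            raise EmptyTraceError("structure must contain at least one residue")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.amino_acids:
            self.amino_acids = ("X",) * n
        if not self.icodes:
            self.icodes = ("",) * n
        if len(self.amino_acids) != n or len(self.icodes) != n:
            raise ValueError("amino_acids/icodes length mismatch")
        if self.model_number < 1:
            raise ValueError("model_number must be >= 1")
        ids = self.residue_ids
        if any(a >= b for a, b in zip(ids, ids[1:])):
            raise ValueError("residue identifiers must be strictly increasing")

    @property
    def residue_ids(self) -> list[tuple[int, str]]:
        """Ordered ``(residue_number, insertion_code)`` keys."""
        return list(zip(self.res_nums.tolist(), self.icodes))

    @property
    def residues(self) -> Iterator[tuple[int, str, np.ndarray]]:
        for num, aa, xyz in zip(self.res_nums, self.amino_acids, self.coords):
            yield int(num), aa, xyz

    def __len__(self) -> int:
        return len(self.res_nums)

    @property
    def conformer_key(self) -> str:
        return f"{self.structure_id}/{self.model_number}"

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaStructure":
        """Copy with coordinates mapped through ``x -> R x + t``."""
        return CalphaStructure(
            structure_id=self.structure_id,
            model_number=self.model_number,
            chain_id=self.chain_id,
            res_nums=self.res_nums.copy(),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            amino_acids=self.amino_acids,
            icodes=self.icodes,
            method=self.method,
        )

    def subset(self, keep: Sequence[int]) -> "CalphaStructure":
        """Copy containing only the residues at positional indices ``keep``."""
        keep = np.asarray(sorted(keep), dtype=int)
        return CalphaStructure(
            structure_id=self.structure_id,
            model_number=self.model_number,
            chain_id=self.chain_id,
            res_nums=self.res_nums[keep],
            coords=self.coords[keep],
            amino_acids=tuple(self.amino_acids[i] for i in keep),
            icodes=tuple(self.icodes[i] for i in keep),
            method=self.method,
        )


@dataclass(frozen=True)
class Correspondence:
    """Positional index pairs matching a model to a reference by residue id."""

    pairs: tuple[tuple[int, int], ...]
    n_reference: int

    def __post_init__(self) -> None:
        if len(self.pairs) > self.n_reference:
            raise ValueError("more pairs than reference residues")
        prev_m, prev_r = -1, -1
        for m, r in self.pairs:
            if m <= prev_m or r <= prev_r:
                raise ValueError("pairs must be strictly increasing in both columns")
            if r >= self.n_reference:
                raise ValueError("reference index out of bounds")
            prev_m, prev_r = m, r

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def model_indices(self) -> np.ndarray:
        return np.array([m for m, _ in self.pairs], dtype=int)

    @property
    def reference_indices(self) -> np.ndarray:
        return np.array([r for _, r in self.pairs], dtype=int)


def _method_from_lines(lines: list[str]) -> Optional[ExperimentalMethod]:
    for line in lines:
        if line.startswith("EXPDTA"):
            text = line[6:].upper()
            if "NMR" in text:
                return ExperimentalMethod.NMR
            if "X-RAY" in text or "XRD" in text:
                return ExperimentalMethod.XRD
            if "SYNTHETIC" in text:
                return ExperimentalMethod.SYNTHETIC
            return ExperimentalMethod.MODEL
    return None


def read_structures(
    path: str | Path,
    chain: Optional[str] = None,
    structure_id: Optional[str] = None,
) -> list[CalphaStructure]:
    """Read a PDB file into one C-alpha trace per MODEL record.

    Parameters
    ----------
    path:
        PDB-format file with ATOM records.
    chain:
        Chain identifier to extract.  If omitted, the first chain that
        contains C-alpha atoms is used.
    structure_id:
        Identifier stored on the returned structures; defaults to the file
        stem.

    Raises
    ------
    ChainNotFoundError
        If ``chain`` is given but not present.
    EmptyTraceError
        If the selection yields zero C-alpha atoms.
    """
    path = Path(path)
    sid = structure_id if structure_id is not None else path.stem
    pdb = PDBFile.read(path)
    with open(path) as fh:
        header = [line for line in fh if not line.startswith(("ATOM", "HETATM"))]
    method = _method_from_lines(header) or ExperimentalMethod.MODEL

    n_models = pdb.get_model_count()
    structures: list[CalphaStructure] = []
    for model in range(1, n_models + 1):
        atoms = pdb.get_structure(model=model, altloc="occupancy")
        is_ca = (atoms.atom_name == "CA") & ~atoms.hetero
        # guard against calcium ions sharing the CA atom name
        is_ca &= np.char.strip(atoms.element.astype(str)) != "CA"
        atoms = atoms[is_ca]
        if atoms.array_length() == 0:
            raise EmptyTraceError(f"{path}: no C-alpha atoms in model {model}")
        chains_present = list(dict.fromkeys(atoms.chain_id.tolist()))
        if chain is None:
            use_chain = chains_present[0]
        elif chain in chains_present:
            use_chain = chain
        else:
            raise ChainNotFoundError(
                f"{path}: chain {chain!r} not found (available: {chains_present})"
            )
        atoms = atoms[atoms.chain_id == use_chain]
        order = np.lexsort((atoms.ins_code, atoms.res_id))
        atoms = atoms[order]
        structures.append(
            CalphaStructure(
                structure_id=sid,
                model_number=model,
                chain_id=str(use_chain),
                res_nums=atoms.res_id.astype(int),
                coords=atoms.coord.astype(float),
                amino_acids=tuple(_one_letter(r) for r in atoms.res_name),
                icodes=tuple(str(i) for i in atoms.ins_code),
                method=method,
            )
        )
    return structures


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

_EXPDTA_TEXT = {
    ExperimentalMethod.NMR: "SOLUTION NMR",
    ExperimentalMethod.XRD: "X-RAY DIFFRACTION",
    ExperimentalMethod.SYNTHETIC: "SYNTHETIC",
}


def write_structures(structures: Sequence[CalphaStructure], path: str | Path) -> None:
    """Write C-alpha traces as fixed-width PDB v3.3 ATOM records.

    Multiple structures are wrapped in MODEL/ENDMDL blocks so that
    :func:`read_structures` recovers them as separate conformers.
    """
    if not structures:
        raise ValueError("nothing to write")
    lines: list[str] = []
    method = structures[0].method
    if method in _EXPDTA_TEXT:
        lines.append(f"EXPDTA    {_EXPDTA_TEXT[method]}")
    multi = len(structures) > 1
    for k, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 1
        for (num, icode), aa, xyz in zip(s.residue_ids, s.amino_acids, s.coords):
            res3 = _ONE_TO_THREE.get(aa, "UNK")
            lines.append(
                f"ATOM  {serial:5d}  CA  {res3:>3s} {s.chain_id:1s}{num:4d}"
                f"{icode or ' ':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}           C  "
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def build_correspondence(model: CalphaStructure, reference: CalphaStructure) -> Correspondence:
    """Match residues of ``model`` to ``reference`` by residue identifier.

    Raises :class:`DisjointNumberingError` when no residue ids are shared.
    """
    ref_index = {rid: i for i, rid in enumerate(reference.residue_ids)}
    pairs = [
        (i, ref_index[rid])
        for i, rid in enumerate(model.residue_ids)
        if rid in ref_index
    ]
    if not pairs:
        raise DisjointNumberingError(
            f"{model.conformer_key} and {reference.conformer_key} share no residue numbers"
        )
    return Correspondence(pairs=tuple(pairs), n_reference=len(reference))


def coverage(
    model: CalphaStructure, reference: CalphaStructure
) -> tuple[float, int]:
    """Fraction of reference residues present in the model, and the longest
    run of consecutive reference positions absent from it."""
    corr = build_correspondence(model, reference)
    frac = len(corr) / corr.n_reference
    present = np.zeros(corr.n_reference, dtype=bool)
    present[corr.reference_indices] = True
    max_run = run = 0
    for p in present:
        run = 0 if p else run + 1
        max_run = max(max_run, run)
    return frac, max_run
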