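"""Dialect-preserving PDB reading and writing.

The reader keeps author residue numbering, insertion codes and chain IDs
verbatim (structure-prediction and crystallographic files frequently start
at arbitrary numbers, and downstream reports must quote those numbers).
HETATM records are retained and CONECT records become bonds.  The writer
round-trips everything the reader keeps, to the format's 3-decimal
coordinate precision.
"""

from __future__ import annotations

import os
from pathlib import Path

from glycokit.core.model import AtomRecord, MolecularModel


class PDBParseError(ValueError):
    """A line could not be interpreted; the message names the line number."""


class EmptyStructureError(ValueError):
    """The input contained no ATOM/HETATM records."""


class SerialOverflowError(ValueError):
    """More than 99999 atoms cannot be written in fixed-width PDB."""


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _guess_element(name: str) -> str:
    """Element from the atom-name column when columns 77-78 are blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. "1HB"
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short: {line!r}")
    try:
        serial = int(line[6:11])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed numeric field: {line!r}") from exc
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    residue_name = line[17:20].strip()
    chain = line[21:22].strip()
    try:
        residue_number = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed residue number: {line!r}") from exc
    icode = line[26:27].strip()
    occupancy = 1.0
    b_factor = 0.0
    if len(line) >= 60 and line[54:60].strip():
        occupancy = float(line[54:60])
    if len(line) >= 66 and line[60:66].strip():
        b_factor = float(line[60:66])
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        insertion_code=icode,
        chain=chain,
        coordinates=(x, y, z),
        occupancy=occupancy,
        b_factor=b_factor,
        het=line.startswith("HETATM"),
        altloc=altloc,
    )


def read_structure(source: str | os.PathLike, model_select: str = "all") -> list[MolecularModel]:
    """Parse PDB text (or a path to it) into one model per MODEL block.

    Parameters
    ----------
    source:
        PDB-format text, or a path to a file containing it.  A string is
        treated as text if it contains a newline or a known record name.
    model_select:
        ``"all"`` (default) or ``"first"``.

    Returns
    -------
    list of MolecularModel, in file order.  CONECT records are converted to
    bonds and applied to every model (serial numbers are resolved per model).
    """
    if model_select not in ("all", "first"):
        raise ValueError("model_select must be 'all' or 'first'")
    text = _as_text(source)
    models: list[MolecularModel] = []
    current: list[AtomRecord] = []
    conect_pairs: set[tuple[int, int]] = set()
    model_id = 1
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                models.append(MolecularModel(atoms=current, model_id=model_id))
                current = []
            field = line[6:].strip()
            model_id = int(field) if field else len(models) + 1
            in_model = True
        elif rec == "ENDMDL":
            models.append(MolecularModel(atoms=current, model_id=model_id))
            current = []
            in_model = False
            model_id = len(models) + 1
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec == "CONECT":
            try:
                serials = [int(line[i : i + 5]) for i in range(6, min(len(line), 31), 5)
                           if line[i : i + 5].strip()]
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed CONECT: {line!r}") from exc
            for other in serials[1:]:
                a, b = sorted((serials[0], other))
                conect_pairs.add((a, b))
        # TER / REMARK / anything else: ignored
    if current or not models:
        if current:
            models.append(MolecularModel(atoms=current, model_id=model_id))
    if not models or all(len(m) == 0 for m in models):
        raise EmptyStructureError("input contains no ATOM/HETATM records")
    models = [m for m in models if len(m)]
    for m in models:
        serial_to_index = {a.serial: i for i, a in enumerate(m.atoms)}
        for a, b in sorted(conect_pairs):
            if a in serial_to_index and b in serial_to_index:
                m.add_bond(serial_to_index[a], serial_to_index[b])
    if model_select == "first":
        return models[:1]
    return models


def _as_text(source: str | os.PathLike) -> str:
    if isinstance(source, os.PathLike):
        return Path(source).read_text()
    if "\n" in source:
        return source
    if any(source.lstrip().startswith(r) for r in ("ATOM", "HETATM", "MODEL", "CONECT")):
        return source
    return Path(source).read_text()


def _format_atom(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.het else "ATOM  "
    name = atom.name
    # PDB convention: 1/2-char element names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    name = f"{name:<4.4s}"
    x, y, z = atom.coordinates
    return (
        f"{record}{serial:>5d} {name}{atom.altloc:1.1s}{atom.residue_name:>3.3s} "
        f"{atom.chain:1.1s}{atom.residue_number:>4d}{atom.insertion_code:1.1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2.2s}"
    )


def write_structure(
    models: MolecularModel | list[MolecularModel],
    path: str | os.PathLike | None = None,
    include_conect: bool = True,
) -> str:
    """Serialize models to PDB text; multi-model output gets MODEL/ENDMDL.

    Bonds are emitted as CONECT records when ``include_conect`` (each pair
    written once, from the lower serial).  Atom serials are renumbered
    sequentially from 1; author residue numbering is untouched.
    """
    if isinstance(models, MolecularModel):
        models = [models]
    if not models:
        raise ValueError("no models to write")
    lines: list[str] = []
    multi = len(models) > 1
    for model in models:
        if len(model.atoms) > 99999:
            raise SerialOverflowError(
                f"{len(model.atoms)} atoms exceed the 99999 fixed-width serial limit"
            )
        if multi:
            lines.append(f"MODEL     {model.model_id:>4d}")
        serials: list[int] = []
        for i, atom in enumerate(model.atoms):
            serial = i + 1
            serials.append(serial)
            lines.append(_format_atom(atom, serial))
        if include_conect and model.bonds:
            neighbors: dict[int, list[int]] = {}
            for i, j in sorted(min_max(b) for b in model.bonds):
                neighbors.setdefault(i, []).append(j)
            for i in sorted(neighbors):
                for chunk_start in range(0, len(neighbors[i]), 4):
                    chunk = neighbors[i][chunk_start : chunk_start + 4]
                    lines.append(
                        "CONECT"
                        + f"{serials[i]:>5d}"
                        + "".join(f"{serials[j]:>5d}" for j in chunk)
                    )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def min_max(pair: tuple[int, int]) -> tuple[int, int]:
    i, j = pair
    return (i, j) if i <= j else (j, i)
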