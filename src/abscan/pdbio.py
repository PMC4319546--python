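"""Fixed-width PDB (v3.3) and AutoDock PDBQT readers/writers.

Only coordinate content is interpreted: ATOM/HETATM records (plus MODEL/
ENDMDL bookkeeping). ANISOU, CONECT, TER and the PDBQT torsion-tree records
(ROOT/BRANCH/TORSDOF) are ignored — no docking is performed, so the tree
carries no information for rescoring a fixed pose.

Alt-loc handling: for each (residue, atom name) the highest-occupancy
location is kept; ties break to the alphabetically first alt-loc id.
Multi-MODEL files keep the first model only (with a warning).
"""

from __future__ import annotations

import warnings
from typing import Optional, TextIO, Union

from .model import Atom, LigandModel, LigandSelector, Residue, Structure, WATER_NAMES
from .params import normalize_element

__all__ = ["parse_pdb", "parse_pdbqt", "write_pdb", "write_pdbqt",
           "PDBParseError", "PDBFormatWarning"]


class PDBParseError(ValueError):
    """Unrecoverable problem with a coordinate file."""


class PDBFormatWarning(UserWarning):
    """Recoverable per-record problem; the record was skipped or defaulted."""


_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "FE", "ZN", "MG", "MN", "CA", "NA", "NI", "CU", "CO",
    "SE", "CD", "HG", "AS", "MO", "AL", "SI", "LI", "BE",
}


def _infer_element(name_raw: str) -> str:
    """Best-effort element from the raw 4-char atom-name field (cols 13-16).

    Single-letter elements are indented to column 14, so a name that starts
    in column 13 is either a hydrogen with a remoteness digit/long name
    (1HB2, HD21) or a genuine two-letter element (FE, CL). This keeps the
    alpha carbon " CA " distinct from a calcium ion "CA  ".
    """
    stripped = name_raw.strip()
    if not stripped:
        return ""
    if name_raw[:1].isdigit() or (name_raw[:1] in "HD" and len(stripped) >= 3):
        return "H"
    if name_raw[:1] != " ":
        two = stripped[:2].upper()
        if two in _TWO_LETTER_ELEMENTS and len(stripped) <= 2:
            return two.capitalize()
    first = stripped.lstrip("0123456789'\"*")[:1].upper()
    return "H" if first == "D" else first


def _element_from_record(line: str, name_raw: str) -> str:
    if len(line) >= 78:
        el = line[76:78].strip()
        if el:
            el = normalize_element(el)
            return el.capitalize() if len(el) > 1 else el
    return _infer_element(name_raw)


def _read_lines(source: Union[str, TextIO]) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
        if "\n" not in text and text.lower().endswith((".pdb", ".pdbqt", ".ent")):
            with open(text) as fh:
                text = fh.read()
    return text.splitlines()


def _parse_coordinate_record(line: str, line_no: int, *, pdbqt: bool) -> Optional[dict]:
    try:
        serial = int(line[6:11])
        name_raw = line[12:16]
        name = name_raw.strip()
        alt_loc = line[16:17].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        res_seq = int(line[22:26])
        i_code = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError):
        warnings.warn(
            f"line {line_no}: malformed fixed-width coordinate record skipped",
            PDBFormatWarning, stacklevel=3)
        return None
    rec = {
        "serial": serial, "name": name, "alt_loc": alt_loc, "res_name": res_name,
        "chain_id": chain_id, "res_seq": res_seq, "i_code": i_code,
        "coords": (x, y, z), "occupancy": min(max(occupancy, 0.0), 1.0),
        "is_hetero": line.startswith("HETATM"),
        "element": _element_from_record(line, name_raw),
        "charge": None, "ad_type": None,
    }
    if pdbqt:
        charge_field = line[70:76].strip()
        type_field = line[77:79].strip()
        if not charge_field or not type_field:
            raise PDBParseError(
                f"line {line_no}: PDBQT record lacks charge (cols 71-76) or "
                f"AutoDock type (cols 78-79)")
        try:
            rec["charge"] = float(charge_field)
        except ValueError:
            raise PDBParseError(f"line {line_no}: unreadable PDBQT charge {charge_field!r}")
        rec["ad_type"] = type_field
        if not rec["element"]:
            rec["element"] = "H" if type_field in ("H", "HD", "HS") else type_field.rstrip("AD")
    return rec


def _resolve_alt_locs(records: list[dict]) -> list[dict]:
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["chain_id"], rec["res_seq"], rec["i_code"], rec["res_name"], rec["name"])
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if (rec["occupancy"], ) > (cur["occupancy"], ) or (
                    rec["occupancy"] == cur["occupancy"]
                    and rec["alt_loc"] < cur["alt_loc"]):
                best[key] = rec
    return [best[k] for k in order]


def _group_residues(records: list[dict]) -> list[Residue]:
    residues: list[Residue] = []
    current: Optional[Residue] = None
    for rec in records:
        rid = (rec["chain_id"], rec["res_seq"], rec["i_code"])
        if current is None or current.rid != rid or current.res_name != rec["res_name"]:
            current = Residue(rec["chain_id"], rec["res_seq"], rec["res_name"], rec["i_code"])
            residues.append(current)
        current.atoms.append(Atom(
            serial=rec["serial"], name=rec["name"], element=rec["element"],
            coords=rec["coords"], alt_loc=rec["alt_loc"], occupancy=rec["occupancy"],
            is_hetero=rec["is_hetero"], ad_type=rec["ad_type"],
            partial_charge=rec["charge"]))
    return residues


def parse_pdb(source: Union[str, TextIO], title: str = "") -> Structure:
    """Parse PDB text (or an open file) into a :class:`Structure`.

    Raises :class:`PDBParseError` if the input carries no coordinate records;
    individually malformed records are skipped with a warning that names the
    offending line.
    """
    lines = _read_lines(source)
    records: list[dict] = []
    model_no = 0
    in_later_model = False
    for i, line in enumerate(lines, start=1):
        tag = line[:6].rstrip()
        if tag == "MODEL":
            model_no += 1
            if model_no > 1:
                warnings.warn("multi-MODEL file: keeping the first model only",
                              PDBFormatWarning, stacklevel=2)
                in_later_model = True
        elif tag == "ENDMDL":
            continue
        elif tag in ("ATOM", "HETATM") and not in_later_model:
            rec = _parse_coordinate_record(line, i, pdbqt=False)
            if rec is not None:
                records.append(rec)
        elif tag == "TITLE" and not title:
            title = line[10:].strip()
    if not records:
        raise PDBParseError("no ATOM/HETATM coordinate records found")
    structure = Structure(_group_residues(_resolve_alt_locs(records)),
                          title=title, source_format="pdb")
    structure.validate()
    return structure


def parse_pdbqt(source: Union[str, TextIO]) -> LigandModel:
    """Parse an AutoDock PDBQT ligand into a :class:`LigandModel`.

    Charges and AD types are taken verbatim from the file. HOH/WAT records
    are retained as ligand atoms and flag ``includes_bridge_waters`` — the
    mechanism by which bridging waters participate in the interaction score.
    """
    lines = _read_lines(source)
    records: list[dict] = []
    for i, line in enumerate(lines, start=1):
        tag = line[:6].rstrip()
        if tag in ("ATOM", "HETATM"):
            rec = _parse_coordinate_record(line, i, pdbqt=True)
            if rec is not None:
                records.append(rec)
        # ROOT/ENDROOT/BRANCH/ENDBRANCH/TORSDOF/REMARK tolerated and ignored
    if not records:
        raise PDBParseError("no ATOM/HETATM coordinate records found in PDBQT")
    records = _resolve_alt_locs(records)
    has_waters = any(rec["res_name"] in WATER_NAMES for rec in records)
    first = records[0]
    selector = LigandSelector(first["res_name"], first["chain_id"], first["res_seq"])
    atoms = [Atom(serial=r["serial"], name=r["name"], element=r["element"],
                  coords=r["coords"], alt_loc=r["alt_loc"], occupancy=r["occupancy"],
                  is_hetero=True, ad_type=r["ad_type"], partial_charge=r["charge"])
             for r in records]
    model = LigandModel(atoms, selector=selector, includes_bridge_waters=has_waters)
    model.validate()
    return model


def _format_atom_name(name: str, element: str) -> str:
    # element symbol occupies columns 13-14; single-letter elements with short
    # names are indented one column
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure) -> str:
    """Serialize a structure to fixed-width PDB text (v3.3 coordinate records)."""
    out: list[str] = []
    if structure.title:
        out.append(f"TITLE     {structure.title}")
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            record = "HETATM" if atom.is_hetero else "ATOM  "
            name = _format_atom_name(atom.name, atom.element)
            el = atom.element.upper().rjust(2)[:2]
            x, y, z = atom.coords
            out.append(
                f"{record}{serial:5d} {name}{atom.alt_loc or ' ':1s}"
                f"{res.res_name:>3s} {res.chain_id or 'A':1s}{res.res_seq:4d}"
                f"{res.i_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {el}")
    out.append("END")
    return "\n".join(out) + "\n"


def write_pdbqt(ligand: LigandModel) -> str:
    """Serialize a typed+charged ligand as a rigid AutoDock PDBQT block."""
    ligand.validate()
    sel = ligand.selector
    res_name = sel.res_name if sel else "LIG"
    chain = sel.chain_id if sel else "L"
    res_seq = sel.res_seq if sel else 1
    out = ["ROOT"]
    for k, atom in enumerate(ligand.atoms, start=1):
        name = _format_atom_name(atom.name, atom.element)
        x, y, z = atom.coords
        out.append(
            f"ATOM  {k:5d} {name} {res_name:>3s} {chain:1s}{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}    "
            f"{atom.partial_charge:6.3f} {atom.ad_type:<2s}")
    out.append("ENDROOT")
    out.append("TORSDOF 0")
    return "\n".join(out) + "\n"
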