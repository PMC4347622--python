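"""Intermolecular element-pair contact counts from PDB + SDF structures.

Produces the geometric "R" descriptor block: for every (protein element,
ligand element) pair in the configured alphabets, the number of
intermolecular atom pairs whose distance is at most ``cutoff`` angstroms.
Defaults — protein {C, N, O, S}, ligand {C, N, O, F, P, S, Cl, Br, I},
cutoff 12 A, boundary inclusive — give the conventional 36-count vector.
These defaults are this package's reconstruction of the common contact-count
recipe and are stamped into output metadata; adjust them to match whatever
convention your other descriptor blocks assume.

Protein atoms come from PDB ATOM/HETATM records (waters excluded, altLoc
'A'/blank kept, all chains); ligand atoms from a V2000 SDF/MOL file
(hydrogens kept by default — elements outside the alphabets simply never
match).  Atoms with unknown elements are logged and ignored unless
``strict`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
DEFAULT_CUTOFF = 12.0

#: Two-letter element symbols recognized by the atom-name fallback.
_TWO_LETTER = {
    "CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "CU", "NI", "CO", "SE", "CD", "HG", "SI",
}


@dataclass
class AtomSet:
    """Element symbols and coordinates (angstroms) for one molecule."""

    elements: list[str]
    coords: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise DataError("element list and coordinate array lengths differ")
        if not np.all(np.isfinite(self.coords)):
            raise DataError(f"non-finite coordinates in {self.source_id or 'atom set'}")

    def __len__(self) -> int:
        return len(self.elements)


def _element_from_name(name_field: str) -> str:
    """Guess the element from the raw 4-char atom-name field (cols 13-16).

    Two-letter elements start in column 13; one-letter elements leave it
    blank (so " CA " is an alpha carbon while "CA  " is calcium).
    """
    if len(name_field) >= 2 and name_field[0] != " ":
        two = name_field[:2].strip().upper()
        if two in _TWO_LETTER:
            return two.capitalize()
    stripped = name_field.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else ""


def read_pdb_atoms(
    path: str | Path,
    exclude_waters: bool = True,
    altloc_keep: tuple[str, ...] = ("", "A"),
) -> AtomSet:
    """Read ATOM/HETATM records from a fixed-column PDB file.

    The element comes from columns 77-78, with a fallback heuristic on the
    atom name (columns 13-16).  Water residues (HOH) are excluded by
    default; alternate locations other than blank/'A' are dropped so each
    atom is counted once.  Malformed records raise with their line number.
    """
    path = Path(path)
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise DataError(f"cannot read PDB file {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        record = line[0:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise DataError(f"{path}:{lineno}: truncated {record} record")
        altloc = line[16:17].strip()
        if altloc not in [a.strip() for a in altloc_keep]:
            continue
        resname = line[17:20].strip()
        if exclude_waters and resname == "HOH":
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise DataError(
                f"{path}:{lineno}: unparseable coordinates in {record} record"
            ) from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(line[12:16])
        if not element:
            raise DataError(f"{path}:{lineno}: cannot determine element")
        elements.append(element.capitalize())
        coords.append((x, y, z))
    if not elements:
        raise DataError(f"no ATOM/HETATM records found in {path}")
    return AtomSet(elements=elements, coords=np.array(coords), source_id=path.stem)


def read_sdf_atoms(
    path: str | Path,
    index: int = 0,
    keep_hydrogens: bool = True,
) -> AtomSet:
    """Read one molecule's atoms from a V2000 SDF/MOL file via RDKit.

    ``index`` selects the record in a multi-molecule SDF (first by
    default).  Hydrogens are kept unless ``keep_hydrogens`` is False.
    """
    from rdkit import Chem  # imported lazily; only this reader needs it

    path = Path(path)
    if not path.exists():
        raise DataError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = list(supplier)
    if index < 0 or index >= len(mols):
        raise DataError(f"{path}: record index {index} out of range (n={len(mols)})")
    mol = mols[index]
    if mol is None:
        raise DataError(f"{path}: record {index} could not be parsed (atom/bond count mismatch?)")
    if mol.GetNumConformers() == 0:
        raise DataError(f"{path}: record {index} has no coordinates")
    conf = mol.GetConformer()
    elements, coords = [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if not keep_hydrogens and sym == "H":
            continue
        p = conf.GetAtomPosition(atom.GetIdx())
        elements.append(sym)
        coords.append((p.x, p.y, p.z))
    if not elements:
        raise DataError(f"{path}: record {index} has no atoms after filtering")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return AtomSet(elements=elements, coords=np.array(coords), source_id=name or path.stem)


def pair_count_names(
    protein_elements: Sequence[str] = PROTEIN_ELEMENTS,
    ligand_elements: Sequence[str] = LIGAND_ELEMENTS,
) -> list[str]:
    """Column names for the count vector, e.g. ``R.C_Cl``."""
    return [f"R.{ep}_{el}" for ep in protein_elements for el in ligand_elements]


def pair_counts(
    protein: AtomSet,
    ligand: AtomSet,
    protein_elements: Sequence[str] = PROTEIN_ELEMENTS,
    ligand_elements: Sequence[str] = LIGAND_ELEMENTS,
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> np.ndarray:
    """Count intermolecular element pairs within the distance cutoff.

    ``count[(ep, el)]`` is the number of (protein atom, ligand atom) pairs
    with those elements at distance <= cutoff (closed boundary).  The vector
    is ordered as :func:`pair_count_names`.  Atoms whose element is outside
    both alphabets never match; elements outside the alphabets are logged,
    or rejected when ``strict``.
    """
    if cutoff <= 0:
        raise UsageError("cutoff must be positive")
    known_p, known_l = set(protein_elements), set(ligand_elements)
    for es, known, which in (
        (protein.elements, known_p, "protein"),
        (ligand.elements, known_l, "ligand"),
    ):
        unknown = sorted(set(es) - known)
        if unknown:
            if strict:
                raise DataError(f"unknown {which} element(s): {unknown}")
            logger.debug("ignoring %s elements outside alphabet: %s", which, unknown)

    # One KD-tree per ligand element; each protein-element group queries it.
    lig_trees = {}
    for el in ligand_elements:
        mask = [e == el for e in ligand.elements]
        if any(mask):
            lig_trees[el] = cKDTree(ligand.coords[mask])
    prot_groups = {}
    for ep in protein_elements:
        mask = [e == ep for e in protein.elements]
        if any(mask):
            prot_groups[ep] = protein.coords[mask]

    counts = np.zeros(len(protein_elements) * len(ligand_elements), dtype=int)
    k = 0
    for ep in protein_elements:
        for el in ligand_elements:
            if ep in prot_groups and el in lig_trees:
                hits = lig_trees[el].query_ball_point(prot_groups[ep], r=cutoff)
                counts[k] = sum(len(h) for h in hits)
            k += 1
    return counts


def featurize_complex(
    pdb_path: str | Path,
    sdf_path: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    sdf_index: int = 0,
    strict: bool = False,
) -> dict[str, int]:
    """End-to-end: structures in, named R-block count columns out."""
    protein = read_pdb_atoms(pdb_path)
    ligand = read_sdf_atoms(sdf_path, index=sdf_index)
    counts = pair_counts(protein, ligand, cutoff=cutoff, strict=strict)
    return dict(zip(pair_count_names(), (int(c) for c in counts)))
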