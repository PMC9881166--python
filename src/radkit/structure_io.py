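"""Reading and writing ribosome structures and result tables.

mmCIF (PDBx) is the primary dialect, with PDB as a fallback; both go through
gemmi.  Author residue numbering is used for reporting, label numbering is
kept alongside for internal bookkeeping.  Only light interpretation happens
here: residues are classified as RNA/protein/other, alternate conformers are
collapsed to the highest-occupancy one, and the two major rRNA strands
(>500 nt) are identified as LSU/SSU by length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "RibosomeStructure",
    "StructureParseError",
    "NoRRNAError",
    "parse_structure",
    "select_rrna_chains",
    "extract_p_atoms",
    "write_structure",
    "write_orientation_table",
    "read_orientation_table",
    "MIN_RRNA_LENGTH",
    "LSU_LENGTH_THRESHOLD",
]

#: an rRNA strand must exceed this many residues to count as LSU/SSU rRNA
MIN_RRNA_LENGTH = 500
#: a lone qualifying RNA chain longer than this is an isolated LSU, else SSU
#: (16S ≈ 1540 nt, 23S ≈ 2900 nt; eukaryotic homologs are larger but ordered
#: the same way)
LSU_LENGTH_THRESHOLD = 2000

RNA_PARENT = {"A": "A", "C": "C", "G": "G", "U": "U"}
#: common modified nucleotides → parent base (positional alignment still works
#: for unmapped ones, which pass through with a warning)
MODIFIED_RNA_PARENT = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "3MU": "U", "70U": "U", "DHU": "U",
    "1MA": "A", "2MA": "A", "A2M": "A", "MA6": "A", "6MZ": "A", "T6A": "A",
    "MIA": "A", "12A": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "5IC": "C",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G", "G7M": "G",
    "YG": "G", "QUO": "G",
}

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureParseError(ValueError):
    """The file could not be read as mmCIF or PDB."""


class NoRRNAError(ValueError):
    """The structure contains no RNA chains."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # (3,), Å
    residue_number: int
    insertion_code: str
    residue_name: str
    chain_id: str
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError("atom coordinates must be finite")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    """One residue: author number + insertion code, label number, name and
    its (altloc-collapsed) atoms."""

    number: int                 # author numbering (reporting)
    insertion_code: str
    name: str
    label_seq: int | None       # label numbering (internal), may be absent
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def residue_id(self) -> str:
        return f"{self.number}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def parent_base(self) -> str | None:
        """One-letter parent base for (possibly modified) nucleotides."""
        if self.name in RNA_PARENT:
            return RNA_PARENT[self.name]
        return MODIFIED_RNA_PARENT.get(self.name)


def _residue_kind(name: str) -> str:
    if name in RNA_PARENT or name in MODIFIED_RNA_PARENT:
        return "rna"
    if name in AMINO3:
        return "protein"
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "protein"
        if info.is_nucleic_acid():
            # DNA or exotic nucleotide; treat unmapped ribonucleotides as RNA
            # if they carry an O2' (checked by caller); default to other
            return "rna_like"
    return "other"


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue]
    kind: str = "other"  # rna | protein | other

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence; modified nucleotides map to parent bases,
        unmapped residues become N/X placeholders."""
        if self.kind == "rna":
            out = []
            for r in self.residues:
                base = r.parent_base
                if base is None:
                    warnings.warn(
                        f"unmapped residue {r.name} at {self.chain_id}:{r.residue_id}"
                        " passed through as N",
                        stacklevel=2,
                    )
                    base = "N"
                out.append(base)
            return "".join(out)
        return "".join(AA1.get(r.name, "X") for r in self.residues)

    def residue_by_number(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == icode:
                return r
        return None


@dataclass
class RibosomeStructure:
    """A parsed structure with its rRNA chains of interest identified.

    ``chains`` retains everything (proteins, tRNA, mRNA — needed for the
    smFRET distance analysis); ``lsu_chain``/``ssu_chain`` point at the two
    major rRNA strands when present.
    """

    accession: str
    chains: list[ChainModel]
    lsu_chain: ChainModel | None = None
    ssu_chain: ChainModel | None = None
    resolution: float | None = None
    source_format: str = "mmCIF"

    @property
    def other_chains(self) -> list[ChainModel]:
        skip = {id(self.lsu_chain), id(self.ssu_chain)}
        return [c for c in self.chains if id(c) not in skip]

    def chain(self, chain_id: str) -> ChainModel | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (tie → first
    altloc alphabetically)."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
            by_name[atom.name] = atom
    return list(by_name.values())


def parse_structure(
    path: str | Path,
    fmt: str | None = None,
    lsu_chain: str | None = None,
    ssu_chain: str | None = None,
) -> RibosomeStructure:
    """Parse an mmCIF or PDB file into a :class:`RibosomeStructure`.

    All chains are retained; each residue is classified by name as
    RNA/protein/other; insertion codes and heterogeneous numbering are kept
    verbatim.  ``lsu_chain``/``ssu_chain`` override the automatic
    length-based rRNA selection (required when a file holds more than one
    ribosome copy).

    Raises
    ------
    StructureParseError
        for unreadable files.
    NoRRNAError
        when no RNA chain is present.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt_in = (fmt or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif")).lower()
    try:
        if fmt_in == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise StructureParseError(f"{path.name}: no atomic coordinates found")
    st.setup_entities()
    model = st[0]

    chains: list[ChainModel] = []
    for ch in model:
        residues: list[Residue] = []
        kinds: dict[str, int] = {}
        for res in ch:
            atoms = []
            for atom in _collapse_altlocs(res):
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        chain_id=ch.name,
                        occupancy=float(atom.occ),
                    )
                )
            label = res.label_seq if res.label_seq is not None else None
            residues.append(
                Residue(
                    number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name,
                    label_seq=label,
                    atoms=atoms,
                )
            )
            kind = _residue_kind(res.name)
            if kind == "rna_like":
                kind = "rna" if res.name not in {"DA", "DC", "DG", "DT"} else "other"
            kinds[kind] = kinds.get(kind, 0) + 1
        if not residues:
            continue
        # waters/ligands attached to a polymer chain must not flip its kind
        polymer_kinds = {k: v for k, v in kinds.items() if k != "other"}
        kind = max(polymer_kinds, key=polymer_kinds.get) if polymer_kinds else "other"
        chains.append(ChainModel(chain_id=ch.name, residues=residues, kind=kind))

    if not any(c.kind == "rna" for c in chains):
        raise NoRRNAError(f"{path.name}: no rRNA found")

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    structure = RibosomeStructure(
        accession=(st.name or path.stem).strip() or path.stem,
        chains=chains,
        resolution=resolution,
        source_format="PDB" if fmt_in == "pdb" else "mmCIF",
    )
    if lsu_chain or ssu_chain:
        structure.lsu_chain = structure.chain(lsu_chain) if lsu_chain else None
        structure.ssu_chain = structure.chain(ssu_chain) if ssu_chain else None
    else:
        lsu, ssu = select_rrna_chains(structure)
        structure.lsu_chain = lsu
        structure.ssu_chain = ssu
    return structure


def select_rrna_chains(
    structure: RibosomeStructure,
) -> tuple[ChainModel | None, ChainModel | None]:
    """Identify the LSU and SSU rRNA strands among RNA chains >500 nt.

    The longest qualifying chain is the LSU and the second-longest the SSU.
    A lone qualifying chain is classified by length (≤2000 nt → isolated
    SSU, otherwise isolated LSU).  Selection is deterministic and
    independent of chain order in the file (ties broken by chain id).
    """
    rna = [c for c in structure.chains if c.kind == "rna" and len(c) > MIN_RRNA_LENGTH]
    rna.sort(key=lambda c: (-len(c), c.chain_id))
    if not rna:
        return None, None
    if len(rna) == 1:
        lone = rna[0]
        if len(lone) > LSU_LENGTH_THRESHOLD:
            return lone, None
        return None, lone
    if len(rna) > 2:
        alternates = ", ".join(f"{c.chain_id}({len(c)})" for c in rna[2:])
        logger.warning(
            "more than two qualifying rRNA chains; picked %s(%d)/%s(%d) by length, "
            "alternates: %s",
            rna[0].chain_id, len(rna[0]), rna[1].chain_id, len(rna[1]), alternates,
        )
    return rna[0], rna[1]


def extract_p_atoms(
    chain: ChainModel,
    residue_subset: set[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Ordered backbone-phosphate coordinates for a chain.

    Returns ``(coords, residue_ids, skipped)``: one coordinate per residue
    possessing a P atom, in residue order; residues lacking a P atom (e.g.
    5′ termini) are skipped and reported.  ``residue_subset`` restricts to
    the given residue ids (author number + insertion code).

    Raises
    ------
    ValueError
        when no residue yields a P atom.
    """
    coords, ids, skipped = [], [], []
    for res in chain.residues:
        if residue_subset is not None and res.residue_id not in residue_subset:
            continue
        p = res.atom("P")
        if p is None:
            skipped.append(res.residue_id)
            continue
        coords.append(p.coords)
        ids.append(res.residue_id)
    if not coords:
        raise ValueError(f"no P atoms found in chain {chain.chain_id}")
    return np.asarray(coords), ids, skipped


def write_structure(structure: RibosomeStructure, path: str | Path, fmt: str | None = None) -> None:
    """Write a structure to mmCIF (default) or PDB via gemmi."""
    path = Path(path)
    fmt_out = (fmt or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif")).lower()
    st = gemmi.Structure()
    st.name = structure.accession
    if structure.resolution:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    for chain in structure.chains:
        ch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            if res.label_seq is not None:
                r.label_seq = res.label_seq
            for atom in res.atoms:
                a = gemmi.Atom()
                a.name = atom.atom_name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.coords)
                a.occ = atom.occupancy
                r.add_atom(a)
            ch.add_residue(r)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if fmt_out == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


ORIENTATION_COLUMNS = [
    "accession", "domain", "phi_deg", "theta_deg", "psi_deg",
    "delta_x_A", "n_core", "core_rmsd_A",
]


def write_orientation_table(records: list[dict], path: str | Path) -> None:
    """Write per-structure decomposition results as a TSV that round-trips
    losslessly through :func:`read_orientation_table`."""
    if not records:
        raise ValueError("no records to write")
    df = pd.DataFrame.from_records(records)
    for col in ORIENTATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extras = [c for c in df.columns if c not in ORIENTATION_COLUMNS]
    df = df[ORIENTATION_COLUMNS + extras]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_orientation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
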