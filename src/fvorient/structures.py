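"""Structure model: IMGT-numbered variable domains, paired receptors, pMHC complexes.

PDB files are parsed with Bio.PDB.  IMGT renumbering is *consumed*, never
computed: every structure is accompanied by a tab-separated "numbering
sidecar" mapping ``(chain, author_number, insertion_code)`` to an IMGT
position (1-128, optional insertion code inside the CDR3 block).  Residues
lacking a mapping are excluded from the domain but retained in a raw pool.

Conventions
-----------
* Domain types are ``VH``/``VL`` (antibody heavy/light) and ``VB``/``VA``
  (TCR beta/alpha).  The VH<->VB, VL<->VA equivalence is used throughout, so
  a paired receptor always has an H-side (``first``: VH or VB) and an L-side
  (``second``: VL or VA) domain.
* A residue missing its C-beta atom (glycine, or incomplete side chain) gets
  a virtual C-beta equal to its C-alpha, which keeps C-beta distance rules
  total without side-chain reconstruction.
* Alternate locations: the highest-occupancy altloc is kept (Bio.PDB's
  selection rule).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .geometry import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "DomainStructure",
    "FvStructure",
    "PMHCComplex",
    "StructureError",
    "IMGT_FRAMEWORK",
    "IMGT_CDR",
    "parse_numbering",
    "format_numbering",
    "read_fv_structure",
    "read_pmhc_complex",
    "write_pdb",
    "transform_residues",
    "shared_framework_positions",
]

# IMGT region definitions on the 1-128 grid (inclusive ranges).
IMGT_CDR: dict[str, frozenset[int]] = {
    "CDR1": frozenset(range(27, 39)),
    "CDR2": frozenset(range(56, 66)),
    "CDR3": frozenset(range(105, 118)),
}
IMGT_FRAMEWORK: frozenset[int] = frozenset(range(1, 129)) - (
    IMGT_CDR["CDR1"] | IMGT_CDR["CDR2"] | IMGT_CDR["CDR3"]
)

DOMAIN_TYPES = ("VH", "VL", "VB", "VA")
H_SIDE = {"VH", "VB"}
L_SIDE = {"VL", "VA"}

_RECEPTOR_DOMAINS = {"antibody": ("VH", "VL"), "tcr": ("VB", "VA")}


class StructureError(ValueError):
    """Invalid or inconsistent structural input."""


@dataclass(frozen=True)
class Residue:
    """One residue with C-alpha/C-beta (and optionally all heavy-atom) coordinates.

    ``imgt_position`` is None for residues outside an IMGT-numbered domain
    (MHC and peptide chains carry author numbering only).
    """

    chain_id: str
    author_number: int
    amino_acid: str
    ca: np.ndarray
    cb: np.ndarray
    insertion_code: str = ""
    imgt_position: int | None = None
    imgt_insertion: str = ""
    atoms: tuple[tuple[str, str, np.ndarray], ...] | None = None

    def __post_init__(self) -> None:
        if self.imgt_position is not None and not 1 <= self.imgt_position <= 128:
            raise StructureError(
                f"IMGT position {self.imgt_position} outside 1-128 "
                f"({self.chain_id}{self.author_number}{self.insertion_code})"
            )
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        object.__setattr__(self, "cb", np.asarray(self.cb, dtype=float))

    @property
    def imgt_key(self) -> tuple[int, str]:
        if self.imgt_position is None:
            raise StructureError("residue has no IMGT position")
        return (self.imgt_position, self.imgt_insertion)

    def transformed(self, t: RigidTransform) -> "Residue":
        atoms = None
        if self.atoms is not None:
            atoms = tuple((n, e, t.apply(c)) for n, e, c in self.atoms)
        return replace(self, ca=t.apply(self.ca), cb=t.apply(self.cb), atoms=atoms)


def transform_residues(residues, t: RigidTransform):
    """Apply a rigid transform to a sequence of residues."""
    return [r.transformed(t) for r in residues]


@dataclass(frozen=True)
class DomainStructure:
    """An IMGT-numbered immunoglobulin variable domain."""

    residues: tuple[Residue, ...]
    domain_type: str
    framework_positions: frozenset[int] = IMGT_FRAMEWORK
    cdr_positions: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(IMGT_CDR)
    )

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise StructureError(f"unknown domain type {self.domain_type!r}")
        object.__setattr__(self, "residues", tuple(self.residues))
        seen: set[tuple[int, str]] = set()
        for r in self.residues:
            if r.imgt_position is None:
                raise StructureError("domain residue lacks an IMGT position")
            if r.imgt_key in seen:
                raise StructureError(
                    f"duplicate IMGT position {r.imgt_position}{r.imgt_insertion} "
                    f"in {self.domain_type} chain {r.chain_id}"
                )
            seen.add(r.imgt_key)
        cdr_union = frozenset().union(*self.cdr_positions.values())
        if self.framework_positions & cdr_union:
            raise StructureError("framework and CDR position sets overlap")

    @property
    def side(self) -> str:
        return "H" if self.domain_type in H_SIDE else "L"

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id if self.residues else "?"

    def positions(self) -> frozenset[int]:
        """Integer IMGT positions present (insertions collapse onto their anchor)."""
        return frozenset(r.imgt_position for r in self.residues)

    def present_framework(self) -> frozenset[int]:
        return self.positions() & self.framework_positions

    def get(self, position: int, insertion: str = "") -> Residue | None:
        for r in self.residues:
            if r.imgt_position == position and r.imgt_insertion == insertion:
                return r
        return None

    def ca_array(self, positions) -> np.ndarray:
        """C-alpha coordinates at the given integer positions, in the given order.

        Only non-inserted residues are used, so the correspondence across
        structures is positional and unambiguous.
        """
        coords = []
        for p in positions:
            r = self.get(p)
            if r is None:
                raise StructureError(
                    f"position {p} absent from {self.domain_type} domain"
                )
            coords.append(r.ca)
        return np.array(coords, dtype=float)

    def sequence(self) -> dict[int, str]:
        """IMGT-position -> one-letter amino acid (non-inserted positions)."""
        return {
            r.imgt_position: r.amino_acid for r in self.residues if not r.imgt_insertion
        }

    def cdr3_length(self) -> int:
        """Number of residues (insertions included) at CDR3 positions 105-117."""
        cdr3 = self.cdr_positions.get("CDR3", IMGT_CDR["CDR3"])
        return sum(1 for r in self.residues if r.imgt_position in cdr3)

    def transformed(self, t: RigidTransform) -> "DomainStructure":
        return replace(self, residues=tuple(r.transformed(t) for r in self.residues))


def shared_framework_positions(a: DomainStructure, b: DomainStructure) -> list[int]:
    """Sorted integer framework positions present in both domains."""
    return sorted(a.present_framework() & b.present_framework())


@dataclass(frozen=True)
class FvStructure:
    """A paired variable fragment: H-side (VH/VB) plus L-side (VL/VA) domain."""

    first: DomainStructure
    second: DomainStructure
    receptor_class: str
    pdb_id: str = ""
    resolution: float | None = None
    raw_pool: tuple[Residue, ...] = ()

    def __post_init__(self) -> None:
        if self.receptor_class not in _RECEPTOR_DOMAINS:
            raise StructureError(
                f"receptor_class must be 'antibody' or 'tcr', got {self.receptor_class!r}"
            )
        want = _RECEPTOR_DOMAINS[self.receptor_class]
        got = (self.first.domain_type, self.second.domain_type)
        if got != want:
            raise StructureError(
                f"domain types {got} inconsistent with receptor_class "
                f"{self.receptor_class!r} (expected {want})"
            )

    @property
    def domains(self) -> tuple[DomainStructure, DomainStructure]:
        return (self.first, self.second)

    def domain(self, side: str) -> DomainStructure:
        if side == "H":
            return self.first
        if side == "L":
            return self.second
        raise StructureError(f"side must be 'H' or 'L', got {side!r}")

    def transformed(self, t: RigidTransform) -> "FvStructure":
        return replace(
            self, first=self.first.transformed(t), second=self.second.transformed(t)
        )

    def concatenated_sequence(self) -> dict[tuple[str, int], str]:
        """(side, IMGT position) -> amino acid over both domains."""
        seq: dict[tuple[str, int], str] = {}
        for side, dom in (("H", self.first), ("L", self.second)):
            for p, aa in dom.sequence().items():
                seq[(side, p)] = aa
        return seq


@dataclass(frozen=True)
class PMHCComplex:
    """A receptor bound to a peptide-MHC: Fv + MHC chain(s) + peptide."""

    receptor: FvStructure
    mhc_chains: tuple[tuple[Residue, ...], ...]
    peptide: tuple[Residue, ...]
    mhc_class: str

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise StructureError("peptide chain is empty")
        if self.mhc_class not in ("I", "II"):
            raise StructureError(f"mhc_class must be 'I' or 'II', got {self.mhc_class!r}")
        object.__setattr__(self, "peptide", tuple(self.peptide))
        object.__setattr__(
            self, "mhc_chains", tuple(tuple(c) for c in self.mhc_chains)
        )

    def environment_residues(self) -> list[Residue]:
        """All MHC and peptide residues (the receptor's steric environment)."""
        out: list[Residue] = []
        for chain in self.mhc_chains:
            out.extend(chain)
        out.extend(self.peptide)
        return out

    def with_receptor(self, receptor: FvStructure) -> "PMHCComplex":
        return replace(self, receptor=receptor)


# ---------------------------------------------------------------------------
# Numbering sidecar
# ---------------------------------------------------------------------------

def parse_numbering(text: str) -> dict[tuple[str, int, str], tuple[int, str]]:
    """Parse a numbering sidecar.

    Tab-separated columns: chain, author_number, insertion_code ('-' or empty
    for none), imgt_position (an integer, optionally with a trailing
    insertion letter, e.g. ``111A``).  Lines starting with '#' are ignored.
    Duplicate author keys or duplicate IMGT targets within a chain are
    rejected.
    """
    mapping: dict[tuple[str, int, str], tuple[int, str]] = {}
    targets: set[tuple[str, int, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise StructureError(f"sidecar line {lineno}: expected 4 columns, got {len(parts)}")
        chain, num_s, icode, imgt_s = parts
        icode = "" if icode in ("-", ".", "") else icode
        try:
            num = int(num_s)
        except ValueError as exc:
            raise StructureError(f"sidecar line {lineno}: bad author number {num_s!r}") from exc
        imgt_s = imgt_s.strip()
        ins = ""
        while imgt_s and imgt_s[-1].isalpha():
            ins = imgt_s[-1] + ins
            imgt_s = imgt_s[:-1]
        try:
            imgt = int(imgt_s)
        except ValueError as exc:
            raise StructureError(f"sidecar line {lineno}: bad IMGT position") from exc
        if not 1 <= imgt <= 128:
            raise StructureError(f"sidecar line {lineno}: IMGT position {imgt} outside 1-128")
        if ins and imgt not in (111, 112):
            raise StructureError(
                f"sidecar line {lineno}: insertion codes only allowed in the "
                f"CDR3 111/112 block, got {imgt}{ins}"
            )
        key = (chain, num, icode)
        if key in mapping:
            raise StructureError(f"sidecar line {lineno}: duplicate author residue {key}")
        tgt = (chain, imgt, ins)
        if tgt in targets:
            raise StructureError(
                f"sidecar line {lineno}: IMGT position {imgt}{ins} mapped twice in chain {chain}"
            )
        mapping[key] = (imgt, ins)
        targets.add(tgt)
    return mapping


def format_numbering(mapping: dict[tuple[str, int, str], tuple[int, str]]) -> str:
    lines = ["# chain\tauthor_number\tinsertion_code\timgt_position"]
    for (chain, num, icode), (imgt, ins) in mapping.items():
        lines.append(f"{chain}\t{num}\t{icode or '-'}\t{imgt}{ins}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _three_to_one(resname: str) -> str:
    resname = resname.upper()
    if resname == "MSE":  # selenomethionine -> methionine
        return "M"
    return protein_letters_3to1.get(resname.capitalize(), "X")


def _extract_chain_residues(chain, chain_id: str) -> list[dict]:
    """Raw per-residue records (author numbering, coordinates) from a Bio.PDB chain."""
    out = []
    for res in chain:
        hetflag, resseq, icode = res.get_id()
        if hetflag not in (" ", "H_MSE"):
            continue
        atoms = []
        ca = cb = None
        for atom in res:  # Bio.PDB yields the highest-occupancy altloc
            name = atom.get_name()
            element = (atom.element or "").strip() or name[0]
            if element == "H":
                continue
            coord = np.array(atom.get_coord(), dtype=float)
            atoms.append((name, element, coord))
            if name == "CA":
                ca = coord
            elif name == "CB":
                cb = coord
        if not atoms:
            continue
        out.append(
            {
                "chain": chain_id,
                "number": resseq,
                "icode": icode.strip(),
                "aa": _three_to_one(res.get_resname()),
                "ca": ca,
                "cb": cb,
                "atoms": tuple(atoms),
            }
        )
    return out


def _parse_pdb_chains(pdb_text: str) -> dict[str, list[dict]]:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    model = next(iter(structure))
    return {c.id: _extract_chain_residues(c, c.id) for c in model}


def _build_domain(
    records: list[dict],
    chain_id: str,
    numbering: dict[tuple[str, int, str], tuple[int, str]],
    domain_type: str,
    min_framework: int,
) -> tuple[DomainStructure, list[Residue]]:
    residues: list[Residue] = []
    raw_pool: list[Residue] = []
    for rec in records:
        key = (chain_id, rec["number"], rec["icode"])
        imgt = numbering.get(key)
        ca = rec["ca"]
        if imgt is not None and ca is None:
            raise StructureError(
                f"residue {chain_id}{rec['number']}{rec['icode']} ({rec['aa']}) "
                "is IMGT-mapped but has no C-alpha atom"
            )
        if ca is None:
            continue
        cb = rec["cb"] if rec["cb"] is not None else ca
        res = Residue(
            chain_id=chain_id,
            author_number=rec["number"],
            insertion_code=rec["icode"],
            amino_acid=rec["aa"],
            ca=ca,
            cb=cb,
            imgt_position=imgt[0] if imgt else None,
            imgt_insertion=imgt[1] if imgt else "",
            atoms=rec["atoms"],
        )
        if imgt is None:
            raw_pool.append(res)
        else:
            residues.append(res)
    n_unmapped = len(raw_pool)
    if n_unmapped:
        logger.warning(
            "chain %s: %d residue(s) lack an IMGT mapping and were excluded "
            "from the %s domain",
            chain_id,
            n_unmapped,
            domain_type,
        )
    domain = DomainStructure(residues=tuple(residues), domain_type=domain_type)
    n_fw = len(domain.present_framework())
    if n_fw < min_framework:
        raise StructureError(
            f"chain {chain_id}: only {n_fw} mapped framework positions "
            f"(minimum {min_framework}) for domain {domain_type}"
        )
    return domain, raw_pool


def read_fv_structure(
    pdb_text: str,
    numbering: str | dict,
    receptor_class: str,
    domain_chains: tuple[str, str] | None = None,
    pdb_id: str = "",
    resolution: float | None = None,
    min_framework: int = 50,
) -> FvStructure:
    """Read a paired variable fragment from PDB text plus a numbering sidecar.

    The sidecar must map residues of exactly two chains.  The first chain (in
    sidecar order, or ``domain_chains`` if given) becomes the H-side domain
    (VH for antibodies, VB for TCRs), the second the L-side domain.

    ``min_framework`` is the minimum number of mapped framework positions per
    domain (default 50; relax only for reduced test fixtures).
    """
    if receptor_class not in _RECEPTOR_DOMAINS:
        raise StructureError(f"unknown receptor_class {receptor_class!r}")
    mapping = parse_numbering(numbering) if isinstance(numbering, str) else dict(numbering)
    chains_in_order: list[str] = []
    for chain, _, _ in mapping:
        if chain not in chains_in_order:
            chains_in_order.append(chain)
    if domain_chains is None:
        if len(chains_in_order) != 2:
            raise StructureError(
                f"numbering sidecar must cover exactly 2 chains, found {chains_in_order}"
            )
        domain_chains = (chains_in_order[0], chains_in_order[1])
    chain_records = _parse_pdb_chains(pdb_text)
    types = _RECEPTOR_DOMAINS[receptor_class]
    domains = []
    pool: list[Residue] = []
    for chain_id, dtype in zip(domain_chains, types):
        if chain_id not in chain_records:
            raise StructureError(f"chain {chain_id!r} not present in PDB text")
        dom, raw = _build_domain(
            chain_records[chain_id], chain_id, mapping, dtype, min_framework
        )
        domains.append(dom)
        pool.extend(raw)
    return FvStructure(
        first=domains[0],
        second=domains[1],
        receptor_class=receptor_class,
        pdb_id=pdb_id,
        resolution=resolution,
        raw_pool=tuple(pool),
    )


def _plain_residues(records: list[dict]) -> tuple[Residue, ...]:
    out = []
    for rec in records:
        if rec["ca"] is None:
            continue
        cb = rec["cb"] if rec["cb"] is not None else rec["ca"]
        out.append(
            Residue(
                chain_id=rec["chain"],
                author_number=rec["number"],
                insertion_code=rec["icode"],
                amino_acid=rec["aa"],
                ca=rec["ca"],
                cb=cb,
                atoms=rec["atoms"],
            )
        )
    return tuple(out)


def read_pmhc_complex(
    pdb_text: str,
    numbering: str | dict,
    chain_roles: dict[str, str],
    receptor_class: str = "tcr",
    mhc_class: str | None = None,
    pdb_id: str = "",
    resolution: float | None = None,
    min_framework: int = 50,
) -> PMHCComplex:
    """Read a receptor/peptide-MHC complex.

    ``chain_roles`` maps chain id to one of ``receptor1`` (H-side: VB or VH),
    ``receptor2`` (L-side), ``mhc``, ``peptide``.  ``mhc_class`` is inferred
    from the number of MHC chains (one -> class I, two -> class II) unless
    overridden.
    """
    roles: dict[str, list[str]] = {"receptor1": [], "receptor2": [], "mhc": [], "peptide": []}
    for chain, role in chain_roles.items():
        if role not in roles:
            raise StructureError(f"unknown chain role {role!r} for chain {chain!r}")
        roles[role].append(chain)
    if len(roles["receptor1"]) != 1 or len(roles["receptor2"]) != 1:
        raise StructureError("chain_roles must name exactly one receptor1 and one receptor2 chain")
    if len(roles["peptide"]) != 1:
        raise StructureError("chain_roles must name exactly one peptide chain")
    if not roles["mhc"]:
        raise StructureError("chain_roles must name at least one MHC chain")

    receptor = read_fv_structure(
        pdb_text,
        numbering,
        receptor_class,
        domain_chains=(roles["receptor1"][0], roles["receptor2"][0]),
        pdb_id=pdb_id,
        resolution=resolution,
        min_framework=min_framework,
    )
    chain_records = _parse_pdb_chains(pdb_text)
    for chain in roles["mhc"] + roles["peptide"]:
        if chain not in chain_records:
            raise StructureError(f"chain {chain!r} not present in PDB text")
    mhc_chains = tuple(_plain_residues(chain_records[c]) for c in roles["mhc"])
    peptide = _plain_residues(chain_records[roles["peptide"][0]])
    if not peptide:
        raise StructureError("peptide chain has no residues with coordinates")
    if mhc_class is None:
        mhc_class = "I" if len(mhc_chains) == 1 else "II"
    for dom in receptor.domains:
        if dom.get(104) is None:
            logger.warning(
                "interface cysteine (IMGT 104) absent in %s domain; "
                "docking-angle requests on this complex will fail",
                dom.domain_type,
            )
    return PMHCComplex(
        receptor=receptor, mhc_chains=mhc_chains, peptide=peptide, mhc_class=mhc_class
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _resname(aa: str) -> str:
    try:
        return protein_letters_1to3[aa.upper()].upper()
    except KeyError:
        return "UNK"


def write_pdb(obj: FvStructure | PMHCComplex) -> str:
    """Write a receptor or complex back to PDB text (chain ids preserved).

    Residues carrying a full atom record are written verbatim; reduced
    residues are written as their C-alpha (plus C-beta when distinct).
    """
    builder = StructureBuilder()
    builder.init_structure("out")
    builder.init_model(0)
    builder.init_seg("    ")

    def add_chain(residues) -> None:
        if not residues:
            return
        builder.init_chain(residues[0].chain_id)
        for r in residues:
            builder.init_residue(_resname(r.amino_acid), " ", r.author_number, r.insertion_code or " ")
            atoms = r.atoms
            if not atoms:
                atoms = [("CA", "C", r.ca)]
                if not np.allclose(r.cb, r.ca):
                    atoms.append(("CB", "C", r.cb))
            for name, element, coord in atoms:
                builder.init_atom(
                    name,
                    np.asarray(coord, dtype=float),
                    0.0,
                    1.0,
                    " ",
                    name.center(4) if len(name) < 4 else name,
                    element=element,
                )

    if isinstance(obj, PMHCComplex):
        for chain in obj.mhc_chains:
            add_chain(list(chain))
        add_chain(list(obj.peptide))
        receptor = obj.receptor
    else:
        receptor = obj
    add_chain(list(receptor.first.residues))
    add_chain(list(receptor.second.residues))

    out = io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    pdbio.save(out)
    return out.getvalue()
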