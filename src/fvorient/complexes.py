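"""Receptor/peptide-MHC geometry: docking angle, orientation grafting, steric counts.

The docking angle quantifies how a receptor sits over the peptide-binding
groove: it is the 3D angle between the major axis of the peptide (oriented N
to C) and the vector joining the C-alpha atoms of the two interface
cysteines (IMGT position 104), directed from the L-side (VA/VL) domain to
the H-side (VB/VH) domain.  Canonical TCR binding lies between 40 and 85
degrees.

Orientation grafting transplants the inter-domain pose of a decoy receptor
onto a native complex: the decoy is aligned to the native anchored domain,
and the native partner domain is then moved to assume the decoy partner's
pose, leaving the MHC, peptide and anchored domain untouched.  Steric
consequences are quantified by residue-pair clash counts (van der Waals
overlap >= 0.4 A over heavy atoms, the Molprobity-style convention; reduced
structures fall back to a C-beta distance rule) and C-beta contact pairs
under 7 A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import principal_axes, superpose, vector_angle
from .structures import (
    FvStructure,
    PMHCComplex,
    Residue,
    StructureError,
    shared_framework_positions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DockingGeometry",
    "GraftResult",
    "MissingAnchorError",
    "CANONICAL_BAND",
    "VDW_RADII",
    "CLASH_OVERLAP",
    "CB_CLASH_CUTOFF",
    "CONTACT_CUTOFF",
    "docking_angle",
    "graft_orientation",
    "count_clashes",
    "contact_pairs",
]

#: Canonical TCR docking-angle band (degrees, inclusive).
CANONICAL_BAND = (40.0, 85.0)

#: Fixed van der Waals radii (Angstrom) for heavy atoms; unknown elements
#: default to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Two residues clash when any heavy-atom pair overlaps the summed vdW radii
#: by at least this much (Angstrom).
CLASH_OVERLAP = 0.4

#: Fallback clash criterion for reduced (C-alpha/C-beta) structures.
CB_CLASH_CUTOFF = 3.0

#: C-beta/C-beta contact cutoff (Angstrom, strict less-than).
CONTACT_CUTOFF = 7.0


class MissingAnchorError(StructureError):
    """A required anchor residue (e.g. the IMGT 104 cysteine) is absent."""


@dataclass(frozen=True)
class DockingGeometry:
    """Docking angle of a receptor over a peptide-MHC groove."""

    angle: float
    canonical: bool
    peptide_axis: np.ndarray
    cys_vector: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle < 180.0:
            raise StructureError(f"docking angle {self.angle} outside [0, 180)")
        if self.canonical != (CANONICAL_BAND[0] <= self.angle <= CANONICAL_BAND[1]):
            raise StructureError("canonical flag inconsistent with angle band")


def docking_angle(complex: PMHCComplex) -> DockingGeometry:
    """Docking angle between the peptide major axis and the 104-104 vector.

    The peptide axis is the first principal axis of the peptide C-alphas,
    oriented N to C; the cysteine vector runs from the L-side (VA/VL) IMGT
    104 C-alpha to the H-side (VB/VH) one.  Reported in [0, 180); canonical
    iff within 40-85 degrees.
    """
    if len(complex.peptide) < 3:
        raise StructureError(
            f"peptide has {len(complex.peptide)} residues; need >= 3 for a major axis"
        )
    anchors = {}
    for side in ("H", "L"):
        dom = complex.receptor.domain(side)
        res = dom.get(104)
        if res is None:
            raise MissingAnchorError(
                f"interface cysteine (IMGT 104) absent from the {dom.domain_type} domain"
            )
        anchors[side] = res.ca
    pep_ca = np.array([r.ca for r in complex.peptide])
    axes, _ = principal_axes(pep_ca)
    axis = axes[0]  # sign already fixed N->C by the first->last convention
    cys = anchors["H"] - anchors["L"]
    ang = vector_angle(axis, cys)
    if ang >= 180.0:  # exactly antiparallel: clamp into the half-open range
        ang = np.nextafter(180.0, 0.0)
    canonical = CANONICAL_BAND[0] <= ang <= CANONICAL_BAND[1]
    return DockingGeometry(
        angle=ang,
        canonical=canonical,
        peptide_axis=axis,
        cys_vector=cys / np.linalg.norm(cys),
    )


@dataclass(frozen=True)
class GraftResult:
    """Outcome of transplanting a decoy inter-domain pose onto a native complex."""

    decoy_id: str
    moved_domain: str  # domain type of the repositioned native domain
    anchored_domain: str
    grafted_complex: PMHCComplex
    clashes_moved_domain: int
    clashes_anchored_domain: int
    contact_pairs: tuple[tuple[Residue, Residue, float], ...]

    @property
    def total_clashes(self) -> int:
        return self.clashes_moved_domain + self.clashes_anchored_domain


def graft_orientation(
    native: PMHCComplex,
    decoy: FvStructure,
    anchored: str = "L",
    min_shared: int = 20,
) -> GraftResult:
    """Re-pose the native receptor into the decoy's inter-domain orientation.

    ``anchored`` names the side that keeps its native pose relative to the
    MHC/peptide: ``'L'`` (VA/VL, the default — the decoy's L-side domain is
    aligned to the native VA and the native H-side domain then assumes the
    decoy H-side pose) or ``'H'`` for the symmetric role swap.

    The moved native domain is carried rigidly: it is superposed onto the
    decoy partner domain's aligned coordinates via their shared framework
    positions, so every chain keeps its internal geometry exactly.
    """
    if anchored not in ("H", "L"):
        raise StructureError(f"anchored side must be 'H' or 'L', got {anchored!r}")
    moved = "H" if anchored == "L" else "L"
    nat_anchor = native.receptor.domain(anchored)
    nat_moved = native.receptor.domain(moved)
    dec_anchor = decoy.domain(anchored)
    dec_moved = decoy.domain(moved)

    shared_anchor = shared_framework_positions(dec_anchor, nat_anchor)
    shared_moved = shared_framework_positions(nat_moved, dec_moved)
    for name, s in (("anchored", shared_anchor), ("moved", shared_moved)):
        if len(s) < min_shared:
            raise StructureError(
                f"only {len(s)} shared framework positions on the {name} side "
                f"(minimum {min_shared})"
            )

    # Align the decoy onto the native anchored domain.
    T1, _ = superpose(
        dec_anchor.ca_array(shared_anchor), nat_anchor.ca_array(shared_anchor)
    )
    dec_moved_aligned = T1.apply(dec_moved.ca_array(shared_moved))
    # Carry the native moved domain into the decoy partner's pose.
    T2, _ = superpose(nat_moved.ca_array(shared_moved), dec_moved_aligned)
    grafted_moved = nat_moved.transformed(T2)

    if moved == "H":
        receptor = FvStructure(
            first=grafted_moved,
            second=nat_anchor,
            receptor_class=native.receptor.receptor_class,
            pdb_id=native.receptor.pdb_id,
            resolution=native.receptor.resolution,
        )
    else:
        receptor = FvStructure(
            first=nat_anchor,
            second=grafted_moved,
            receptor_class=native.receptor.receptor_class,
            pdb_id=native.receptor.pdb_id,
            resolution=native.receptor.resolution,
        )
    grafted = native.with_receptor(receptor)
    clashes = count_clashes(grafted)
    contacts = contact_pairs(grafted)
    return GraftResult(
        decoy_id=decoy.pdb_id or "decoy",
        moved_domain=grafted_moved.domain_type,
        anchored_domain=nat_anchor.domain_type,
        grafted_complex=grafted,
        clashes_moved_domain=clashes[moved],
        clashes_anchored_domain=clashes[anchored],
        contact_pairs=tuple(contacts),
    )


def _is_reduced(res: Residue) -> bool:
    """True when the residue carries no side-chain information beyond C-beta."""
    return not res.atoms or all(n in ("CA", "CB") for n, _, _ in res.atoms)


def _residues_clash(a: Residue, b: Residue, overlap: float, cb_cutoff: float) -> bool:
    """Clash test for one residue pair; counted once regardless of how many
    atom pairs overlap.  All-atom vdW rule when both residues carry full
    atoms, else the C-beta fallback."""
    if _is_reduced(a) or _is_reduced(b):
        return bool(np.linalg.norm(a.cb - b.cb) < cb_cutoff)
    ca = np.array([c for _, _, c in a.atoms])
    ra = np.array([VDW_RADII.get(e, VDW_RADII["C"]) for _, e, _ in a.atoms])
    cbb = np.array([c for _, _, c in b.atoms])
    rb = np.array([VDW_RADII.get(e, VDW_RADII["C"]) for _, e, _ in b.atoms])
    d = np.linalg.norm(ca[:, None, :] - cbb[None, :, :], axis=-1)
    return bool(np.any(d <= ra[:, None] + rb[None, :] - overlap))


def count_clashes(
    complex: PMHCComplex,
    overlap: float = CLASH_OVERLAP,
    cb_cutoff: float = CB_CLASH_CUTOFF,
) -> dict[str, int]:
    """Per-side counts of receptor residues clashing with the MHC/peptide.

    A receptor/environment residue pair clashes when any heavy-atom pair
    overlaps the summed van der Waals radii by >= ``overlap`` (0.4 A); when
    either residue carries only C-alpha/C-beta coordinates the pair instead
    clashes when the C-beta distance is below ``cb_cutoff`` (3.0 A).  Each
    residue pair is counted at most once.  Returns ``{'H': n, 'L': n}``.
    """
    env = complex.environment_residues()
    counts = {"H": 0, "L": 0}
    if not env:
        return counts
    env_reduced = np.array([_is_reduced(e) for e in env])
    env_cb = np.array([e.cb for e in env])
    for side in ("H", "L"):
        dom = complex.receptor.domain(side)
        if not dom.residues:
            continue
        rec_reduced = np.array([_is_reduced(r) for r in dom.residues])
        rec_cb = np.array([r.cb for r in dom.residues])
        # vectorised C-beta fallback for every pair with a reduced member
        d = np.linalg.norm(rec_cb[:, None, :] - env_cb[None, :, :], axis=-1)
        fallback_pair = rec_reduced[:, None] | env_reduced[None, :]
        n = int(np.count_nonzero(fallback_pair & (d < cb_cutoff)))
        # all-atom rule for fully-atomed pairs
        full_idx = np.argwhere(~fallback_pair)
        for i, j in full_idx:
            if _residues_clash(dom.residues[i], env[j], overlap, cb_cutoff):
                n += 1
        counts[side] = n
    return counts


def contact_pairs(
    complex: PMHCComplex, cutoff: float = CONTACT_CUTOFF
) -> list[tuple[Residue, Residue, float]]:
    """All receptor/MHC-peptide residue pairs with C-beta distance < ``cutoff``.

    Glycines (and other residues without a C-beta) use their C-alpha as the
    virtual C-beta.  Sorted by increasing distance.
    """
    env = complex.environment_residues()
    if not env:
        return []
    env_cb = np.array([e.cb for e in env])
    out: list[tuple[Residue, Residue, float]] = []
    for dom in complex.receptor.domains:
        for r in dom.residues:
            d = np.linalg.norm(env_cb - r.cb, axis=1)
            for j in np.nonzero(d < cutoff)[0]:
                out.append((r, env[j], float(d[j])))
    out.sort(key=lambda t: t[2])
    return out
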