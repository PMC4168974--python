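"""Ground-truth generator: synthetic Fv assemblies and toy pMHC complexes.

Every stage of the pipeline is testable without downloads: this module
builds rigid two-domain assemblies at *controlled* inter-domain poses
(requested values of the six orientation measures, with optional Gaussian
coordinate noise), families of such poses, and toy peptide-MHC complexes
with a known docking angle and a tunable receptor-groove separation.

The domain scaffold is a pseudo-beta-sandwich: two sheets of ideal-geometry
C-alpha strands plus CDR arcs, labelled with IMGT positions and
framework/CDR/interface annotations.  It is deliberately not chemically
realistic — every consumer operates on labelled C-alpha/C-beta positions,
not chemistry — but it satisfies all structure-model invariants and round
trips through the PDB writer/reader.

Pose construction works in the L-domain's canonical frame (origin at the
interface centroid, e1 along x, e2 along y).  Writing c1 = cos(HC1) etc.,
the requested measures determine the H-domain frame uniquely (up to the
documented sign conventions): the pivot direction in the L frame is
(-cos LC1, -cos LC2, +sqrt(1 - cos^2 LC1 - cos^2 LC2)), the H origin sits at
distance dc along it, e1H makes angle HC1 with the pivot at torsion HL about
it, and e2H makes angle HC2 while staying orthogonal to e1H.  Angle
combinations violating cos^2 LC1 + cos^2 LC2 <= 1 or
cos^2 HC1 + cos^2 HC2 <= 1 (or with HC1/LC1 at 0 or 180 degrees) are
geometrically unreachable and raise an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, RigidTransform
from .orientation import (
    DEFAULT_INTERFACE_POSITIONS,
    ConsensusDomain,
    Coreset,
    Frame,
    FrameSystem,
    fit_frame,
)
from .structures import (
    DomainStructure,
    FvStructure,
    PMHCComplex,
    Residue,
    format_numbering,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PoseSpec",
    "DEFAULT_POSE",
    "make_fv",
    "make_pose_family",
    "make_pmhc",
    "make_twist_decoys",
    "scaffold_domain",
    "scaffold_frame_system",
    "fv_numbering_sidecar",
]

#: IMGT positions commonly absent from the 1-128 grid; skipped by the scaffold.
_SKIPPED_POSITIONS = frozenset({10, 73, 81, 82})

_AA_CYCLE = "AVLISTDEKRNQ"
_AA_OVERRIDES = {23: "C", 104: "C", 41: "W", 118: "F", 8: "G", 50: "L", 6: "E", 4: "L"}


@dataclass(frozen=True)
class PoseSpec:
    """Target orientation measures plus noise/seed for one synthetic Fv.

    Angles in degrees, ``dc`` in Angstrom (> 5), ``noise`` the SD of
    isotropic Gaussian coordinate jitter (>= 0).
    """

    HL: float = -60.0
    HC1: float = 70.0
    HC2: float = 120.0
    LC1: float = 120.0
    LC2: float = 80.0
    dc: float = 16.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dc <= 5.0:
            raise GeometryError(f"dc must exceed 5 A, got {self.dc}")
        if self.noise < 0:
            raise GeometryError("noise SD must be >= 0")

    def measures(self) -> dict[str, float]:
        return {
            "HL": self.HL,
            "HC1": self.HC1,
            "HC2": self.HC2,
            "LC1": self.LC1,
            "LC2": self.LC2,
            "dc": self.dc,
        }


DEFAULT_POSE = PoseSpec()

_STRAND_RISE = 3.4
_STRAND_X = 4.8
_SHEET_Y = 9.5


def _scaffold_coords(cdr3_length: int) -> dict[int, np.ndarray]:
    """Deterministic C-alpha coordinates per IMGT position."""

    def strand(p0, p1, x, y, z0, direction):
        pts = {}
        idx = 0
        for p in range(p0, p1 + 1):
            if p in _SKIPPED_POSITIONS:
                continue
            pts[p] = np.array([x, y, z0 + direction * _STRAND_RISE * idx])
            idx += 1
        return pts

    def arc(positions, center, radius, normal_y):
        pts = {}
        n = len(positions)
        for i, p in enumerate(positions):
            theta = np.pi * (i + 1) / (n + 1)
            pts[p] = np.array(
                [
                    center[0] + radius * np.cos(theta),
                    center[1] + normal_y * (1.0 + 0.3 * i),
                    center[2] + radius * np.sin(theta),
                ]
            )
        return pts

    coords: dict[int, np.ndarray] = {}
    coords.update(strand(1, 13, 0.0, _SHEET_Y, 0.0, +1))
    coords.update(strand(14, 26, _STRAND_X, _SHEET_Y, 44.0, -1))
    cdr1 = [p for p in range(27, 38) if p not in _SKIPPED_POSITIONS]
    coords.update(arc(cdr1, (2.4, _SHEET_Y, 46.0), 5.0, +1.0))
    coords.update(strand(38, 50, 0.0, 0.0, 0.0, +1))
    coords.update(strand(51, 55, -_STRAND_X, 0.0, 14.0, -1))
    cdr2 = [p for p in range(56, 66) if p not in _SKIPPED_POSITIONS]
    coords.update(arc(cdr2, (-2.4, 0.0, -8.0), 5.0, +1.0))
    coords.update(strand(66, 76, 2 * _STRAND_X, _SHEET_Y, 0.0, +1))
    coords.update(strand(77, 86, -_STRAND_X, _SHEET_Y, 34.0, -1))
    coords.update(strand(87, 104, _STRAND_X, 0.0, -8.0, +1))
    # CDR3: IMGT-style symmetric deletion around the 111/112 apex
    full = list(range(105, 118))
    if not 0 <= cdr3_length <= 13:
        raise GeometryError("scaffold CDR3 length must be in 0..13")
    head = full[: (cdr3_length + 1) // 2]
    tail = full[len(full) - cdr3_length // 2 :]
    coords.update(arc(head + tail, (2.4, 0.0, 52.0), 5.0, -1.0))
    coords.update(strand(118, 128, 2 * _STRAND_X, 0.0, 44.0, -1))
    return coords


def scaffold_domain(
    domain_type: str, chain_id: str, cdr3_length: int = 13
) -> DomainStructure:
    """The canonical scaffold domain in its own (untransformed) coordinates."""
    coords = _scaffold_coords(cdr3_length)
    residues = []
    for i, p in enumerate(sorted(coords)):
        aa = _AA_OVERRIDES.get(p, _AA_CYCLE[p % len(_AA_CYCLE)])
        ca = coords[p]
        side = -1.0 if (ca[1] > _SHEET_Y / 2) else 1.0  # point away from the partner sheet
        offset = np.array([0.0, side * (1.0 if p % 2 else -1.0), 0.0]) * 1.53
        cb = ca if aa == "G" else ca + offset
        residues.append(
            Residue(
                chain_id=chain_id,
                author_number=p,
                amino_acid=aa,
                ca=ca,
                cb=cb,
                imgt_position=p,
            )
        )
    return DomainStructure(residues=tuple(residues), domain_type=domain_type)


def _domain_as_consensus(domain: DomainStructure) -> ConsensusDomain:
    positions = tuple(sorted(domain.positions()))
    coords = np.array([domain.get(p).ca for p in positions])
    return ConsensusDomain(domain.domain_type, positions, coords)


def _scaffold_frame(domain: DomainStructure) -> Frame:
    return fit_frame(_domain_as_consensus(domain), DEFAULT_INTERFACE_POSITIONS)


def _canonicalising_transform(frame: Frame) -> RigidTransform:
    """Transform taking a frame to the canonical pose (origin 0, e1=x, e2=y)."""
    e3 = np.cross(frame.e1, frame.e2)
    R = np.vstack([frame.e1, frame.e2, e3])
    return RigidTransform(R, -R @ frame.origin)


def _pose_transforms(spec: PoseSpec) -> tuple[np.ndarray, np.ndarray]:
    """H-frame basis (columns e1H, e2H, e3H) and origin realising the spec,
    in the canonical L frame."""
    deg = np.deg2rad
    cl1, cl2 = np.cos(deg(spec.LC1)), np.cos(deg(spec.LC2))
    ch1, ch2 = np.cos(deg(spec.HC1)), np.cos(deg(spec.HC2))
    sz2 = 1.0 - cl1**2 - cl2**2
    if sz2 < -1e-12:
        raise GeometryError(
            f"unreachable pose: cos^2(LC1) + cos^2(LC2) = {cl1**2 + cl2**2:.4f} > 1"
        )
    if 1.0 - ch1**2 - ch2**2 < -1e-12:
        raise GeometryError(
            f"unreachable pose: cos^2(HC1) + cos^2(HC2) = {ch1**2 + ch2**2:.4f} > 1"
        )
    sh1 = np.sin(deg(spec.HC1))
    sl1 = np.sin(deg(spec.LC1))
    if sh1 < 1e-9 or sl1 < 1e-9:
        raise GeometryError("unreachable pose: HC1/LC1 of 0 or 180 degrees is degenerate")
    c_dir = np.array([-cl1, -cl2, np.sqrt(max(sz2, 0.0))])
    e1l = np.array([1.0, 0.0, 0.0])
    # torsion reference frame perpendicular to the pivot
    p = e1l - (e1l @ c_dir) * c_dir
    p = p / np.linalg.norm(p)
    q = np.cross(c_dir, p)
    hl = deg(spec.HL)
    e1h = ch1 * c_dir + sh1 * (np.cos(hl) * p + np.sin(hl) * q)
    # e2H: orthogonal to e1H, at angle HC2 to the pivot
    a = c_dir - ch1 * e1h
    a = a / np.linalg.norm(a)
    b = np.cross(e1h, a)
    cphi = ch2 / sh1
    cphi = np.clip(cphi, -1.0, 1.0)
    sphi = np.sqrt(max(1.0 - cphi**2, 0.0))
    e2h = cphi * a + sphi * b
    e3h = np.cross(e1h, e2h)
    basis = np.column_stack([e1h, e2h, e3h])
    origin = spec.dc * c_dir
    return basis, origin


def _jitter(domain: DomainStructure, sd: float, rng: np.random.Generator) -> DomainStructure:
    if sd == 0:
        return domain
    residues = []
    for r in domain.residues:
        ca = r.ca + rng.normal(0.0, sd, 3)
        cb = ca if np.allclose(r.cb, r.ca) else r.cb + rng.normal(0.0, sd, 3)
        residues.append(
            Residue(
                chain_id=r.chain_id,
                author_number=r.author_number,
                insertion_code=r.insertion_code,
                amino_acid=r.amino_acid,
                ca=ca,
                cb=cb,
                imgt_position=r.imgt_position,
                imgt_insertion=r.imgt_insertion,
            )
        )
    return DomainStructure(
        residues=tuple(residues),
        domain_type=domain.domain_type,
        framework_positions=domain.framework_positions,
        cdr_positions=domain.cdr_positions,
    )


def make_fv(
    spec: PoseSpec = DEFAULT_POSE,
    receptor_class: str = "tcr",
    cdr3_length_h: int = 13,
    cdr3_length_l: int = 13,
    pdb_id: str = "synthetic",
    scaffold: DomainStructure | None = None,
) -> tuple[FvStructure, dict]:
    """Build a synthetic paired receptor at the requested inter-domain pose.

    Returns the receptor and a ground-truth record (requested measures, seed,
    noise SD).  With ``noise=0`` the measures recovered against the scaffold
    frame system reproduce the request to numerical precision.
    """
    h_type, l_type = ("VB", "VA") if receptor_class == "tcr" else ("VH", "VL")
    h_chain, l_chain = ("B", "A") if receptor_class == "tcr" else ("H", "L")
    if scaffold is not None:
        base_h = base_l = scaffold
    else:
        base_h = scaffold_domain(h_type, h_chain, cdr3_length_h)
        base_l = scaffold_domain(l_type, l_chain, cdr3_length_l)
    if scaffold is not None:
        base_h = DomainStructure(
            residues=tuple(
                Residue(
                    chain_id=h_chain,
                    author_number=r.author_number,
                    amino_acid=r.amino_acid,
                    ca=r.ca,
                    cb=r.cb,
                    imgt_position=r.imgt_position,
                )
                for r in scaffold.residues
            ),
            domain_type=h_type,
        )
        base_l = DomainStructure(
            residues=tuple(
                Residue(
                    chain_id=l_chain,
                    author_number=r.author_number,
                    amino_acid=r.amino_acid,
                    ca=r.ca,
                    cb=r.cb,
                    imgt_position=r.imgt_position,
                )
                for r in scaffold.residues
            ),
            domain_type=l_type,
        )

    canon_l = _canonicalising_transform(_scaffold_frame(base_l))
    canon_h = _canonicalising_transform(_scaffold_frame(base_h))
    basis, origin = _pose_transforms(spec)
    place_h = RigidTransform(basis, origin).compose(canon_h)

    rng = np.random.default_rng(spec.seed)
    dom_l = _jitter(base_l.transformed(canon_l), spec.noise, rng)
    dom_h = _jitter(base_h.transformed(place_h), spec.noise, rng)
    fv = FvStructure(
        first=dom_h, second=dom_l, receptor_class=receptor_class, pdb_id=pdb_id
    )
    truth = dict(spec.measures(), noise=spec.noise, seed=spec.seed)
    return fv, truth


def scaffold_frame_system(receptor_class: str = "tcr", cdr3_length: int = 13) -> FrameSystem:
    """The exact frame system of the noiseless scaffold.

    Coresets are the scaffold's framework positions, the consensus is the
    scaffold itself, and the frames are fitted through the default interface
    positions — the same conventions a data-derived frame system converges to
    on a noiseless synthetic ensemble.
    """
    h_type, l_type = ("VB", "VA") if receptor_class == "tcr" else ("VH", "VL")
    systems = {}
    for side, dtype, chain in (("H", h_type, "B"), ("L", l_type, "A")):
        dom = scaffold_domain(dtype, chain, cdr3_length)
        cons = _domain_as_consensus(dom)
        coreset = Coreset(dtype, dom.present_framework())
        frame = fit_frame(cons, DEFAULT_INTERFACE_POSITIONS)
        systems[side] = (coreset, cons, frame)
    return FrameSystem(
        coresets={s: systems[s][0] for s in systems},
        consensus={s: systems[s][1] for s in systems},
        frames={s: systems[s][2] for s in systems},
        interface_positions={
            "H": DEFAULT_INTERFACE_POSITIONS,
            "L": DEFAULT_INTERFACE_POSITIONS,
        },
    )


def make_pose_family(
    center: PoseSpec, spread: float, n: int, seed: int = 0, receptor_class: str = "tcr"
) -> list[FvStructure]:
    """``n`` receptors with the five angles drawn from N(center, spread^2).

    ``dc`` is held at the centre value; coordinate noise follows
    ``center.noise``.  Fully deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError(f"a pose family needs n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        angles = {
            name: getattr(center, name) + (rng.normal(0.0, spread) if spread > 0 else 0.0)
            for name in ("HL", "HC1", "HC2", "LC1", "LC2")
        }
        member_seed = int(rng.integers(0, 2**31 - 1))
        spec = PoseSpec(dc=center.dc, noise=center.noise, seed=member_seed, **angles)
        fv, _ = make_fv(spec, receptor_class=receptor_class, pdb_id=f"fam{seed}-{i}")
        out.append(fv)
    return out


# ---------------------------------------------------------------------------
# Toy pMHC complexes
# ---------------------------------------------------------------------------

_PEPTIDE_LENGTH = 9
_PEPTIDE_SPACING = 3.5
_SLAB_Z = (-4.0, -8.0)
_SLAB_X = np.arange(-24.0, 24.1, 4.0)
_SLAB_Y = np.arange(-16.0, 16.1, 4.0)


def _peptide_residues() -> tuple[Residue, ...]:
    out = []
    seq = "FLRGRAYGL"  # a 9-mer; any sequence would do
    for i in range(_PEPTIDE_LENGTH):
        ca = np.array(
            [(i - (_PEPTIDE_LENGTH - 1) / 2) * _PEPTIDE_SPACING, 0.3 * (-1) ** i, 0.0]
        )
        cb = ca + np.array([0.0, 0.0, 1.53])
        out.append(
            Residue(chain_id="P", author_number=i + 1, amino_acid=seq[i], ca=ca, cb=cb)
        )
    return tuple(out)


def _slab_residues() -> tuple[Residue, ...]:
    out = []
    num = 1
    for z in _SLAB_Z:
        for x in _SLAB_X:
            for y in _SLAB_Y:
                ca = np.array([x, y, z])
                out.append(
                    Residue(
                        chain_id="M", author_number=num, amino_acid="A", ca=ca, cb=ca
                    )
                )
                num += 1
    return tuple(out)


def _receptor_points(fv: FvStructure) -> np.ndarray:
    pts = []
    for dom in fv.domains:
        for r in dom.residues:
            pts.append(r.ca)
            pts.append(r.cb)
    return np.array(pts)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector u onto unit vector v."""
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2 * K @ K
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K


def make_pmhc(
    docking_spec: float,
    groove_gap: float = 5.0,
    seed: int = 0,
    pose: PoseSpec | None = None,
    receptor_class: str = "tcr",
) -> tuple[PMHCComplex, dict]:
    """A toy class-I pMHC complex with a known docking angle.

    The peptide runs along +x (N to C); the MHC is a two-layer slab of
    pseudo-residues beneath it.  The receptor is rotated so its 104-104
    cysteine vector (VA to VB) lies in the groove plane at ``docking_spec``
    degrees to the peptide axis, then lowered until the minimum
    receptor-to-MHC/peptide atom separation equals ``groove_gap``.
    """
    if not 0.0 <= docking_spec < 180.0:
        raise GeometryError(f"docking angle spec must be in [0, 180), got {docking_spec}")
    if pose is None:
        pose = PoseSpec(seed=seed)
    fv, fv_truth = make_fv(pose, receptor_class=receptor_class, pdb_id="synthetic-pmhc-receptor")
    peptide = _peptide_residues()
    slab = _slab_residues()

    ca104_h = fv.first.get(104).ca
    ca104_l = fv.second.get(104).ca
    v = ca104_h - ca104_l
    v = v / np.linalg.norm(v)
    theta = np.deg2rad(docking_spec)
    target = np.array([np.cos(theta), np.sin(theta), 0.0])
    R1 = _rotation_between(v, target)
    fv = fv.transformed(RigidTransform(R1, np.zeros(3)))

    # spin about the cysteine axis so the receptor body points up (+z)
    pts = _receptor_points(fv)
    mid = 0.5 * (fv.first.get(104).ca + fv.second.get(104).ca)
    body = pts.mean(axis=0) - mid
    body_perp = body - (body @ target) * target
    up = np.array([0.0, 0.0, 1.0])
    up_perp = up - (up @ target) * target
    if np.linalg.norm(body_perp) > 1e-9 and np.linalg.norm(up_perp) > 1e-9:
        R2 = _rotation_between(
            body_perp / np.linalg.norm(body_perp), up_perp / np.linalg.norm(up_perp)
        )
        fv = fv.transformed(RigidTransform(R2, np.zeros(3)))
        mid = 0.5 * (fv.first.get(104).ca + fv.second.get(104).ca)

    # centre over the peptide, high above, then settle to the requested gap
    fv = fv.transformed(RigidTransform(np.eye(3), np.array([0.0, 0.0, 60.0]) - mid))
    env_pts = np.array([c for r in list(slab) + list(peptide) for c in (r.ca, r.cb)])
    for _ in range(100):
        pts = _receptor_points(fv)
        d = np.sqrt(
            ((pts[:, None, :] - env_pts[None, :, :]) ** 2).sum(axis=-1)
        ).min()
        if abs(d - groove_gap) < 1e-8:
            break
        fv = fv.transformed(
            RigidTransform(np.eye(3), np.array([0.0, 0.0, groove_gap - d]))
        )
    complex_ = PMHCComplex(
        receptor=fv, mhc_chains=(slab,), peptide=peptide, mhc_class="I"
    )
    truth = {
        "docking_angle": docking_spec,
        "groove_gap": groove_gap,
        "receptor_pose": fv_truth,
        "seed": seed,
    }
    return complex_, truth


def make_twist_decoys(
    pmhc: PMHCComplex, twists: list[float]
) -> list[tuple[float, FvStructure]]:
    """Decoy receptors whose H-side (VB/VH) domain is twisted toward the groove.

    Each decoy equals the native receptor with the H-side domain rotated
    about an axis through the L-side IMGT 104 C-alpha along the peptide
    direction, with the rotation sign chosen so the H-side domain moves
    toward the MHC slab (decreasing z).  A zero twist reproduces the native
    receptor exactly.
    """
    native = pmhc.receptor
    pep_ca = np.array([r.ca for r in pmhc.peptide])
    axis = pep_ca[-1] - pep_ca[0]
    axis = axis / np.linalg.norm(axis)
    pivot = native.second.get(104).ca
    h_centroid = np.array([r.ca for r in native.first.residues]).mean(axis=0)

    def rotated(angle_deg: float, sign: float) -> FvStructure:
        t = np.deg2rad(angle_deg) * sign
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * K @ K
        T = RigidTransform(R, pivot - R @ pivot)
        return FvStructure(
            first=native.first.transformed(T),
            second=native.second,
            receptor_class=native.receptor_class,
            pdb_id=f"twist{angle_deg:g}",
        )

    # pick the rotation sign that lowers the H-side centroid
    probe_plus = rotated(10.0, +1.0)
    probe_minus = rotated(10.0, -1.0)
    zp = np.array([r.ca for r in probe_plus.first.residues]).mean(axis=0)[2]
    zm = np.array([r.ca for r in probe_minus.first.residues]).mean(axis=0)[2]
    sign = +1.0 if zp < zm else -1.0
    return [(tw, rotated(tw, sign)) for tw in twists]


def fv_numbering_sidecar(fv: FvStructure) -> str:
    """Numbering sidecar text for a (synthetic or real) paired receptor."""
    mapping = {}
    for dom in fv.domains:
        for r in dom.residues:
            mapping[(r.chain_id, r.author_number, r.insertion_code)] = (
                r.imgt_position,
                r.imgt_insertion,
            )
    return format_numbering(mapping)
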