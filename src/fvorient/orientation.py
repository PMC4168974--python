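"""Quantifying the relative pose of paired variable domains.

Two complementary quantifications are provided:

* the **orientation RMSD** — a symmetric, relative measure: align two
  receptors on one shared domain, superpose the partner domains
  independently, and report the mean C-alpha displacement over both
  directions — together with complete-linkage hierarchical clustering of a
  pairwise orientation-RMSD matrix;

* six **absolute measures** in the ABangle style: a torsion angle ``HL``,
  two tilt angles ``HC1``/``LC1``, two twist angles ``HC2``/``LC2`` and the
  pivot-axis length ``dc``, defined from per-domain reference frames
  registered onto each structure via coreset superposition.

Frame construction is anchored on the data at hand: structurally conserved
framework "coresets" are derived by spread pruning, consensus (mean) domains
are built by iterative superposition, and reference frames are fitted
through the interface positions of the consensus.  Absolute values are
therefore internally consistent across structures measured with the same
frame system, but are offset from published antibody ABangle values, whose
frames were fitted to different reference data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .geometry import GeometryError, RigidTransform, superpose, torsion_angle, vector_angle
from .structures import (
    DomainStructure,
    FvStructure,
    Residue,
    StructureError,
    shared_framework_positions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Coreset",
    "ConsensusDomain",
    "Frame",
    "FrameSystem",
    "OrientationMeasures",
    "DEFAULT_INTERFACE_POSITIONS",
    "MEASURE_NAMES",
    "orientation_rmsd",
    "pairwise_orientation_matrix",
    "pairwise_matrix_and_cluster",
    "derive_coresets",
    "build_consensus",
    "build_consensus_and_frames",
    "build_frame_system",
    "compute_measures",
    "linkage_to_newick",
]

#: The beta-sheet faces forming the dimer interface (user-overridable).
DEFAULT_INTERFACE_POSITIONS: frozenset[int] = frozenset(range(38, 51)) | frozenset(
    range(87, 105)
)

MEASURE_NAMES = ("HL", "HC1", "HC2", "LC1", "LC2", "dc")

#: Sign anchors for the in-plane frame vectors: e1 is oriented toward the
#: IMGT 104 consensus C-alpha, e2 toward IMGT 50.
E1_ANCHOR_POSITION = 104
E2_ANCHOR_POSITION = 50


# ---------------------------------------------------------------------------
# Orientation RMSD
# ---------------------------------------------------------------------------

def _one_direction(x: FvStructure, y: FvStructure, anchor: str, shared: dict) -> float:
    """Align y onto x via the anchor-side domain, then measure how far the
    partner domain sits from its best superposition onto x's partner."""
    other = "L" if anchor == "H" else "H"
    A, _ = superpose(
        y.domain(anchor).ca_array(shared[anchor]),
        x.domain(anchor).ca_array(shared[anchor]),
    )
    moved = A.apply(y.domain(other).ca_array(shared[other]))
    B, _ = superpose(moved, x.domain(other).ca_array(shared[other]))
    fitted = B.apply(moved)
    d = moved - fitted
    return float(np.sqrt((d * d).sum() / len(moved)))


def orientation_rmsd(x: FvStructure, y: FvStructure, min_shared: int = 20) -> float:
    """Mean bidirectional orientation RMSD between two paired receptors (Angstrom).

    Symmetric, non-negative, zero for identical relative poses, and invariant
    under any rigid motion of either whole structure.  Computed over the
    framework positions shared by the corresponding domains.
    """
    shared = {
        side: shared_framework_positions(x.domain(side), y.domain(side))
        for side in ("H", "L")
    }
    for side, positions in shared.items():
        if len(positions) < min_shared:
            raise StructureError(
                f"only {len(positions)} shared {side}-side framework positions "
                f"(minimum {min_shared}) between {x.pdb_id or 'x'} and {y.pdb_id or 'y'}"
            )
    return 0.5 * (
        _one_direction(x, y, "L", shared) + _one_direction(x, y, "H", shared)
    )


def _structure_labels(structures) -> list[str]:
    labels = []
    for i, s in enumerate(structures):
        base = s.pdb_id or f"s{i}"
        labels.append(base if base not in labels else f"{base}_{i}")
    return labels


def pairwise_orientation_matrix(
    structures: list[FvStructure], min_shared: int = 20, on_error: str = "raise"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Symmetric zero-diagonal orientation-RMSD matrix.

    ``on_error='drop'`` flags failing entries as NaN and reports the labels of
    structures involved in any failure; ``'raise'`` propagates the error.
    """
    n = len(structures)
    labels = _structure_labels(structures)
    mat = np.zeros((n, n))
    failed: set[int] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = orientation_rmsd(structures[i], structures[j], min_shared)
            except (StructureError, GeometryError):
                if on_error == "raise":
                    raise
                d = np.nan
                failed.update((i, j))
                logger.warning("orientation RMSD failed for %s vs %s", labels[i], labels[j])
            mat[i, j] = mat[j, i] = d
    return mat, labels, [labels[i] for i in sorted(failed)]


@dataclass
class ClusterResult:
    distance_matrix: np.ndarray
    labels: list[str]
    cluster_labels: np.ndarray
    linkage_matrix: np.ndarray | None
    dropped: list[str] = field(default_factory=list)

    def newick(self) -> str:
        if self.linkage_matrix is None:
            return f"({self.labels[0]});" if self.labels else "();"
        return linkage_to_newick(self.linkage_matrix, self.labels)


def pairwise_matrix_and_cluster(
    structures: list[FvStructure],
    k: int | None = None,
    height: float | None = None,
    min_shared: int = 20,
    on_error: str = "raise",
) -> ClusterResult:
    """Cluster receptors by orientation RMSD with complete linkage.

    The merge height of any complete-linkage cluster equals the maximum
    pairwise distance within it.  Cut either at ``k`` clusters or at a merge
    ``height``; with neither, every structure gets its own cluster label.
    Structures involved in failed pairwise computations are dropped (with a
    warning) before clustering when ``on_error='drop'``.
    """
    if len(structures) < 1:
        raise ValueError("need at least one structure")
    mat, labels, dropped = pairwise_orientation_matrix(structures, min_shared, on_error)
    if dropped:
        keep = [i for i, lab in enumerate(labels) if lab not in dropped]
        mat = mat[np.ix_(keep, keep)]
        labels = [labels[i] for i in keep]
    n = len(labels)
    if n == 1:
        return ClusterResult(mat, labels, np.array([1]), None, dropped)
    Z = linkage(squareform(mat, checks=False), method="complete")
    if k is not None:
        cl = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        cl = fcluster(Z, t=height, criterion="distance")
    else:
        cl = np.arange(1, n + 1)
    return ClusterResult(mat, labels, cl, Z, dropped)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# Coresets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Coreset:
    """Structurally conserved framework positions used for superposition."""

    domain_type: str
    positions: frozenset[int]
    spreads: dict[int, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.positions) < 20:
            raise StructureError(f"coreset has {len(self.positions)} positions (< 20)")


def _align_ensemble(
    members: list[DomainStructure],
    positions: list[int],
    n_iter: int = 20,
    tol: float = 1e-6,
):
    """Superpose ensemble members onto their evolving mean over ``positions``.

    Returns per-member transforms, the converged per-position mean, the
    per-position spreads, and whether the mean shift fell below ``tol``.
    """
    member_positions = [set(m.positions()) for m in members]
    usable = [sorted(set(positions) & mp) for mp in member_positions]
    transforms = [RigidTransform.identity() for _ in members]
    # initial reference: first member
    ref = {p: members[0].get(p).ca for p in usable[0]}
    converged = False
    for _ in range(n_iter):
        new_transforms = []
        for m, pos in zip(members, usable):
            common = [p for p in pos if p in ref]
            T, _ = superpose(
                m.ca_array(common), np.array([ref[p] for p in common])
            )
            new_transforms.append(T)
        # recompute mean over observed members
        sums: dict[int, np.ndarray] = {}
        counts: dict[int, int] = {}
        for m, T, pos in zip(members, new_transforms, usable):
            for p in pos:
                c = T.apply(m.get(p).ca)
                sums[p] = sums.get(p, 0.0) + c
                counts[p] = counts.get(p, 0) + 1
        new_ref = {p: sums[p] / counts[p] for p in sums}
        shift = max(
            (np.linalg.norm(new_ref[p] - ref[p]) for p in ref if p in new_ref),
            default=0.0,
        )
        ref = new_ref
        transforms = new_transforms
        if shift < tol:
            converged = True
            break
    spreads: dict[int, float] = {}
    for p in ref:
        devs = []
        for m, T in zip(members, transforms):
            r = m.get(p)
            if r is not None:
                devs.append(np.sum((T.apply(r.ca) - ref[p]) ** 2))
        spreads[p] = float(np.sqrt(np.mean(devs)))
    return transforms, ref, spreads, converged


def derive_coresets(
    ensemble: list[DomainStructure],
    presence: float = 0.95,
    spread_threshold: float = 1.0,
    min_positions: int = 20,
) -> Coreset:
    """Derive the structurally conserved coreset of a domain ensemble.

    Starting from all framework positions present in at least ``presence`` of
    the members, the ensemble is iteratively superposed on the current
    coreset and the position with the highest positional spread (RMS
    deviation from the aligned per-position mean) is dropped, until every
    remaining position has spread <= ``spread_threshold`` (Angstrom) or the
    floor of ``min_positions`` is reached.
    """
    if len(ensemble) < 5:
        raise StructureError(f"coreset derivation needs >= 5 structures, got {len(ensemble)}")
    dtype = ensemble[0].domain_type
    n = len(ensemble)
    counts: dict[int, int] = {}
    for m in ensemble:
        for p in m.present_framework():
            counts[p] = counts.get(p, 0) + 1
    positions = sorted(p for p, c in counts.items() if c / n >= presence)
    if len(positions) < min_positions:
        raise StructureError(
            f"only {len(positions)} framework positions pass the {presence:.0%} "
            f"presence rule (need >= {min_positions})"
        )
    while True:
        _, _, spreads, _ = _align_ensemble(ensemble, positions)
        core_spreads = {p: spreads[p] for p in positions}
        worst = max(core_spreads, key=core_spreads.get)
        if core_spreads[worst] <= spread_threshold or len(positions) <= min_positions:
            return Coreset(dtype, frozenset(positions), core_spreads)
        positions.remove(worst)


# ---------------------------------------------------------------------------
# Consensus and frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusDomain:
    """Per-position mean C-alpha structure of an aligned domain ensemble."""

    domain_type: str
    positions: tuple[int, ...]
    coords: np.ndarray  # (N, 3), row i <-> positions[i]
    spreads: dict[int, float] = field(default_factory=dict, compare=False)

    def coord(self, position: int) -> np.ndarray:
        try:
            i = self.positions.index(position)
        except ValueError as exc:
            raise StructureError(f"position {position} absent from consensus") from exc
        return self.coords[i]

    def ca_array(self, positions) -> np.ndarray:
        return np.array([self.coord(p) for p in positions])

    def as_domain(self, chain_id: str) -> DomainStructure:
        """Materialise the consensus as a reduced (C-alpha only) domain."""
        residues = tuple(
            Residue(
                chain_id=chain_id,
                author_number=p,
                amino_acid="A",
                ca=c,
                cb=c,
                imgt_position=p,
            )
            for p, c in zip(self.positions, self.coords)
        )
        return DomainStructure(residues=residues, domain_type=self.domain_type)


def build_consensus(
    ensemble: list[DomainStructure],
    coreset: Coreset,
    tol: float = 1e-4,
    max_iter: int = 100,
    min_presence: float = 0.5,
) -> ConsensusDomain:
    """Consensus (mean) domain by iterative superposition onto the evolving mean.

    Members are aligned on the coreset; the mean C-alpha is recorded for every
    position present in at least ``min_presence`` of the members.  Converged
    when the maximum mean shift drops below ``tol`` Angstrom; non-convergence
    after ``max_iter`` iterations is an error.
    """
    if len(ensemble) < 2:
        raise StructureError("consensus requires >= 2 structures")
    core = sorted(coreset.positions)
    transforms, ref, _, converged = _align_ensemble(
        ensemble, core, n_iter=max_iter, tol=tol
    )
    if not converged:
        raise StructureError(f"consensus did not converge in {max_iter} iterations")
    # mean over all sufficiently present positions, in the converged alignment
    n = len(ensemble)
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    sq: dict[int, float] = {}
    for m, T in zip(ensemble, transforms):
        for r in m.residues:
            if r.imgt_insertion:
                continue
            p = r.imgt_position
            c = T.apply(r.ca)
            sums[p] = sums.get(p, 0.0) + c
            counts[p] = counts.get(p, 0) + 1
    positions = tuple(sorted(p for p, c in counts.items() if c / n >= min_presence))
    coords = np.array([sums[p] / counts[p] for p in positions])
    mean_at = dict(zip(positions, coords))
    devs: dict[int, list[float]] = {p: [] for p in positions}
    for m, T in zip(ensemble, transforms):
        for p in positions:
            r = m.get(p)
            if r is not None:
                devs[p].append(float(np.sum((T.apply(r.ca) - mean_at[p]) ** 2)))
    spreads = {p: float(np.sqrt(np.mean(d))) for p, d in devs.items() if d}
    return ConsensusDomain(ensemble[0].domain_type, positions, coords, spreads)


@dataclass(frozen=True)
class Frame:
    """A per-domain reference frame: origin plus two orthonormal in-plane vectors."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def __post_init__(self) -> None:
        e1 = np.asarray(self.e1, dtype=float)
        e2 = np.asarray(self.e2, dtype=float)
        if abs(np.linalg.norm(e1) - 1) > 1e-9 or abs(np.linalg.norm(e2) - 1) > 1e-9:
            raise GeometryError("frame vectors must be unit length")
        if abs(e1 @ e2) > 1e-9:
            raise GeometryError("frame vectors must be orthogonal")

    def transformed(self, t: RigidTransform) -> "Frame":
        return Frame(t.apply(self.origin), t.apply_vector(self.e1), t.apply_vector(self.e2))


def fit_frame(consensus: ConsensusDomain, interface_positions) -> Frame:
    """Fit a reference frame through the consensus interface positions.

    Origin: centroid of the interface C-alphas.  e1/e2: the two leading
    principal axes of those C-alphas, with signs fixed so e1 points toward
    the IMGT 104 consensus C-alpha and e2 toward IMGT 50.
    """
    avail = [p for p in sorted(interface_positions) if p in consensus.positions]
    if len(avail) < 3:
        raise StructureError("fewer than 3 interface positions available for frame fit")
    P = consensus.ca_array(avail)
    origin = P.mean(axis=0)
    cov = np.cov((P - origin).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    e1 = evecs[:, order[0]]
    e2 = evecs[:, order[1]]
    for vec_name, anchor in ((0, E1_ANCHOR_POSITION), (1, E2_ANCHOR_POSITION)):
        try:
            a = consensus.coord(anchor)
        except StructureError as exc:
            raise StructureError(
                f"sign anchor position {anchor} absent from consensus"
            ) from exc
        v = e1 if vec_name == 0 else e2
        proj = (a - origin) @ v
        if abs(proj) < 1e-9:
            raise StructureError(f"sign anchor {anchor} lies in the frame plane; sign undefined")
        if proj < 0:
            if vec_name == 0:
                e1 = -e1
            else:
                e2 = -e2
    return Frame(origin, e1, e2)


@dataclass
class FrameSystem:
    """Per-side coresets, consensus domains and reference frames.

    Frames live in each consensus' own coordinates; measuring a query
    registers them onto it by coreset superposition.  ``reference_measures``
    (when set by :func:`build_frame_system`) are the six measures of the
    consensus pair in its reference pose, whose pivot axis is the stored
    ``reference_c``.
    """

    coresets: dict[str, Coreset]
    consensus: dict[str, ConsensusDomain]
    frames: dict[str, Frame]
    interface_positions: dict[str, frozenset[int]]
    reference_measures: "OrientationMeasures | None" = None
    reference_c: np.ndarray | None = None

    def register(self, side: str, domain: DomainStructure, min_shared: int = 20):
        """Superpose the consensus coreset onto a query domain.

        Returns the registered frame and the registration RMSD.
        """
        cons = self.consensus[side]
        core = sorted(
            set(self.coresets[side].positions)
            & set(cons.positions)
            & set(domain.positions())
        )
        if len(core) < min_shared:
            raise StructureError(
                f"only {len(core)} coreset positions shared with the query "
                f"{side}-side domain (minimum {min_shared})"
            )
        T, rmsd = superpose(cons.ca_array(core), domain.ca_array(core))
        return self.frames[side].transformed(T), rmsd

    def consensus_fv(self, reference: FvStructure) -> FvStructure:
        """The consensus pair materialised in the pose of ``reference``."""
        domains = {}
        for side in ("H", "L"):
            cons = self.consensus[side]
            dom = reference.domain(side)
            core = sorted(
                set(self.coresets[side].positions)
                & set(cons.positions)
                & set(dom.positions())
            )
            T, _ = superpose(cons.ca_array(core), dom.ca_array(core))
            chain = dom.chain_id
            domains[side] = cons.as_domain(chain).transformed(T)
        return FvStructure(
            first=domains["H"],
            second=domains["L"],
            receptor_class=reference.receptor_class,
            pdb_id=f"{reference.pdb_id or 'ref'}-consensus",
        )


@dataclass(frozen=True)
class OrientationMeasures:
    """The six absolute orientation measures (five angles in degrees, dc in Angstrom)."""

    HL: float
    HC1: float
    HC2: float
    LC1: float
    LC2: float
    dc: float
    registration_rmsd: dict[str, float] = field(default_factory=dict, compare=False)
    registration_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        vals = [self.HL, self.HC1, self.HC2, self.LC1, self.LC2, self.dc]
        if not all(np.isfinite(vals)):
            raise GeometryError("non-finite orientation measure")
        if self.dc <= 0:
            raise GeometryError("dc must be positive")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in MEASURE_NAMES])


def build_consensus_and_frames(
    ensembles: dict[str, list[DomainStructure]],
    interface_positions: dict[str, frozenset[int]] | None = None,
    coresets: dict[str, Coreset] | None = None,
) -> FrameSystem:
    """Derive coresets, consensus domains and frames from per-side ensembles.

    ``ensembles`` maps side ('H'/'L') to a list of domains of that side.
    """
    if interface_positions is None:
        interface_positions = {
            "H": DEFAULT_INTERFACE_POSITIONS,
            "L": DEFAULT_INTERFACE_POSITIONS,
        }
    if coresets is None:
        coresets = {side: derive_coresets(doms) for side, doms in ensembles.items()}
    consensus = {
        side: build_consensus(doms, coresets[side]) for side, doms in ensembles.items()
    }
    frames = {
        side: fit_frame(consensus[side], interface_positions[side])
        for side in ensembles
    }
    return FrameSystem(coresets, consensus, frames, dict(interface_positions))


def build_frame_system(
    fvs: list[FvStructure],
    interface_positions: dict[str, frozenset[int]] | None = None,
    coresets: dict[str, Coreset] | None = None,
) -> FrameSystem:
    """Build a frame system from paired receptors and record the reference pose.

    The reference pose is the consensus pair registered onto the first
    structure; its measures and pivot axis are stored on the returned system.
    """
    ensembles = {
        "H": [fv.first for fv in fvs],
        "L": [fv.second for fv in fvs],
    }
    fs = build_consensus_and_frames(ensembles, interface_positions, coresets)
    ref_fv = fs.consensus_fv(fvs[0])
    fs.reference_measures = compute_measures(ref_fv, fs)
    fh, _ = fs.register("H", ref_fv.first)
    fl, _ = fs.register("L", ref_fv.second)
    fs.reference_c = fh.origin - fl.origin
    return fs


def compute_measures(
    query: FvStructure,
    frame_system: FrameSystem,
    min_shared: int = 20,
    max_registration_rmsd: float = 2.5,
) -> OrientationMeasures:
    """The six absolute orientation measures of a paired receptor.

    Each consensus frame is registered onto the query by coreset
    superposition.  With the registered origins O_H, O_L and in-plane vectors
    e1/e2, the pivot axis is C = O_H - O_L and::

        dc  = |C|
        HL  = torsion(O_H + e1H, O_H, O_L, O_L + e1L)
        HC1 = angle(C, e1H)      HC2 = angle(C, e2H)
        LC1 = angle(-C, e1L)     LC2 = angle(-C, e2L)

    A registration RMSD above ``max_registration_rmsd`` (default 2.5 A) sets
    the ``registration_warning`` flag: the frame may be unreliable.
    """
    registered = {}
    rmsds = {}
    for side in ("H", "L"):
        frame, rmsd = frame_system.register(side, query.domain(side), min_shared)
        registered[side] = frame
        rmsds[side] = rmsd
    fh, fl = registered["H"], registered["L"]
    C = fh.origin - fl.origin
    dc = float(np.linalg.norm(C))
    hl = torsion_angle(fh.origin + fh.e1, fh.origin, fl.origin, fl.origin + fl.e1)
    hc1 = vector_angle(C, fh.e1)
    hc2 = vector_angle(C, fh.e2)
    lc1 = vector_angle(-C, fl.e1)
    lc2 = vector_angle(-C, fl.e2)
    warning = any(r > max_registration_rmsd for r in rmsds.values())
    if warning:
        logger.warning(
            "frame registration RMSD %s exceeds %.2f A for %s; measures may be unreliable",
            {k: round(v, 2) for k, v in rmsds.items()},
            max_registration_rmsd,
            query.pdb_id or "query",
        )
    return OrientationMeasures(
        HL=hl,
        HC1=hc1,
        HC2=hc2,
        LC1=lc1,
        LC2=lc2,
        dc=dc,
        registration_rmsd=rmsds,
        registration_warning=warning,
    )
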