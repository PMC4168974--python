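"""IMGT-position-wise sequence analyses.

Sequences are represented on the IMGT grid as mappings from integer position
(1-128) to one-letter amino acid; unobserved positions are simply absent and
are excluded from both numerator and denominator of every frequency.

The analyses here mirror the receptor-comparison questions: which residue
(if any) is conserved at a position, which positions argue for the VH<->VB /
VL<->VA domain equivalence over its alternative, which interface positions
are conserved in both receptor classes but with *different* residues (and
whether the other class's residue is a plausible antibody mutation), CDR3
length distributions, and a greedy sequence-identity redundancy filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .structures import DomainStructure, FvStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PositionProfile",
    "DivergentPosition",
    "EquivalenceSupport",
    "column_profile",
    "column_conservation",
    "equivalence_support",
    "divergent_interface_positions",
    "cdr3_length_distribution",
    "filter_redundant",
    "sequence_identity",
]

ImgtSequence = dict[int, str]

#: A position is called conserved when one residue reaches this frequency.
CONSERVATION_THRESHOLD = 0.5

#: A divergent position is an "antibody-compatible" engineering target when
#: the other class's conserved residue occurs at this background frequency.
COMPATIBILITY_THRESHOLD = 0.02


@dataclass(frozen=True)
class PositionProfile:
    """Amino-acid frequencies observed at one IMGT position."""

    imgt_position: int
    frequencies: dict[str, float]
    n_observed: int

    def frequency(self, aa: str) -> float:
        return self.frequencies.get(aa, 0.0)

    def top(self) -> tuple[str, float] | None:
        if not self.frequencies:
            return None
        aa = max(sorted(self.frequencies), key=lambda a: self.frequencies[a])
        return aa, self.frequencies[aa]


@dataclass(frozen=True)
class DivergentPosition:
    """A position conserved in both sequence sets but with different residues."""

    position: int
    residue_a: str
    percent_a: float
    residue_b: str
    percent_b: float
    compatible: bool

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("divergent position must conserve different residues")
        if self.percent_a < 50 or self.percent_b < 50:
            raise ValueError("divergent position percentages must be >= 50")


def column_profile(sequences: list[ImgtSequence], position: int) -> PositionProfile:
    """Observed amino-acid frequencies at one position (gaps excluded)."""
    observed = [s[position] for s in sequences if position in s]
    n = len(observed)
    counts = Counter(observed)
    freqs = {aa: c / n for aa, c in counts.items()} if n else {}
    return PositionProfile(position, freqs, n)


def column_conservation(
    sequences: list[ImgtSequence],
    position: int,
    threshold: float = CONSERVATION_THRESHOLD,
    strict: bool = False,
) -> str | None:
    """The conserved residue at a position, or None.

    A residue is conserved when its frequency is >= ``threshold`` (or
    strictly > with ``strict=True``).  An exact two-way tie at the threshold
    is ambiguous: None is returned with a warning.  A position observed in
    no sequence returns None (zero coverage).
    """
    profile = column_profile(sequences, position)
    if profile.n_observed == 0:
        logger.warning("position %d observed in no sequence (zero coverage)", position)
        return None
    qualifying = sorted(
        aa
        for aa, f in profile.frequencies.items()
        if (f > threshold if strict else f >= threshold)
    )
    if len(qualifying) > 1:
        logger.warning(
            "position %d: tie between %s at the %.0f%% threshold; ambiguous",
            position,
            qualifying,
            100 * threshold,
        )
        return None
    return qualifying[0] if qualifying else None


@dataclass(frozen=True)
class EquivalenceSupport:
    """Position tallies for the two domain-pairing hypotheses.

    ``support_hb_la`` counts positions whose conservation pattern argues for
    the VH-VB/VL-VA pairing; ``support_ha_lb`` for the VH-VA/VL-VB
    alternative.
    """

    support_hb_la: int
    support_ha_lb: int
    positions_hb_la: tuple[int, ...]
    positions_ha_lb: tuple[int, ...]


def equivalence_support(
    vh: list[ImgtSequence],
    vl: list[ImgtSequence],
    vb: list[ImgtSequence],
    va: list[ImgtSequence],
    threshold: float = CONSERVATION_THRESHOLD,
) -> EquivalenceSupport:
    """Tally positions supporting each domain-equivalence hypothesis.

    A position argues *against* a pairing (and so supports the alternative)
    when a putatively non-equivalent cross pair shares the same conserved
    residue while the within-receptor partner domain conserves a different
    one.  E.g. VH and VA sharing conserved alanine while VL conserves glycine
    counts toward the VH-VA/VL-VB alternative.
    """
    positions = set()
    for group in (vh, vl, vb, va):
        for s in group:
            positions.update(s)

    def conserved(group, p):
        return column_conservation(group, p, threshold)

    against_hb_la: list[int] = []  # i.e. support for VH-VA/VL-VB
    against_ha_lb: list[int] = []  # i.e. support for VH-VB/VL-VA
    for p in sorted(positions):
        ch, cl, cb, ca_ = (conserved(g, p) for g in (vh, vl, vb, va))
        # evidence against VH-VB/VL-VA: a cross pair (VH,VA) or (VL,VB)
        # shares a conserved residue while the same-receptor partner differs
        if (ch is not None and ch == ca_ and cl is not None and cl != ch) or (
            cl is not None and cl == cb and ch is not None and ch != cl
        ):
            against_hb_la.append(p)
        # evidence against VH-VA/VL-VB: (VH,VB) or (VL,VA) share while the
        # partner differs
        if (ch is not None and ch == cb and cl is not None and cl != ch) or (
            cl is not None and cl == ca_ and ch is not None and ch != cl
        ):
            against_ha_lb.append(p)
    return EquivalenceSupport(
        support_hb_la=len(against_ha_lb),
        support_ha_lb=len(against_hb_la),
        positions_hb_la=tuple(against_ha_lb),
        positions_ha_lb=tuple(against_hb_la),
    )


def divergent_interface_positions(
    set_a: list[ImgtSequence],
    set_b: list[ImgtSequence],
    interface: set[int],
    compat_threshold: float = COMPATIBILITY_THRESHOLD,
    conservation_threshold: float = CONSERVATION_THRESHOLD,
) -> list[DivergentPosition]:
    """Interface positions conserved (> 50%) in both sets with different residues.

    ``compatible`` is True when set B's conserved residue also appears at a
    frequency >= ``compat_threshold`` (default 2%) in set A — i.e. the
    mutation toward B's residue has been observed naturally in A's
    background.
    """
    out: list[DivergentPosition] = []
    for p in sorted(interface):
        ca_ = column_conservation(set_a, p, conservation_threshold, strict=True)
        cb_ = column_conservation(set_b, p, conservation_threshold, strict=True)
        if ca_ is None or cb_ is None or ca_ == cb_:
            continue
        prof_a = column_profile(set_a, p)
        prof_b = column_profile(set_b, p)
        out.append(
            DivergentPosition(
                position=p,
                residue_a=ca_,
                percent_a=100 * prof_a.frequency(ca_),
                residue_b=cb_,
                percent_b=100 * prof_b.frequency(cb_),
                compatible=prof_a.frequency(cb_) >= compat_threshold,
            )
        )
    return out


def cdr3_length_distribution(
    domains: list[DomainStructure],
) -> tuple[dict[int, int], int]:
    """Histogram of CDR3 lengths (residues at IMGT 105-117, insertions included).

    Returns (per-length counts, modal length).  Domains with an empty CDR3
    are counted at length 0 with a warning.  Modal ties resolve to the
    smaller length.
    """
    if not domains:
        raise ValueError("cdr3_length_distribution needs at least one domain")
    counts: Counter[int] = Counter()
    for d in domains:
        n = d.cdr3_length()
        if n == 0:
            logger.warning("domain %s has no CDR3 residues; counted at length 0", d.domain_type)
        counts[n] += 1
    mode = min(
        (length for length in counts), key=lambda k: (-counts[k], k)
    )
    return dict(sorted(counts.items())), mode


def sequence_identity(a: FvStructure, b: FvStructure) -> float:
    """Position-wise identity over the shared observed IMGT grid of both domains.

    Matches / shared observed positions of the concatenated two-domain
    sequence; unobserved positions are excluded from numerator and
    denominator.
    """
    sa = a.concatenated_sequence()
    sb = b.concatenated_sequence()
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    matches = sum(1 for k in shared if sa[k] == sb[k])
    return matches / len(shared)


def filter_redundant(
    structures: list[FvStructure], identity_threshold: float = 0.9
) -> list[FvStructure]:
    """Greedy sequence-identity redundancy filter.

    Candidates are visited in (resolution ascending, pdb_id lexicographic)
    order — best-resolved first — and kept iff their identity to every
    already-kept structure is strictly below the threshold.  The result is
    therefore independent of the input order.
    """
    def sort_key(s: FvStructure):
        res = s.resolution if s.resolution is not None else float("inf")
        return (res, s.pdb_id)

    kept: list[FvStructure] = []
    for s in sorted(structures, key=sort_key):
        if all(sequence_identity(s, k) < identity_threshold for k in kept):
            kept.append(s)
    return kept
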