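"""End-to-end experiments: the orientation survey and the grafting experiment.

``run_survey`` compares two receptor cohorts (e.g. antibodies vs TCRs): it
builds coresets/consensus/frames from the pooled structures, computes the
six absolute orientation measures for every receptor, tests each measure
between the cohorts with a two-sided two-sample Kolmogorov-Smirnov test,
and clusters the pooled pairwise orientation-RMSD matrix with complete
linkage, summarising how much the two classes mix across clusters.

``run_graft_experiment`` transplants every decoy's inter-domain pose onto a
native pMHC complex — anchoring first the L-side (VA) and then the H-side
(VB) domain — counts the steric clashes each graft induces against the
MHC/peptide, and compares the per-decoy total clash counts between two decoy
cohorts with a two-sided Mann-Whitney U test.

No multiple-testing correction is applied across the six measures; the
per-measure p-values are reported as-is.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .complexes import (
    CB_CLASH_CUTOFF,
    CLASH_OVERLAP,
    CONTACT_CUTOFF,
    GraftResult,
    graft_orientation,
)
from .orientation import (
    MEASURE_NAMES,
    ClusterResult,
    FrameSystem,
    build_frame_system,
    compute_measures,
    pairwise_matrix_and_cluster,
)
from .structures import FvStructure, PMHCComplex, StructureError

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "SurveyReport", "GraftReport", "run_survey", "run_graft_experiment"]


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across the pipeline (documented defaults)."""

    clash_overlap: float = CLASH_OVERLAP          # A of vdW overlap
    cb_clash_cutoff: float = CB_CLASH_CUTOFF      # A, reduced-structure fallback
    contact_cutoff: float = CONTACT_CUTOFF        # A, C-beta contact rule
    canonical_band: tuple[float, float] = (40.0, 85.0)  # degrees
    conservation_threshold: float = 0.5
    compatibility_threshold: float = 0.02
    identity_threshold: float = 0.9
    min_shared_positions: int = 20
    cluster_k: int = 2

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "canonical_band" in data:
            data["canonical_band"] = tuple(data["canonical_band"])
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["canonical_band"] = list(d["canonical_band"])
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class SurveyReport:
    """Per-structure measures, per-measure KS tests, clustering and class mixing."""

    measures: pd.DataFrame
    ks_tests: dict[str, tuple[float, float]]
    clustering: ClusterResult
    class_by_label: dict[str, str]
    frame_system: FrameSystem

    @property
    def mixing_fraction(self) -> float:
        """Fraction of clusters containing both receptor classes."""
        clusters: dict[int, set[str]] = {}
        for label, cl in zip(self.clustering.labels, self.clustering.cluster_labels):
            clusters.setdefault(int(cl), set()).add(self.class_by_label[label])
        return sum(1 for v in clusters.values() if len(v) > 1) / len(clusters)


def run_survey(
    cohort_a: list[FvStructure],
    cohort_b: list[FvStructure],
    config: AnalysisConfig | None = None,
    frame_system: FrameSystem | None = None,
) -> SurveyReport:
    """Compare the variable-domain orientations of two receptor cohorts.

    The frame system is built from the pooled cohorts unless one is supplied.
    KS p-values come from scipy's two-sample test (exact for small samples,
    asymptotic otherwise).
    """
    config = config or AnalysisConfig()
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise StructureError("each cohort needs at least 2 structures")
    pooled = list(cohort_a) + list(cohort_b)
    if frame_system is None:
        frame_system = build_frame_system(pooled)

    rows = []
    cohort_of: dict[str, str] = {}
    from .orientation import _structure_labels  # shared labelling rule

    labels = _structure_labels(pooled)
    for idx, (fv, label) in enumerate(zip(pooled, labels)):
        cohort = "A" if idx < len(cohort_a) else "B"
        try:
            m = compute_measures(fv, frame_system, config.min_shared_positions)
        except StructureError as exc:
            logger.warning("measures failed for %s: %s", label, exc)
            continue
        row = {"id": label, "cohort": cohort, "receptor_class": fv.receptor_class}
        row.update(m.as_dict())
        row["registration_warning"] = m.registration_warning
        rows.append(row)
        cohort_of[label] = cohort
    table = pd.DataFrame(rows)

    ks: dict[str, tuple[float, float]] = {}
    for name in MEASURE_NAMES:
        a = table.loc[table.cohort == "A", name].to_numpy()
        b = table.loc[table.cohort == "B", name].to_numpy()
        res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
        ks[name] = (float(res.statistic), float(res.pvalue))

    clustering = pairwise_matrix_and_cluster(
        pooled, k=config.cluster_k, min_shared=config.min_shared_positions, on_error="drop"
    )
    class_by_label = dict(zip(labels, ["A"] * len(cohort_a) + ["B"] * len(cohort_b)))
    return SurveyReport(table, ks, clustering, class_by_label, frame_system)


@dataclass
class GraftReport:
    """Per-decoy graft outcomes, cohort medians and the rank test between cohorts."""

    table: pd.DataFrame
    medians: dict[str, dict[str, float]]
    mannwhitney: tuple[float, float]
    native_clashes: dict[str, int]

    def cohort_totals(self, cohort: str) -> np.ndarray:
        sub = self.table[self.table.cohort == cohort]
        return sub.groupby("decoy_id", sort=False)["clashes_moved"].sum().to_numpy()


def run_graft_experiment(
    native: PMHCComplex,
    decoys_a: list[FvStructure],
    decoys_b: list[FvStructure],
    config: AnalysisConfig | None = None,
) -> GraftReport:
    """Transplant decoy poses onto a native complex and compare cohorts.

    Every decoy is grafted twice — L-side (VA) anchored, then H-side (VB)
    anchored — mirroring the two directions of the published protocol.  The
    per-decoy total clash count is the sum of the moved-domain clashes over
    both anchorings; cohort totals are compared with a two-sided
    Mann-Whitney U test (exact for small samples without ties).
    Individual decoy failures are logged and excluded, not fatal.
    """
    config = config or AnalysisConfig()
    if not decoys_a or not decoys_b:
        raise StructureError("each decoy cohort needs at least 1 structure")
    from .complexes import count_clashes

    native_counts = count_clashes(native, config.clash_overlap, config.cb_clash_cutoff)
    rows = []
    for cohort, decoys in (("A", decoys_a), ("B", decoys_b)):
        for i, decoy in enumerate(decoys):
            decoy_id = decoy.pdb_id or f"{cohort}{i}"
            for anchored in ("L", "H"):
                try:
                    result = graft_orientation(
                        native, decoy, anchored, config.min_shared_positions
                    )
                except StructureError as exc:
                    logger.warning(
                        "graft of %s (anchored %s) failed: %s", decoy_id, anchored, exc
                    )
                    continue
                rows.append(
                    {
                        "decoy_id": decoy_id,
                        "cohort": cohort,
                        "anchored": result.anchored_domain,
                        "moved": result.moved_domain,
                        "clashes_moved": result.clashes_moved_domain,
                        "clashes_anchored": result.clashes_anchored_domain,
                        "n_contacts": len(result.contact_pairs),
                    }
                )
    table = pd.DataFrame(rows)
    medians: dict[str, dict[str, float]] = {}
    for cohort in ("A", "B"):
        sub = table[table.cohort == cohort]
        medians[cohort] = {
            moved: float(sub.loc[sub.moved == moved, "clashes_moved"].median())
            for moved in sub["moved"].unique()
        }
        medians[cohort]["total"] = float(
            sub.groupby("decoy_id", sort=False)["clashes_moved"].sum().median()
        )
    totals_a = table[table.cohort == "A"].groupby("decoy_id", sort=False)["clashes_moved"].sum()
    totals_b = table[table.cohort == "B"].groupby("decoy_id", sort=False)["clashes_moved"].sum()
    if totals_a.nunique() == 1 and totals_b.nunique() == 1 and set(totals_a) == set(totals_b):
        # degenerate identical samples: U test undefined variance, report p=1
        u = len(totals_a) * len(totals_b) / 2.0
        mw = (u, 1.0)
    else:
        res = stats.mannwhitneyu(totals_a, totals_b, alternative="two-sided")
        mw = (float(res.statistic), float(res.pvalue))
    return GraftReport(table, medians, mw, native_counts)
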