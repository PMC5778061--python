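"""End-to-end analysis: aligned sequences in, profile and regions out.

This is the library entry point the CLI wraps: gap-column filtering, guide
tree construction when no phylogeny is supplied, per-column parsimony
reconstruction with substitution scoring, profile smoothing, ECR calling,
and mapping of the calls to reference-protein coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import FilteredAlignment, MultipleAlignment, filter_gap_columns
from .ancestral import ColumnStates, reconstruct_column
from .errors import PairingError
from .matrix import NssMatrix, build_nss, load_qij
from .phylo import RootedTree, build_guide_tree, resolve_polytomies
from .profile import (ConstraintProfile, EcrRegion, call_ecrs, compute_profile,
                      regions_to_reference)
from .seqio import SequenceRecord, validate_pairing

log = logging.getLogger("ecrscan")

__all__ = ["AnalysisParams", "AnalysisResult", "run_analysis"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable pipeline parameters (defaults match the published pipeline)."""

    gap_threshold: float = 0.5
    window: int = 11
    smooth_window: int = 7
    smooth_passes: int = 2
    ecr_threshold: float = 1.0


@dataclass
class AnalysisResult:
    """Everything one run produces, in memory."""

    filtered: FilteredAlignment
    tree: RootedTree
    guide_tree_generated: bool
    columns: list[ColumnStates]
    profile: ConstraintProfile
    regions: list[EcrRegion]
    params: AnalysisParams
    nss: NssMatrix = field(repr=False, default=None)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "sequences": self.filtered.alignment.n_records,
            "raw_columns": (self.filtered.raw or self.filtered.alignment).length,
            "filtered_columns": self.filtered.length,
            "ecrs_called": len(self.regions),
        }


def run_analysis(records: list[SequenceRecord], tree: RootedTree | None = None,
                 reference_id: str | None = None,
                 params: AnalysisParams = AnalysisParams(),
                 nss: NssMatrix | None = None) -> AnalysisResult:
    """Run the full pipeline on aligned records.

    ``reference_id`` defaults to the first record; when ``tree`` is None a
    neighbor-joining guide tree is built from the filtered alignment.
    """
    reference_id = reference_id or records[0].id
    aln = MultipleAlignment(records=records, reference_id=reference_id)
    filtered = filter_gap_columns(aln, threshold=params.gap_threshold)
    log.info("stage=filter columns_in=%d columns_out=%d threshold=%g",
             aln.length, filtered.length, params.gap_threshold)

    generated = tree is None
    if generated:
        tree = build_guide_tree(filtered.alignment.records)
        log.info("stage=guide_tree leaves=%d", tree.n_leaves)
    tree = resolve_polytomies(tree)
    report = validate_pairing(records, tree)
    if not report.ok:
        raise PairingError(str(report))

    if nss is None:
        nss = build_nss(load_qij())

    arr = filtered.alignment.to_array()
    labels = [r.id for r in filtered.alignment.records]
    columns = []
    for k in range(filtered.length):
        column = {label: arr[i, k] for i, label in enumerate(labels)}
        columns.append(reconstruct_column(tree, column, nss))
    log.info("stage=reconstruction columns=%d", len(columns))

    profile = compute_profile(columns, filtered, window=params.window,
                              smooth_window=params.smooth_window,
                              smooth_passes=params.smooth_passes)
    regions = call_ecrs(profile, minimum_threshold=params.ecr_threshold)
    regions = regions_to_reference(regions, filtered)
    log.info("stage=ecr_calling regions=%d", len(regions))

    return AnalysisResult(filtered=filtered, tree=tree,
                          guide_tree_generated=generated, columns=columns,
                          profile=profile, regions=regions, params=params,
                          nss=nss)
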