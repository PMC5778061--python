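"""Feature enrichment inside vs. outside constrained regions.

Given per-residue annotations (amino-acid class, PTM type, variant
pathogenicity, ...) and per-protein ECR masks, each feature is tested with a
two-sided Fisher exact test on the 2x2 table

                      in ECR   not in ECR
    feature residues     a          b
    other residues       c          d

over all annotated residues supplied, with Bonferroni correction across the
features tested.  The background is the annotated residues themselves (not
every residue of every protein); callers wanting a whole-proteome background
can annotate every residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationError
from .profile import EcrRegion

__all__ = ["ResidueAnnotation", "EnrichmentResult", "residue_ecr_mask",
           "read_annotations", "fisher_enrichment", "ecr_fraction"]


@dataclass(frozen=True)
class ResidueAnnotation:
    """One annotated residue: protein, 1-based position, feature label."""

    protein_id: str
    position: int
    feature: str


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    a: int  # feature residues inside ECRs
    b: int  # feature residues outside ECRs
    c: int  # other residues inside ECRs
    d: int  # other residues outside ECRs
    odds_ratio: float
    p_value: float
    adjusted_p: float


def residue_ecr_mask(regions: list[EcrRegion], protein_length: int) -> np.ndarray:
    """Boolean track over reference residues: True inside any ECR.

    Regions must carry reference coordinates; regions with None reference
    bounds (wholly inside a reference gap) are skipped.
    """
    mask = np.zeros(protein_length, dtype=bool)
    for region in regions:
        if region.start_ref is None or region.end_ref is None:
            continue
        if not (1 <= region.start_ref <= region.end_ref <= protein_length):
            raise AnnotationError(
                f"region {region.start_ref}..{region.end_ref} outside protein "
                f"of length {protein_length}"
            )
        mask[region.start_ref - 1:region.end_ref] = True
    return mask


def read_annotations(source) -> list[ResidueAnnotation]:
    """Read a TSV with columns protein_id, position, feature."""
    df = pd.read_csv(source, sep="\t", dtype={"protein_id": str, "feature": str})
    required = {"protein_id", "position", "feature"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"annotation table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        ResidueAnnotation(protein_id=row.protein_id, position=int(row.position),
                          feature=row.feature)
        for row in df.itertuples()
    ]


def _fisher(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and the sample odds ratio (a*d)/(b*c).

    Odds ratio is inf when b*c == 0 with a*d > 0, and nan when both products
    are zero.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)


def fisher_enrichment(annotations: list[ResidueAnnotation],
                      masks: dict[str, np.ndarray],
                      features: list[str] | None = None) -> list[EnrichmentResult]:
    """Per-feature two-sided Fisher tests with Bonferroni correction.

    ``masks`` maps protein_id to its per-residue ECR mask; every annotated
    protein must have a mask, and positions must fall inside it.
    """
    if not annotations:
        raise AnnotationError("empty annotation set")
    in_ecr: list[bool] = []
    labels: list[str] = []
    for ann in annotations:
        mask = masks.get(ann.protein_id)
        if mask is None:
            raise AnnotationError(f"no ECR mask for protein {ann.protein_id!r}")
        if not 1 <= ann.position <= len(mask):
            raise AnnotationError(
                f"annotation at {ann.protein_id}:{ann.position} outside protein "
                f"of length {len(mask)}"
            )
        in_ecr.append(bool(mask[ann.position - 1]))
        labels.append(ann.feature)
    in_ecr_arr = np.array(in_ecr)
    labels_arr = np.array(labels)
    if features is None:
        features = sorted(set(labels))
    m = len(features)
    results = []
    for feature in features:
        is_feature = labels_arr == feature
        a = int((is_feature & in_ecr_arr).sum())
        b = int((is_feature & ~in_ecr_arr).sum())
        c = int((~is_feature & in_ecr_arr).sum())
        d = int((~is_feature & ~in_ecr_arr).sum())
        odds, p = _fisher(a, b, c, d)
        results.append(EnrichmentResult(
            feature=feature, a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p,
            adjusted_p=min(1.0, p * m),
        ))
    return results


def ecr_fraction(masks: dict[str, np.ndarray]) -> float:
    """Residue-weighted fraction of the supplied proteins covered by ECRs
    (the 'expected by random distribution' baseline)."""
    total = sum(len(m) for m in masks.values())
    covered = sum(int(m.sum()) for m in masks.values())
    return covered / total if total else float("nan")


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results (one row per feature) for TSV export."""
    return pd.DataFrame([r.__dict__ for r in results])


def write_results(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(Path(path), sep="\t", index=False)
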