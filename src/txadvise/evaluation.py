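"""The advisor estimator: intron-chain matching and scaled AUC.

A predicted transcriptome is scored against the reference catalogue by
sweeping a confidence (coverage) threshold: at each threshold the kept
predictions yield a sensitivity (fraction of reference transcripts
recovered) and a precision (fraction of kept predictions that match the
reference).  The estimator is the trapezoidal area under precision as a
function of sensitivity, multiplied by 1e4 — sensitivity against a full
reference catalogue is tiny (often below 0.1%), so the raw area would be
unreadably small.

Matching follows the exact-match convention of transcript-assembly
benchmarking: a multi-exon prediction matches a reference transcript iff
both lie on the same chromosome and strand and their intron chains are
identical; single-exon transcripts, having no introns, instead require a
reciprocal overlap of at least ``single_exon_overlap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .gtf_io import Transcript, Transcriptome, read_gtf

#: The estimator is reported on this scale throughout.
AUC_SCALE = 1e4

DEFAULT_SINGLE_EXON_OVERLAP = 0.8


@dataclass(frozen=True)
class MatchLabel:
    """Match verdict for one predicted transcript."""

    transcript_id: str
    coverage: float
    matched: bool
    matched_ref_id: str | None = None

    def __post_init__(self) -> None:
        if self.matched != (self.matched_ref_id is not None):
            raise ValidationError("matched_ref_id must be present iff matched")


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    kept: int
    matched_kept: int
    distinct_ref_matched: int
    sensitivity: float
    precision: float


@dataclass
class RocCurve:
    """Sensitivity/precision sweep over decreasing coverage thresholds."""

    points: list[RocPoint]
    reference_size: int
    auc_scaled: float

    @property
    def max_sensitivity(self) -> float:
        return self.points[-1].sensitivity if self.points else 0.0


def _strands_compatible(pred_strand: str, ref_strand: str) -> bool:
    # '.' (unknown) is compatible with anything; otherwise strands must agree.
    return pred_strand == "." or ref_strand == "." or pred_strand == ref_strand


def _reciprocal_overlap(a: Transcript, b: Transcript) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return ov / max(a.length, b.length)


def match_transcripts(
    pred: Transcriptome,
    ref: Transcriptome,
    single_exon_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
) -> list[MatchLabel]:
    """Label each prediction matched/unmatched against the reference.

    Multi-exon: identical intron chain on the same chromosome and a
    compatible strand.  Single-exon: a single-exon reference transcript on
    the same chromosome/compatible strand with reciprocal overlap
    (overlap length over the longer transcript's length) at least
    ``single_exon_overlap``.  Ties are broken by the lexicographically
    smallest reference id.  Predictions on chromosomes absent from the
    reference are simply unmatched.  Absent coverage is treated as 0.
    """
    if len(ref) == 0:
        raise ValidationError("empty reference: sensitivity undefined")
    if not 0.0 < single_exon_overlap <= 1.0:
        raise ValidationError(
            f"single_exon_overlap must be in (0, 1], got {single_exon_overlap}"
        )

    # index multi-exon reference transcripts by (chrom, intron chain)
    chain_index: dict[tuple[str, tuple[tuple[int, int], ...]], list[Transcript]] = {}
    single_index: dict[str, list[Transcript]] = {}
    for rt in ref:
        chain = rt.intron_chain()
        if chain:
            chain_index.setdefault((rt.chrom, chain), []).append(rt)
        else:
            single_index.setdefault(rt.chrom, []).append(rt)

    labels: list[MatchLabel] = []
    for pt in pred:
        chain = pt.intron_chain()
        candidates: list[Transcript] = []
        if chain:
            for rt in chain_index.get((pt.chrom, chain), ()):
                if _strands_compatible(pt.strand, rt.strand):
                    candidates.append(rt)
        else:
            for rt in single_index.get(pt.chrom, ()):
                if (
                    _strands_compatible(pt.strand, rt.strand)
                    and _reciprocal_overlap(pt, rt) >= single_exon_overlap
                ):
                    candidates.append(rt)
        ref_id = min((rt.transcript_id for rt in candidates), default=None)
        labels.append(
            MatchLabel(
                transcript_id=pt.transcript_id,
                coverage=pt.coverage if pt.coverage is not None else 0.0,
                matched=ref_id is not None,
                matched_ref_id=ref_id,
            )
        )
    return labels


def roc_curve(
    labels: Sequence[MatchLabel],
    reference_size: int,
    bins: int | None = None,
) -> RocCurve:
    """Build the threshold sweep and its scaled AUC.

    Thresholds are the distinct coverage values, visited in decreasing
    order; with ``bins`` set, ``bins`` evenly spaced thresholds between the
    maximum and minimum coverage are used instead (the fixed-binning mode
    of the original external scoring tool, kept for cross-checks).

    The area is the trapezoidal integral of precision over sensitivity,
    with an anchor point at sensitivity 0 carrying the precision of the
    highest-threshold point; no extrapolation past the lowest threshold.
    """
    if reference_size <= 0:
        raise ValidationError(f"reference_size must be positive, got {reference_size}")
    if not labels:
        return RocCurve(points=[], reference_size=reference_size, auc_scaled=0.0)

    cov = np.array([lab.coverage for lab in labels], dtype=float)
    matched = np.array([lab.matched for lab in labels], dtype=bool)
    ref_ids = [lab.matched_ref_id for lab in labels]

    if bins is None:
        thresholds = np.unique(cov)[::-1]
    else:
        if bins < 1:
            raise ValidationError(f"bins must be >= 1, got {bins}")
        thresholds = np.linspace(cov.max(), cov.min(), num=bins)

    points: list[RocPoint] = []
    # sort by decreasing coverage so each threshold is a prefix
    order = np.argsort(-cov, kind="stable")
    cov_sorted = cov[order]
    matched_sorted = matched[order]
    ids_sorted = [ref_ids[i] for i in order]

    seen_refs: set[str] = set()
    kept = matched_kept = 0
    i = 0
    n = len(labels)
    for t in thresholds:
        while i < n and cov_sorted[i] >= t:
            kept += 1
            if matched_sorted[i]:
                matched_kept += 1
                seen_refs.add(ids_sorted[i])
            i += 1
        if kept == 0:
            continue
        points.append(
            RocPoint(
                threshold=float(t),
                kept=kept,
                matched_kept=matched_kept,
                distinct_ref_matched=len(seen_refs),
                sensitivity=len(seen_refs) / reference_size,
                precision=matched_kept / kept,
            )
        )

    auc = _trapezoid_auc(points)
    return RocCurve(points=points, reference_size=reference_size, auc_scaled=auc)


def _trapezoid_auc(points: Sequence[RocPoint]) -> float:
    if not points:
        return 0.0
    sens = [0.0] + [p.sensitivity for p in points]
    prec = [points[0].precision] + [p.precision for p in points]
    area = float(np.trapezoid(prec, sens))
    return AUC_SCALE * area


def auc(
    pred_gtf: str | Path | Transcriptome,
    ref_gtf: str | Path | Transcriptome,
    single_exon_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
    bins: int | None = None,
) -> float:
    """Scaled AUC of a predicted assembly against a reference catalogue.

    Accepts GTF paths or in-memory :class:`Transcriptome` objects; the
    composition read → match → sweep → area.
    """
    pred = pred_gtf if isinstance(pred_gtf, Transcriptome) else read_gtf(pred_gtf)
    ref = ref_gtf if isinstance(ref_gtf, Transcriptome) else read_gtf(ref_gtf)
    labels = match_transcripts(pred, ref, single_exon_overlap=single_exon_overlap)
    return roc_curve(labels, reference_size=len(ref), bins=bins).auc_scaled
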