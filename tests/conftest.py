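"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results with naive algorithms
(all-pairs matching, exhaustive threshold enumeration, manual trapezoid
sums) so they share no code path with the package implementations they
check.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pytest

from txadvise import load_parameter_space
from txadvise.gtf_io import Exon, Transcript, Transcriptome


# ---------------------------------------------------------------------------
# oracle: naive all-pairs transcript matcher

def oracle_match(pred, ref, single_exon_overlap=0.8):
    """O(n*m) comparator applying the matching rules directly."""
    out = {}
    for p in pred:
        hits = []
        for r in ref:
            if p.chrom != r.chrom:
                continue
            if not (p.strand == "." or r.strand == "." or p.strand == r.strand):
                continue
            p_introns = [(a.end + 1, b.start - 1)
                         for a, b in zip(p.exons, p.exons[1:])]
            r_introns = [(a.end + 1, b.start - 1)
                         for a, b in zip(r.exons, r.exons[1:])]
            if p_introns:
                if p_introns == r_introns:
                    hits.append(r.transcript_id)
            else:
                if r_introns:
                    continue
                ov = min(p.end, r.end) - max(p.start, r.start) + 1
                longer = max(sum(e.end - e.start + 1 for e in p.exons),
                             sum(e.end - e.start + 1 for e in r.exons))
                if ov > 0 and ov / longer >= single_exon_overlap:
                    hits.append(r.transcript_id)
        out[p.transcript_id] = min(hits) if hits else None
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive-threshold AUC

def oracle_auc(cov_matched_pairs, reference_size, ref_of=None):
    """Scaled AUC by brute force.

    ``cov_matched_pairs``: list of (coverage, matched_ref_id_or_None).
    For every distinct coverage value t (descending) recompute kept /
    matched / distinct-reference counts from scratch, then integrate
    precision over sensitivity with an explicit trapezoid loop, anchored
    at (0, first precision).
    """
    if not cov_matched_pairs:
        return 0.0
    thresholds = sorted({c for c, _ in cov_matched_pairs}, reverse=True)
    pts = []
    for t in thresholds:
        kept = [(c, r) for c, r in cov_matched_pairs if c >= t]
        matched = [r for _, r in kept if r is not None]
        sens = len(set(matched)) / reference_size
        prec = len(matched) / len(kept)
        pts.append((sens, prec))
    area = 0.0
    prev_s, prev_p = 0.0, pts[0][1]
    for s, p in pts:
        area += (s - prev_s) * (p + prev_p) / 2.0
        prev_s, prev_p = s, p
    return 1e4 * area


# ---------------------------------------------------------------------------
# random instance generators used by oracle comparisons

def random_instance(rng, n_ref=30, n_pred=50):
    """A (pred, ref) transcriptome pair exercising every matching rule.

    Predictions mix verbatim copies, strand flips, perturbed chains,
    single-exon overlaps of varying degree, unknown strands, and
    off-reference chromosomes.
    """
    ref = Transcriptome()
    for i in range(n_ref):
        chrom = f"chr{rng.integers(1, 4)}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, 500_000))
        n_ex = int(rng.integers(1, 5))
        exons, pos = [], start
        for j in range(n_ex):
            ln = int(rng.integers(50, 300))
            exons.append(Exon(pos, pos + ln - 1))
            pos += ln + int(rng.integers(40, 400))
        ref.add(Transcript(f"ref{i:03d}", f"rg{i:03d}", chrom, strand, exons))

    ref_list = list(ref)
    pred = Transcriptome()
    for i in range(n_pred):
        cov = float(rng.lognormal(1.5, 1.0))
        kind = rng.random()
        src = ref_list[int(rng.integers(len(ref_list)))]
        tid = f"pred{i:03d}"
        if kind < 0.35:  # verbatim copy (maybe strand-unknown)
            strand = "." if rng.random() < 0.2 else src.strand
            pred.add(Transcript(tid, src.gene_id, src.chrom, strand,
                                list(src.exons), cov))
        elif kind < 0.55:  # strand flip
            strand = "-" if src.strand == "+" else "+"
            pred.add(Transcript(tid, src.gene_id, src.chrom, strand,
                                list(src.exons), cov))
        elif kind < 0.75 and len(src.exons) > 1:  # perturbed intron boundary
            exons = list(src.exons)
            d = int(rng.integers(2, 10))
            e = exons[0]
            if e.end - e.start > d + 1:
                exons[0] = Exon(e.start, e.end - d)
            pred.add(Transcript(tid, src.gene_id, src.chrom, src.strand,
                                exons, cov))
        elif kind < 0.9:  # single-exon with partial overlap
            ln = int(rng.integers(100, 400))
            shift = int(rng.integers(0, ln))
            s0 = src.start + shift
            pred.add(Transcript(tid, src.gene_id, src.chrom, src.strand,
                                [Exon(s0, s0 + ln - 1)], cov))
        else:  # foreign chromosome
            pred.add(Transcript(tid, src.gene_id, "chrUn", src.strand,
                                list(src.exons), cov))
    return pred, ref


# ---------------------------------------------------------------------------
# fixtures

SMALL_SPACE_YAML = """
assembler: toy
parameters:
  - {name: a, kind: integer, default: 5, lower: 0, upper: 10, step: 1, flag: "-a"}
  - {name: b, kind: real, default: 2.0, lower: 0.0, upper: 4.0, step: 0.5, flag: "-b"}
  - {name: flip, kind: boolean, default: false, flag: "--flip"}
  - {name: mode, kind: categorical, default: fast, choices: [fast, full, safe], flag: "--mode"}
"""


@pytest.fixture
def small_spec():
    return load_parameter_space(io.StringIO(SMALL_SPACE_YAML))


@pytest.fixture
def numeric_spec():
    """Two integer parameters on [0, 10], step 1 — grid-enumerable."""
    return load_parameter_space(io.StringIO("""
parameters:
  - {name: a, kind: integer, default: 1, lower: 0, upper: 10, step: 1, flag: "-a"}
  - {name: b, kind: integer, default: 1, lower: 0, upper: 10, step: 1, flag: "-b"}
"""))


@pytest.fixture
def tiny_reference():
    """Four transcripts on two chromosomes, incl. one single-exon."""
    return Transcriptome([
        Transcript("r1", "g1", "chr1", "+", [Exon(100, 200), Exon(300, 400)]),
        Transcript("r2", "g1", "chr1", "+", [Exon(100, 200), Exon(350, 450)]),
        Transcript("r3", "g2", "chr1", "-", [Exon(1000, 1500)]),
        Transcript("r4", "g3", "chr2", "+", [Exon(10, 90), Exon(200, 290), Exon(400, 480)]),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
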