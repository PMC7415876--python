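"""Synthetic transcriptomes and assemblies with planted ground truth.

The generator emulates the shape of real reference-based assembly
evaluation without any sequencing data: a reference transcriptome of
multi- and single-exon transcripts laid out on a few chromosomes, and
predicted assemblies that mix verbatim copies of reference transcripts
(planted true positives, drawing coverage from a high-mean distribution)
with intron-perturbed decoys (false positives, low-mean coverage).  The
perturbation moves an intron boundary by at least two bases and is checked
against every reference intron chain, so a decoy can never accidentally
match — the planted labels are exact ground truth for the matcher.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .advisor_core import AdvisorSet, ParameterSpec, ParameterVector, validate_vector
from .errors import ValidationError
from .gtf_io import Exon, Transcript, Transcriptome

_GENE_GAP = 10_000  # bases between neighbouring gene loci


@dataclass
class CoverageModel:
    """Log-normal coverage distributions for planted TPs and decoy FPs.

    True positives draw from a clearly higher-mean distribution so the
    coverage-threshold sweep produces a non-trivial curve; both are
    configurable.  Parameters are of the underlying normal.
    """

    tp_log_mean: float = math.log(20.0)
    tp_log_sigma: float = 0.5
    fp_log_mean: float = math.log(2.0)
    fp_log_sigma: float = 0.5


@dataclass
class ReferenceModel:
    """Declarative model of a synthetic reference transcriptome."""

    n_genes: int
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (1, 8)
    exon_length: tuple[int, int] = (80, 400)
    intron_length: tuple[int, int] = (60, 2000)
    chrom_count: int = 3
    single_exon_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transcripts_per_gene", "exons_per_transcript",
                     "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name}: infeasible range ({lo}, {hi})")
        if self.chrom_count < 1 or self.n_genes < 0:
            raise ValidationError("chrom_count must be >= 1 and n_genes >= 0")


def _sample_exons(rng: np.random.Generator, start: int, n_exons: int,
                  model: ReferenceModel) -> list[Exon]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(model.exon_length[0], model.exon_length[1] + 1))
        exons.append(Exon(pos, pos + length - 1))
        if i < n_exons - 1:
            gap = int(rng.integers(model.intron_length[0], model.intron_length[1] + 1))
            pos = pos + length + gap
    return exons


def generate_reference(model: ReferenceModel) -> Transcriptome:
    """Generate a reference transcriptome from a :class:`ReferenceModel`.

    Genes are placed without overlap, round-robin across chromosomes;
    transcripts within a gene share the locus start but differ in their
    intron chains (a gene gets at most one single-exon transcript).
    """
    rng = np.random.default_rng(model.seed)
    out = Transcriptome()
    cursor = {f"chr{c + 1}": 1 for c in range(model.chrom_count)}

    for gi in range(model.n_genes):
        chrom = f"chr{gi % model.chrom_count + 1}"
        gene_id = f"g{gi:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(model.transcripts_per_gene[0],
                                model.transcripts_per_gene[1] + 1))
        start = cursor[chrom]
        chains_seen: set[tuple] = set()
        gene_end = start
        tj = 0
        for _ in range(n_tx):
            lo, hi = model.exons_per_transcript
            if hi < 2 or (lo <= 1 and rng.random() < model.single_exon_fraction):
                n_exons = 1
            else:
                n_exons = int(rng.integers(max(2, lo), hi + 1))
            # retry a few times for a chain distinct within the gene
            for _attempt in range(8):
                exons = _sample_exons(rng, start, n_exons, model)
                t = Transcript(
                    transcript_id=f"{gene_id}.t{tj}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
                chain = t.intron_chain()
                if chain not in chains_seen:
                    chains_seen.add(chain)
                    out.add(t)
                    gene_end = max(gene_end, t.end)
                    tj += 1
                    break
        cursor[chrom] = gene_end + _GENE_GAP
    return out


def _chain_blacklist(ref: Transcriptome) -> set[tuple[str, tuple]]:
    return {(t.chrom, t.intron_chain()) for t in ref if t.intron_chain()}


def perturb_intron_chain(
    t: Transcript,
    rng: np.random.Generator,
    blacklist: set[tuple[str, tuple]],
    new_id: str,
    coverage: float,
) -> Transcript | None:
    """A decoy copy of multi-exon ``t`` with one intron boundary moved >= 2 bases.

    Keeps the source gene's locus (a plausible mis-assembly, not random
    noise).  Returns ``None`` if no perturbation avoids every reference
    intron chain in ``blacklist`` — callers then pick another source.
    """
    chain = t.intron_chain()
    if not chain:
        return None
    intron_ix = int(rng.integers(len(chain)))
    for delta in rng.permutation([2, 3, 4, 5, 7, 9, 12, 15]):
        delta = int(delta)
        exons = list(t.exons)
        donor = exons[intron_ix]
        if len(donor) <= delta + 1:
            continue
        # shrink the donor exon: intron start moves left by delta
        exons[intron_ix] = Exon(donor.start, donor.end - delta)
        cand = Transcript(
            transcript_id=new_id,
            gene_id=t.gene_id,
            chrom=t.chrom,
            strand=t.strand,
            exons=exons,
            coverage=coverage,
        )
        if (cand.chrom, cand.intron_chain()) not in blacklist:
            return cand
    return None


def false_positive_pool(
    ref: Transcriptome,
    count: int,
    rng: np.random.Generator,
    coverages: Sequence[float],
) -> list[Transcript]:
    """``count`` decoy transcripts derived from multi-exon reference sources."""
    blacklist = _chain_blacklist(ref)
    sources = sorted((t for t in ref if t.intron_chain()),
                     key=lambda t: t.transcript_id)
    if not sources and count > 0:
        raise ValidationError("no multi-exon reference transcripts to perturb")
    pool: list[Transcript] = []
    si = 0
    attempts = 0
    while len(pool) < count:
        if attempts > 20 * count + 100:
            raise ValidationError("could not generate enough distinct decoys")
        src = sources[si % len(sources)]
        si += 1
        attempts += 1
        fp = perturb_intron_chain(
            src, rng, blacklist, new_id=f"fp{len(pool):05d}",
            coverage=float(coverages[len(pool)]),
        )
        if fp is not None:
            pool.append(fp)
            blacklist.add((fp.chrom, fp.intron_chain()))
    return pool


def generate_assembly(
    ref: Transcriptome,
    tp_fraction: float,
    fp_count: int,
    coverage_model: CoverageModel | None = None,
    seed: int = 0,
) -> Transcriptome:
    """A predicted assembly with planted truth.

    ``round(tp_fraction * |ref|)`` reference transcripts are copied
    verbatim (true positives) with coverages from the TP distribution;
    ``fp_count`` intron-perturbed decoys carry FP-distribution coverages.
    """
    if not 0.0 <= tp_fraction <= 1.0:
        raise ValidationError(f"tp_fraction must be in [0,1], got {tp_fraction}")
    cm = coverage_model or CoverageModel()
    rng = np.random.default_rng(seed)
    n_tp = round(tp_fraction * len(ref))
    ids = sorted(t.transcript_id for t in ref)
    chosen = [ids[i] for i in rng.permutation(len(ids))[:n_tp]]
    tp_cov = rng.lognormal(cm.tp_log_mean, cm.tp_log_sigma, size=n_tp)
    fp_cov = rng.lognormal(cm.fp_log_mean, cm.fp_log_sigma, size=fp_count)

    out = Transcriptome()
    for tid, cov in zip(chosen, tp_cov):
        src = ref[tid]
        out.add(Transcript(
            transcript_id=tid, gene_id=src.gene_id, chrom=src.chrom,
            strand=src.strand, exons=list(src.exons), coverage=float(cov),
        ))
    for fp in false_positive_pool(ref, fp_count, rng, fp_cov):
        out.add(fp)
    return out


def random_advisor_set(
    spec: Sequence[ParameterSpec], n: int, seed: int = 0
) -> AdvisorSet:
    """``n`` distinct parameter vectors sampled uniformly on the value grid.

    Numeric parameters are uniform over the step grid within bounds;
    booleans and categoricals uniform over their values.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def grid(p: ParameterSpec) -> list:
        if p.kind in ("integer", "real"):
            if p.multiplicative:
                vals, v = [], p.lower
                while v <= p.upper * (1 + 1e-12):
                    vals.append(int(round(v)) if p.kind == "integer" else float(v))
                    v *= p.step
                return vals
            k = int(np.floor((p.upper - p.lower) / p.step + 1e-9))
            vals = [p.lower + i * p.step for i in range(k + 1)]
            return [int(round(v)) if p.kind == "integer" else float(v) for v in vals]
        if p.kind == "boolean":
            return [False, True]
        return list(p.choices)

    grids = {p.name: grid(p) for p in spec}
    total = int(np.prod([len(g) for g in grids.values()], dtype=object))
    if n > total:
        raise ValidationError(
            f"requested {n} distinct vectors but the grid has only {total} points"
        )

    seen: set[tuple] = set()
    vectors: list[ParameterVector] = []
    while len(vectors) < n:
        values = {name: g[int(rng.integers(len(g)))] for name, g in grids.items()}
        v = ParameterVector(values, provenance=f"random:{len(vectors)}")
        if v.key() in seen:
            continue
        violations = validate_vector(spec, v)
        if violations:  # grid points are in-bounds by construction
            raise ValidationError("; ".join(violations))
        seen.add(v.key())
        vectors.append(v)
    return AdvisorSet(vectors=vectors, includes_default=False)
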