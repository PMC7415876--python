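"""Assembler adapters: Scallop, StringTie, and an internal mock.

An adapter turns (sample, parameter vector) into an assembly GTF under a
uniform contract: the output file name encodes a stable hash of the
vector (so concurrent runs never collide), every invocation is logged
with its command line, exit status and duration, and failures raise
:class:`AdapterError` carrying the captured process output.

The mock assembler needs no external binary: a sample is a small YAML
landscape file declaring a planted optimum vector, per-parameter weights,
and a reference transcriptome.  Assembly "quality" is a separable
unimodal function of the parameter vector,

    quality(p) = exp(-sum_i w_i * d_i(p, p*)^2),    d_i in steps,

and the emitted assembly contains ``round(quality * max_sensitivity *
|reference|)`` true-positive transcripts (high coverage) plus
``round(fp_max * (1 - quality))`` intron-perturbed decoys (low coverage),
so the estimator's AUC increases with quality and is maximal exactly at
the planted optimum.  The full advising stack runs end-to-end on the mock
in seconds.
"""

from __future__ import annotations

import hashlib
import logging
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .advisor_core import ParameterSpec, ParameterVector, validate_vector
from .errors import AdapterError, ValidationError
from .gtf_io import Transcript, Transcriptome, read_gtf, write_gtf
from .synthetic import CoverageModel, false_positive_pool

logger = logging.getLogger(__name__)


def vector_hash(v: ParameterVector) -> str:
    """Stable 12-hex-digit digest of a vector's value assignment."""
    canon = repr(sorted(v.values.items())).encode()
    return hashlib.sha1(canon).hexdigest()[:12]


class AssemblerAdapter:
    """Base contract: produce an assembly GTF from (sample, vector)."""

    #: how boolean parameters render: "value" (--flag true/false) or
    #: "presence" (flag emitted only when true)
    bool_style = "value"

    def __init__(self, spec: Sequence[ParameterSpec], name: str = "assembler",
                 timeout: float = 3600.0) -> None:
        self.spec = list(spec)
        self.name = name
        self.timeout = timeout

    def render_args(self, v: ParameterVector) -> list[str]:
        """Command-line arguments for ``v``; each parameter's flag used once."""
        violations = validate_vector(self.spec, v)
        if violations:
            raise ValidationError("; ".join(violations))
        args: list[str] = []
        for p in self.spec:
            value = v.values[p.name]
            if p.kind == "boolean":
                if self.bool_style == "presence":
                    if value:
                        args.append(p.flag)
                else:
                    args.extend([p.flag, "true" if value else "false"])
            else:
                args.extend([p.flag, str(value)])
        return args

    def output_path(self, out_dir: str | Path, v: ParameterVector) -> Path:
        return Path(out_dir) / f"assembly_{vector_hash(v)}.gtf"

    def run(self, sample: str | Path, v: ParameterVector, out_dir: str | Path) -> Path:
        raise NotImplementedError


class SubprocessAdapter(AssemblerAdapter):
    """Adapter driving an external assembler binary."""

    def __init__(self, spec: Sequence[ParameterSpec], executable: str,
                 name: str, timeout: float = 3600.0) -> None:
        super().__init__(spec, name=name, timeout=timeout)
        self.executable = executable

    def build_command(self, sample: Path, out_path: Path,
                      v: ParameterVector) -> list[str]:
        raise NotImplementedError

    def run(self, sample: str | Path, v: ParameterVector, out_dir: str | Path) -> Path:
        sample = Path(sample)
        if not sample.exists():
            raise AdapterError(f"sample {sample} does not exist")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = self.output_path(out_dir, v)
        cmd = self.build_command(sample, out_path, v)
        logger.info("%s: %s", self.name, " ".join(cmd))
        t0 = time.monotonic()
        try:
            proc = subprocess.run(
                cmd, capture_output=True, text=True, timeout=self.timeout
            )
        except (subprocess.TimeoutExpired, OSError) as exc:
            raise AdapterError(f"{self.name} invocation failed: {exc}") from exc
        dt = time.monotonic() - t0
        logger.info("%s: exit %d in %.1fs", self.name, proc.returncode, dt)
        if proc.returncode != 0:
            raise AdapterError(
                f"{self.name} exited {proc.returncode}:\n{proc.stderr[-2000:]}"
            )
        if not out_path.exists() or out_path.stat().st_size == 0:
            raise AdapterError(f"{self.name} produced no output at {out_path}")
        return out_path


class ScallopAdapter(SubprocessAdapter):
    """Scallop: ``scallop -i sample.bam -o out.gtf [flags...]``.

    Scallop takes value-style boolean flags (``--flag true``).
    """

    bool_style = "value"

    def __init__(self, spec: Sequence[ParameterSpec],
                 executable: str = "scallop", timeout: float = 3600.0) -> None:
        super().__init__(spec, executable, name="scallop", timeout=timeout)

    def build_command(self, sample: Path, out_path: Path,
                      v: ParameterVector) -> list[str]:
        return [self.executable, "-i", str(sample), "-o", str(out_path),
                *self.render_args(v)]


class StringTieAdapter(SubprocessAdapter):
    """StringTie: ``stringtie sample.bam -o out.gtf [flags...]``.

    StringTie takes presence-style boolean flags (``-t`` emitted or not).
    """

    bool_style = "presence"

    def __init__(self, spec: Sequence[ParameterSpec],
                 executable: str = "stringtie", timeout: float = 3600.0) -> None:
        super().__init__(spec, executable, name="stringtie", timeout=timeout)

    def build_command(self, sample: Path, out_path: Path,
                      v: ParameterVector) -> list[str]:
        return [self.executable, str(sample), "-o", str(out_path),
                *self.render_args(v)]


# ---------------------------------------------------------------------------
# mock assembler


@dataclass
class MockLandscape:
    """A declared assembly-quality landscape with a planted optimum.

    ``quality(p) = exp(-sum_i w_i d_i^2)`` with the per-parameter distance
    ``d_i`` measured in spec steps for numeric parameters and as 0/1 for
    booleans/categoricals; ``quality(p*) = 1``.  An optional second
    optimum (``optimum2``, scaled by ``mode2_height < 1``) turns the
    landscape bimodal for robustness experiments.
    """

    spec: list[ParameterSpec]
    optimum: ParameterVector
    weights: dict[str, float]
    reference: Transcriptome
    max_sensitivity: float = 0.5
    fp_max: int = 100
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    seed: int = 0
    optimum2: ParameterVector | None = None
    mode2_height: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.max_sensitivity <= 1.0:
            raise ValidationError("max_sensitivity must be in (0, 1]")
        bad = validate_vector(self.spec, self.optimum)
        if bad:
            raise ValidationError("invalid optimum: " + "; ".join(bad))
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be non-negative")
        self._sample_cache: dict[int, tuple] = {}

    def _distance_sq(self, v: ParameterVector, opt: ParameterVector) -> float:
        total = 0.0
        for p in self.spec:
            w = self.weights.get(p.name, 0.0)
            a, b = v.values[p.name], opt.values[p.name]
            if p.kind in ("integer", "real"):
                d = abs(a - b) / p.step
            else:
                d = 0.0 if a == b else 1.0
            total += w * d * d
        return total

    def quality(self, v: ParameterVector) -> float:
        q = float(np.exp(-self._distance_sq(v, self.optimum)))
        if self.optimum2 is not None:
            q2 = self.mode2_height * float(
                np.exp(-self._distance_sq(v, self.optimum2))
            )
            q = max(q, q2)
        return q

    def _sample_state(self, sample_seed: int):
        """Priority order, TP coverages and FP pool — fixed per sample.

        Independent of the parameter vector, so the TP sets produced for
        two vectors are nested and AUC is monotone in quality.
        """
        if sample_seed not in self._sample_cache:
            rng = np.random.default_rng([self.seed, sample_seed])
            ids = sorted(t.transcript_id for t in self.reference)
            priority = [ids[i] for i in rng.permutation(len(ids))]
            cm = self.coverage_model
            tp_cov = rng.lognormal(cm.tp_log_mean, cm.tp_log_sigma, size=len(ids))
            fp_cov = rng.lognormal(cm.fp_log_mean, cm.fp_log_sigma, size=self.fp_max)
            fp_pool = false_positive_pool(self.reference, self.fp_max, rng, fp_cov)
            self._sample_cache[sample_seed] = (priority, tp_cov, fp_pool)
        return self._sample_cache[sample_seed]


def mock_assemble(
    landscape: MockLandscape, v: ParameterVector, sample_seed: int = 0
) -> Transcriptome:
    """Deterministic mock assembly for ``v`` on one sample.

    The highest-priority ``round(quality * max_sensitivity * |reference|)``
    reference transcripts are emitted verbatim with high-mean coverages;
    ``round(fp_max * (1 - quality))`` decoys with low-mean coverages are
    appended.  Same (landscape, vector, seed) gives identical output.
    """
    q = landscape.quality(v)
    priority, tp_cov, fp_pool = landscape._sample_state(sample_seed)
    ref = landscape.reference
    n_tp = round(q * landscape.max_sensitivity * len(ref))
    n_fp = round(landscape.fp_max * (1.0 - q))

    out = Transcriptome()
    for i, tid in enumerate(priority[:n_tp]):
        src = ref[tid]
        out.add(Transcript(
            transcript_id=tid, gene_id=src.gene_id, chrom=src.chrom,
            strand=src.strand, exons=list(src.exons), coverage=float(tp_cov[i]),
        ))
    for fp in fp_pool[:n_fp]:
        out.add(fp)
    return out


class MockAssemblerAdapter(AssemblerAdapter):
    """Adapter whose "sample" is a landscape YAML file (no binaries needed)."""

    def __init__(self, spec: Sequence[ParameterSpec], timeout: float = 60.0) -> None:
        super().__init__(spec, name="mock", timeout=timeout)
        self._landscapes: dict[Path, MockLandscape] = {}
        self._sample_seeds: dict[Path, int] = {}

    def _load(self, sample: Path) -> tuple[MockLandscape, int]:
        sample = sample.resolve()
        if sample not in self._landscapes:
            landscape, sample_seed = load_landscape(sample, self.spec)
            self._landscapes[sample] = landscape
            self._sample_seeds[sample] = sample_seed
        return self._landscapes[sample], self._sample_seeds[sample]

    def run(self, sample: str | Path, v: ParameterVector, out_dir: str | Path) -> Path:
        sample = Path(sample)
        if not sample.exists():
            raise AdapterError(f"sample {sample} does not exist")
        violations = validate_vector(self.spec, v)
        if violations:
            raise ValidationError("; ".join(violations))
        try:
            landscape, sample_seed = self._load(sample)
        except (OSError, KeyError, yaml.YAMLError) as exc:
            raise AdapterError(f"cannot load landscape {sample}: {exc}") from exc
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = self.output_path(out_dir, v)
        assembly = mock_assemble(landscape, v, sample_seed)
        write_gtf(assembly, out_path)
        return out_path


# ---------------------------------------------------------------------------
# landscape files


def write_landscape(
    landscape: MockLandscape,
    path: str | Path,
    reference_path: str | Path,
    sample_seed: int = 0,
) -> None:
    """Serialise a landscape to YAML; the reference stays a GTF next to it.

    ``reference_path`` is stored relative to the YAML file when possible.
    """
    path = Path(path)
    ref_path = Path(reference_path)
    try:
        ref_rel = str(ref_path.resolve().relative_to(path.resolve().parent))
    except ValueError:
        ref_rel = str(ref_path.resolve())
    doc = {
        "kind": "mock-landscape",
        "reference": ref_rel,
        "seed": landscape.seed,
        "sample_seed": sample_seed,
        "max_sensitivity": landscape.max_sensitivity,
        "fp_max": landscape.fp_max,
        "optimum": dict(landscape.optimum.values),
        "weights": dict(landscape.weights),
        "coverage_model": {
            "tp_log_mean": float(landscape.coverage_model.tp_log_mean),
            "tp_log_sigma": float(landscape.coverage_model.tp_log_sigma),
            "fp_log_mean": float(landscape.coverage_model.fp_log_mean),
            "fp_log_sigma": float(landscape.coverage_model.fp_log_sigma),
        },
    }
    if landscape.optimum2 is not None:
        doc["optimum2"] = dict(landscape.optimum2.values)
        doc["mode2_height"] = landscape.mode2_height
    with open(path, "wt") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_landscape(
    path: str | Path, spec: Sequence[ParameterSpec]
) -> tuple[MockLandscape, int]:
    """Load a landscape YAML; returns (landscape, sample_seed)."""
    path = Path(path)
    with open(path, "rt") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("kind") != "mock-landscape":
        raise ValidationError(f"{path}: not a mock-landscape file")
    ref_path = Path(doc["reference"])
    if not ref_path.is_absolute():
        ref_path = path.parent / ref_path
    cm_doc = doc.get("coverage_model", {})
    landscape = MockLandscape(
        spec=list(spec),
        optimum=ParameterVector(dict(doc["optimum"]), provenance="optimum"),
        weights=dict(doc["weights"]),
        reference=read_gtf(ref_path),
        max_sensitivity=float(doc.get("max_sensitivity", 0.5)),
        fp_max=int(doc.get("fp_max", 100)),
        coverage_model=CoverageModel(**cm_doc) if cm_doc else CoverageModel(),
        seed=int(doc.get("seed", 0)),
        optimum2=(
            ParameterVector(dict(doc["optimum2"]), provenance="optimum2")
            if "optimum2" in doc else None
        ),
        mode2_height=float(doc.get("mode2_height", 0.6)),
    )
    return landscape, int(doc.get("sample_seed", 0))


def random_landscape(
    spec: Sequence[ParameterSpec],
    reference: Transcriptome,
    seed: int,
    max_offset_steps: int = 2,
    weight_range: tuple[float, float] = (0.1, 0.3),
    max_sensitivity: float = 0.5,
    fp_max: int = 100,
) -> MockLandscape:
    """Sample a landscape with a planted optimum near the default vector.

    The optimum sits within ``max_offset_steps`` grid steps of the default
    on every numeric coordinate (clamped to bounds) and the weights are
    uniform in ``weight_range`` — gentle enough that the quality at the
    default is non-negligible and every single-coordinate step toward the
    optimum moves the rounded true-positive count, which is what makes
    coordinate-ascent recovery of the optimum a fair test.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, Any] = {}
    for p in spec:
        if p.kind in ("integer", "real"):
            k = int(rng.integers(-max_offset_steps, max_offset_steps + 1))
            v = p.default + k * p.step
            v = min(max(v, p.lower), p.upper)
            values[p.name] = int(round(v)) if p.kind == "integer" else float(v)
        elif p.kind == "boolean":
            values[p.name] = bool(rng.integers(2))
        else:
            values[p.name] = p.choices[int(rng.integers(len(p.choices)))]
    weights = {
        p.name: float(rng.uniform(*weight_range)) for p in spec
    }
    return MockLandscape(
        spec=list(spec),
        optimum=ParameterVector(values, provenance=f"planted:{seed}"),
        weights=weights,
        reference=reference,
        max_sensitivity=max_sensitivity,
        fp_max=fp_max,
        seed=seed,
    )
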