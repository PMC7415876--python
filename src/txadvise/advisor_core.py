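"""Parameter spaces, parameter vectors, advisor sets, and advising.

An advisor set is a small collection of parameter vectors learned in
advance; advising a new sample means running the assembler once per
vector and keeping the assembly the estimator scores highest.  Ties are
broken by position in the set, so placing the default vector first makes
"never worse than the default" a structural guarantee rather than a
statistical one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Callable, Iterable, Sequence

import yaml

from . import evaluation
from .errors import AdapterError, ValidationError

logger = logging.getLogger(__name__)

_NUMERIC_KINDS = ("integer", "real")
_KINDS = ("integer", "real", "boolean", "categorical")


@dataclass(frozen=True)
class ParameterSpec:
    """Declaration of one tunable assembler parameter.

    ``step`` is the coordinate-ascent move size for numeric kinds; with
    ``multiplicative`` set the move is multiply/divide by ``step`` instead
    of add/subtract (for scale-like parameters).  ``flag`` is the
    command-line flag the assembler adapter renders.
    """

    name: str
    kind: str
    default: Any
    lower: float | None = None
    upper: float | None = None
    step: float | None = None
    choices: tuple[Any, ...] | None = None
    flag: str = ""
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"parameter {self.name!r}: unknown kind {self.kind!r}")
        if self.kind in _NUMERIC_KINDS:
            if self.lower is None or self.upper is None or self.step is None:
                raise ValidationError(
                    f"parameter {self.name!r}: numeric kinds need lower/upper/step"
                )
            if self.step <= 0 or (self.multiplicative and self.step <= 1):
                raise ValidationError(f"parameter {self.name!r}: invalid step {self.step}")
            if not self.lower <= self.default <= self.upper:
                raise ValidationError(
                    f"parameter {self.name!r}: default {self.default} outside "
                    f"[{self.lower}, {self.upper}]"
                )
        elif self.kind == "categorical":
            if not self.choices:
                raise ValidationError(f"parameter {self.name!r}: categorical needs choices")
            if self.default not in self.choices:
                raise ValidationError(
                    f"parameter {self.name!r}: default {self.default!r} not in choices"
                )
        elif self.kind == "boolean" and not isinstance(self.default, bool):
            raise ValidationError(f"parameter {self.name!r}: boolean default expected")

    def check_value(self, value: Any) -> str | None:
        """Return a violation description for ``value``, or None if valid."""
        if self.kind == "integer":
            if not isinstance(value, int) or isinstance(value, bool):
                return f"{self.name}: expected integer, got {value!r}"
            if not self.lower <= value <= self.upper:
                return f"{self.name}: {value} outside [{self.lower}, {self.upper}]"
        elif self.kind == "real":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                return f"{self.name}: expected real, got {value!r}"
            if not self.lower <= value <= self.upper:
                return f"{self.name}: {value} outside [{self.lower}, {self.upper}]"
        elif self.kind == "boolean":
            if not isinstance(value, bool):
                return f"{self.name}: expected boolean, got {value!r}"
        elif self.kind == "categorical":
            if value not in self.choices:
                return f"{self.name}: {value!r} not among choices {self.choices}"
        return None


@dataclass
class ParameterVector:
    """One assignment of a value to every tunable parameter."""

    values: dict[str, Any]
    provenance: str = ""

    def key(self) -> tuple[tuple[str, Any], ...]:
        """Hashable identity of the assignment (provenance excluded)."""
        return tuple(sorted(self.values.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterVector):
            return NotImplemented
        return self.values == other.values

    def __hash__(self) -> int:
        return hash(self.key())


def default_vector(spec: Sequence[ParameterSpec]) -> ParameterVector:
    """The assembler's default parameter vector."""
    return ParameterVector({p.name: p.default for p in spec}, provenance="default")


def validate_vector(spec: Sequence[ParameterSpec], v: ParameterVector) -> list[str]:
    """All constraint violations of ``v`` under ``spec`` (empty = valid)."""
    violations: list[str] = []
    declared = {p.name for p in spec}
    for name in v.values:
        if name not in declared:
            violations.append(f"extra parameter {name!r} not declared in the space")
    for p in spec:
        if p.name not in v.values:
            violations.append(f"missing parameter {p.name!r}")
            continue
        msg = p.check_value(v.values[p.name])
        if msg is not None:
            violations.append(msg)
    return violations


@dataclass
class AdvisorSet:
    """An ordered, duplicate-free collection of parameter vectors."""

    vectors: list[ParameterVector]
    includes_default: bool = False

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValidationError("advisor set must be non-empty")
        seen = set()
        for v in self.vectors:
            if v.key() in seen:
                raise ValidationError(
                    f"advisor set contains duplicate vector ({v.provenance or 'unnamed'})"
                )
            seen.add(v.key())

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)


@dataclass
class AdvisingResult:
    chosen_vector: ParameterVector
    chosen_auc: float
    per_vector_auc: dict[int, float]
    assembly_path: Path


def advise(
    sample: str | Path,
    advisor_set: AdvisorSet,
    adapter: "AssemblerAdapter",
    ref_gtf: str | Path,
    out_dir: str | Path,
    single_exon_overlap: float = evaluation.DEFAULT_SINGLE_EXON_OVERLAP,
) -> AdvisingResult:
    """Run the assembler under every vector in the set and keep the best.

    Each invocation is independent (and could run in parallel); the
    reduction is deterministic — the argmax over scaled AUC with ties
    broken by the earliest position in the set.  A failed invocation
    excludes that vector with a warning; if every invocation fails the
    advisor raises :class:`AdapterError`.
    """
    from .gtf_io import read_gtf  # local import to avoid cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = read_gtf(ref_gtf) if not hasattr(ref_gtf, "by_chrom") else ref_gtf

    per_vector_auc: dict[int, float] = {}
    paths: dict[int, Path] = {}
    for i, v in enumerate(advisor_set):
        try:
            path = adapter.run(sample, v, out_dir)
        except AdapterError as exc:
            logger.warning("vector %d (%s) failed: %s", i, v.provenance, exc)
            continue
        per_vector_auc[i] = evaluation.auc(
            path, ref, single_exon_overlap=single_exon_overlap
        )
        paths[i] = Path(path)
    if not per_vector_auc:
        raise AdapterError("all assembler invocations failed")

    best_i = max(sorted(per_vector_auc), key=lambda i: per_vector_auc[i])
    # max() keeps the first of equal keys, so ties go to the earliest index
    return AdvisingResult(
        chosen_vector=advisor_set.vectors[best_i],
        chosen_auc=per_vector_auc[best_i],
        per_vector_auc=per_vector_auc,
        assembly_path=paths[best_i],
    )


# ---------------------------------------------------------------------------
# parameter-space declaration files (YAML) and advisor-set files (TSV)

def load_parameter_space(source: str | Path | IO[str]) -> list[ParameterSpec]:
    """Load a parameter-space declaration (YAML).

    Expected layout::

        assembler: scallop
        parameters:
          - {name: ..., kind: integer, default: 1, lower: 0, upper: 60,
             step: 5, flag: "--min_mapping_quality"}
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    entries = doc["parameters"] if isinstance(doc, dict) else doc
    specs = []
    for e in entries:
        specs.append(
            ParameterSpec(
                name=e["name"],
                kind=e["kind"],
                default=e["default"],
                lower=e.get("lower"),
                upper=e.get("upper"),
                step=e.get("step"),
                choices=tuple(e["choices"]) if e.get("choices") else None,
                flag=e.get("flag", ""),
                multiplicative=bool(e.get("multiplicative", False)),
            )
        )
    names = [p.name for p in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate parameter names in space declaration")
    return specs


def _render_value(p: ParameterSpec, value: Any) -> str:
    if p.kind == "boolean":
        return "true" if value else "false"
    if p.kind == "real":
        return repr(float(value))
    return str(value)


def _parse_value(p: ParameterSpec, text: str) -> Any:
    if p.kind == "integer":
        return int(text)
    if p.kind == "real":
        return float(text)
    if p.kind == "boolean":
        if text not in ("true", "false"):
            raise ValidationError(f"{p.name}: bad boolean literal {text!r}")
        return text == "true"
    return text


def write_advisor_set(
    s: AdvisorSet, spec: Sequence[ParameterSpec], sink: str | Path | IO[str]
) -> None:
    """Write an advisor set as TSV: provenance column + one column per parameter."""
    if isinstance(sink, (str, Path)):
        with open(sink, "wt") as fh:
            write_advisor_set(s, spec, fh)
        return
    sink.write("\t".join(["provenance"] + [p.name for p in spec]) + "\n")
    for v in s:
        row = [v.provenance] + [_render_value(p, v.values[p.name]) for p in spec]
        sink.write("\t".join(row) + "\n")


def read_advisor_set(
    source: str | Path | IO[str], spec: Sequence[ParameterSpec]
) -> AdvisorSet:
    """Read and validate an advisor-set TSV against a parameter space."""
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_advisor_set(fh, spec)
    lines = [ln.rstrip("\n") for ln in source if ln.strip()]
    if not lines:
        raise ValidationError("empty advisor-set file")
    header = lines[0].split("\t")
    if header[0] != "provenance":
        raise ValidationError("first column must be 'provenance'")
    names = header[1:]
    declared = [p.name for p in spec]
    missing = sorted(set(declared) - set(names))
    extra = sorted(set(names) - set(declared))
    if missing or extra:
        raise ValidationError(
            f"advisor-set header mismatch: missing {missing}, extra {extra}"
        )
    by_name = {p.name: p for p in spec}
    vectors = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValidationError(f"row {lineno}: expected {len(header)} columns")
        values = {
            name: _parse_value(by_name[name], cell)
            for name, cell in zip(names, cells[1:])
        }
        v = ParameterVector(values, provenance=cells[0])
        violations = validate_vector(spec, v)
        if violations:
            raise ValidationError(f"row {lineno}: " + "; ".join(violations))
        vectors.append(v)
    default = default_vector(spec)
    return AdvisorSet(
        vectors=vectors,
        includes_default=any(v == default for v in vectors),
    )
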