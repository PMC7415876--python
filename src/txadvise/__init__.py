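"""Parameter advising for reference-based transcript assembly.

Score candidate assemblies against a reference transcriptome with a
scaled sensitivity–precision AUC, learn advisor sets of parameter
vectors by per-sample coordinate ascent, select compact subsets, and
advise: pick, per input sample, the parameter vector whose assembly
the estimator scores highest.
"""

from importlib import resources

from .advisor_core import (
    AdvisingResult,
    AdvisorSet,
    ParameterSpec,
    ParameterVector,
    advise,
    default_vector,
    load_parameter_space,
    read_advisor_set,
    validate_vector,
    write_advisor_set,
)
from .coordinate_ascent import AscentConfig, AscentTrace, build_advisor_set, coordinate_ascent
from .errors import AdapterError, GtfParseError, TxAdviseError, ValidationError
from .evaluation import auc, match_transcripts, roc_curve
from .gtf_io import Exon, Transcript, Transcriptome, intron_chain, read_gtf, write_gtf
from .set_selection import AucMatrix, advising_score, exhaustive_subset, greedy_subsets

__version__ = "0.1.0"


def shipped_space(assembler: str):
    """Load a parameter space shipped with the package ('scallop' or 'stringtie')."""
    ref = resources.files("txadvise") / "spaces" / f"{assembler}.yaml"
    with resources.as_file(ref) as path:
        return load_parameter_space(path)


__all__ = [
    "AdapterError", "AdvisingResult", "AdvisorSet", "AscentConfig", "AscentTrace",
    "AucMatrix", "Exon", "GtfParseError", "ParameterSpec", "ParameterVector",
    "Transcript", "Transcriptome", "TxAdviseError", "ValidationError",
    "advise", "advising_score", "auc", "build_advisor_set", "coordinate_ascent",
    "default_vector", "exhaustive_subset", "greedy_subsets", "intron_chain",
    "load_parameter_space", "match_transcripts", "read_advisor_set", "read_gtf",
    "roc_curve", "shipped_space", "validate_vector", "write_advisor_set",
    "write_gtf",
]
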