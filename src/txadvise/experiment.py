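"""Learned-vs-random advisor-set comparison at desk scale.

Replays the advising experiment in miniature: for each sample, assemble
under the default vector and under every vector of an advisor set, and
report the advising ratio — advised AUC over default AUC, where a value
above 1.0 is an improvement.  Medians (not means) are the headline
summary.  All AUC values are on the x1e4 scale.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .advisor_core import AdvisorSet, ParameterSpec, advise, default_vector
from .assemblers import AssemblerAdapter

logger = logging.getLogger(__name__)


def experiment_advising_ratio(
    samples: Sequence[str | Path],
    advisor_set: AdvisorSet,
    adapter: "AssemblerAdapter",
    ref_gtf: str | Path,
    spec: Sequence[ParameterSpec],
    workdir: str | Path,
    single_exon_overlap: float = evaluation.DEFAULT_SINGLE_EXON_OVERLAP,
) -> pd.DataFrame:
    """Per-sample default AUC, advised AUC, and their ratio.

    Returns a DataFrame with columns ``sample``, ``default_auc``,
    ``advised_auc``, ``ratio`` and a ``median`` attribute in
    ``df.attrs["median_ratio"]``.  A sample whose default AUC is 0 gets a
    NaN ratio and is excluded from the median with a warning.
    """
    workdir = Path(workdir)
    default = default_vector(spec)
    rows = []
    for sample in samples:
        sample = Path(sample)
        out_dir = workdir / f"exp_{sample.stem}"
        default_path = adapter.run(sample, default, out_dir)
        default_auc = evaluation.auc(
            default_path, ref_gtf, single_exon_overlap=single_exon_overlap
        )
        result = advise(
            sample, advisor_set, adapter, ref_gtf, out_dir,
            single_exon_overlap=single_exon_overlap,
        )
        if default_auc > 0:
            ratio = result.chosen_auc / default_auc
        else:
            logger.warning(
                "sample %s: default AUC is 0, ratio undefined", sample.name
            )
            ratio = float("nan")
        rows.append({
            "sample": sample.stem,
            "default_auc": default_auc,
            "advised_auc": result.chosen_auc,
            "ratio": ratio,
        })
    df = pd.DataFrame(rows, columns=["sample", "default_auc", "advised_auc", "ratio"])
    finite = df["ratio"].dropna()
    df.attrs["median_ratio"] = float(np.median(finite)) if len(finite) else float("nan")
    return df
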