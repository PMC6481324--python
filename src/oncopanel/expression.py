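"""Transcriptional-silencing flag from normalized expression vs a cohort.

The motivating use-case is MLH1: MSI-H tumors without a coding MMR
alteration often silence MLH1 epigenetically, visible as sharply reduced
RNA expression relative to a reference cohort. The rule here flags a
sample whose normalized expression falls below a low percentile (default
5th) of the reference-labeled (default MSS) samples for that gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from oncopanel.errors import ParameterError

REFERENCE_LABEL = "MSS"


@dataclass(frozen=True)
class ExpressionCohort:
    """Gene x sample normalized expression with per-sample labels."""

    matrix: pd.DataFrame
    labels: pd.Series  # indexed by sample

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ParameterError("expression values must be non-negative")
        missing = set(self.matrix.columns) - set(self.labels.index)
        if missing:
            raise ParameterError(f"labels missing for samples {sorted(missing)}")


def low_expression_flag(
    gene: str,
    sample_value: float,
    cohort: ExpressionCohort,
    percentile: float = 5.0,
    reference_label: str = REFERENCE_LABEL,
) -> bool:
    """Flag iff the value is below the cohort's per-gene low percentile.

    The percentile is computed over reference-labeled samples with
    linear interpolation between order statistics (NumPy's default
    rule), which is deterministic across platforms. Requires at least
    two reference samples; ``percentile`` must lie in (0, 50].
    """
    if not 0.0 < percentile <= 50.0:
        raise ParameterError(f"percentile {percentile} outside (0, 50]")
    if gene not in cohort.matrix.index:
        raise LookupError(f"gene {gene!r} absent from cohort")
    ref_samples = cohort.labels.index[cohort.labels == reference_label]
    ref_samples = [s for s in ref_samples if s in cohort.matrix.columns]
    if len(ref_samples) < 2:
        raise ParameterError(
            f"need >= 2 reference samples, found {len(ref_samples)}"
        )
    values = cohort.matrix.loc[gene, ref_samples].to_numpy(dtype=float)
    threshold = float(np.percentile(values, percentile, method="linear"))
    return sample_value < threshold
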