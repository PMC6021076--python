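"""Quality control and normalization of raw cycle thresholds.

Three stages: hemolysis QC (flagging plasma samples contaminated by
red-cell miRNAs via the ∆CT between a red-cell-enriched marker and a
stable reference), global-mean −∆CT normalization, and a
detection-prevalence filter that drops miRNAs observed in too few samples.

The pipeline order is normalize first (global mean over *all* amplified
miRNAs of a sample, including ones a later filter removes), then filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_types import CtMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: red-cell marker, stable reference, and flag cutoff (cycles) by convention
#: of the standard hemolysis workflow for plasma miRNA panels.
DEFAULT_RED_CELL_MIRNA = "hsa-miR-451a"
DEFAULT_REFERENCE_MIRNA = "hsa-miR-23a-3p"
DEFAULT_HEMOLYSIS_CUTOFF = 7.0
BORDERLINE_HEMOLYSIS_DELTA = 5.0

#: detection filter default: the 30-of-42 prevalence rule.
DEFAULT_MIN_DETECTED = 30
DEFAULT_MIN_DETECTED_FRACTION = 30 / 42


class ConfigurationError(ValueError):
    """A configured marker or parameter does not match the data."""


class EmptyResultError(ValueError):
    """A filter removed every miRNA."""


@dataclass
class QcReport:
    """Per-sample hemolysis assessment.

    ``hemolysis_flag`` is True/False when both marker miRNAs amplified,
    and None (indeterminate) otherwise.
    """

    sample_id: str
    hemolysis_delta: float | None
    hemolysis_flag: bool | None
    n_amplified: int
    borderline: bool = False


def hemolysis_qc(
    ct: CtMatrix,
    red_cell_mirna: str = DEFAULT_RED_CELL_MIRNA,
    reference_mirna: str = DEFAULT_REFERENCE_MIRNA,
    cutoff: float = DEFAULT_HEMOLYSIS_CUTOFF,
    borderline: float = BORDERLINE_HEMOLYSIS_DELTA,
) -> list[QcReport]:
    """Flag hemolysed samples by ∆CT = CT(reference) − CT(red-cell marker).

    A large positive delta means the red-cell miRNA is far more abundant
    than the stable reference, indicating red-cell lysis during handling.
    Flagged samples are reported, never dropped automatically.
    """
    for marker in (red_cell_mirna, reference_mirna):
        if marker not in ct.mirna_ids:
            raise ConfigurationError(f"hemolysis marker {marker!r} not in CT matrix")
    j_red = ct.mirna_ids.index(red_cell_mirna)
    j_ref = ct.mirna_ids.index(reference_mirna)
    reports = []
    for i, sid in enumerate(ct.sample_ids):
        n_amp = int(ct.amplified[i].sum())
        if not (ct.amplified[i, j_red] and ct.amplified[i, j_ref]):
            reports.append(QcReport(sid, None, None, n_amp))
            continue
        delta = float(ct.ct[i, j_ref] - ct.ct[i, j_red])
        flag = delta > cutoff
        is_borderline = (not flag) and (delta > borderline)
        if flag:
            logger.warning("sample %s flagged for hemolysis (delta %.2f)", sid, delta)
        elif is_borderline:
            logger.info("sample %s borderline hemolysis (delta %.2f)", sid, delta)
        reports.append(QcReport(sid, delta, flag, n_amp, is_borderline))
    return reports


def qc_report_frame(reports: list[QcReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "hemolysis_delta": [r.hemolysis_delta for r in reports],
            "hemolysis_flag": [
                "indeterminate" if r.hemolysis_flag is None else str(r.hemolysis_flag)
                for r in reports
            ],
            "n_amplified": [r.n_amplified for r in reports],
        }
    )


def write_qc_report(reports: list[QcReport], path: str | Path) -> None:
    qc_report_frame(reports).to_csv(path, sep="\t", index=False)


def normalize_global_mean(ct: CtMatrix) -> ExpressionMatrix:
    """Global-mean −∆CT normalization.

    For each sample ``s`` and amplified miRNA ``m``::

        dct[s, m] = mean(ct[s, amplified]) − ct[s, m]

    so a miRNA amplifying *earlier* (lower CT) than the sample's average
    gets a *positive* −∆CT. Un-amplified entries stay missing. Samples with
    fewer than two amplified miRNAs are dropped with a warning (their global
    mean would be meaningless).
    """
    n_amp = ct.amplified.sum(axis=1)
    keep = n_amp >= 2
    if not keep.all():
        dropped = [s for s, k in zip(ct.sample_ids, keep) if not k]
        logger.warning(
            "dropping %d sample(s) with <2 amplified miRNAs: %s", len(dropped), dropped
        )
    if not keep.any():
        raise ValidationError("no sample has >=2 amplified miRNAs")
    ct_vals = ct.ct[keep]
    amplified = ct.amplified[keep]
    with np.errstate(invalid="ignore"):
        sample_mean = np.nanmean(np.where(amplified, ct_vals, np.nan), axis=1)
    dct = sample_mean[:, None] - ct_vals
    return ExpressionMatrix(
        sample_ids=[s for s, k in zip(ct.sample_ids, keep) if k],
        mirna_ids=list(ct.mirna_ids),
        dct=np.where(amplified, dct, np.nan),
        missing=~amplified,
    )


def detection_filter(
    expr: ExpressionMatrix,
    min_samples: int | None = None,
    min_fraction: float | None = None,
) -> ExpressionMatrix:
    """Keep only miRNAs detected (non-missing) in at least ``min_samples``.

    ``min_fraction`` expresses the threshold as a fraction of the cohort
    size instead (ceil), for cohorts of a different size than the 42-sample
    default. Column order is preserved; the sample set is unchanged.
    """
    if min_samples is None:
        if min_fraction is not None:
            min_samples = int(np.ceil(min_fraction * expr.n_samples))
        else:
            min_samples = DEFAULT_MIN_DETECTED
    if min_samples > expr.n_samples:
        raise ValidationError(
            f"min_samples {min_samples} exceeds cohort size {expr.n_samples}"
        )
    counts = expr.detection_counts()
    keep = [m for m in expr.mirna_ids if counts[m] >= min_samples]
    if not keep:
        raise EmptyResultError(
            f"detection filter (>= {min_samples} samples) removed all miRNAs"
        )
    dropped = expr.n_mirnas - len(keep)
    if dropped:
        logger.info(
            "detection filter (>= %d/%d samples) removed %d of %d miRNAs",
            min_samples,
            expr.n_samples,
            dropped,
            expr.n_mirnas,
        )
    return expr.subset_mirnas(keep)
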