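"""Domain data model and readers/writers for qPCR CT tables, miRNA
annotations, and sample metadata.

The central objects are :class:`CtMatrix` (raw cycle thresholds with an
amplification mask), :class:`ExpressionMatrix` (global-mean normalized
−∆CT values with a missingness mask), :class:`MirnaAnnotation` (genomic
coordinates of a miRNA locus), and :class:`SampleMetadata` (per-sample
clinical covariates and the matched-pair design).

Cycle thresholds above a configurable cutoff (default 50 cycles) are
treated as un-amplified and propagate as missing values through every
downstream statistic; no imputation is performed anywhere in the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CT values strictly greater than this are considered un-amplified.
DEFAULT_UNAMPLIFIED_CT = 50.0


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(dups)}")
    return ids


@dataclass
class CtMatrix:
    """Raw cycle-threshold matrix (samples × miRNAs) with amplification mask.

    ``ct[i, j]`` is the PCR cycle at which miRNA ``j`` crossed the
    fluorescence threshold in sample ``i``; lower CT means higher abundance.
    ``amplified[i, j]`` is False where the reaction never amplified (empty
    cell or CT above the un-amplified cutoff); such entries carry NaN in
    ``ct`` and are missing in all downstream statistics.
    """

    sample_ids: list[str]
    mirna_ids: list[str]
    ct: np.ndarray
    amplified: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA ids")
        self.ct = np.asarray(self.ct, dtype=float)
        self.amplified = np.asarray(self.amplified, dtype=bool)
        shape = (len(self.sample_ids), len(self.mirna_ids))
        if self.ct.shape != shape or self.amplified.shape != shape:
            raise ValidationError(
                f"ct/amplified shape {self.ct.shape}/{self.amplified.shape} "
                f"does not match ids {shape}"
            )
        if not np.all(np.isfinite(self.ct[self.amplified])):
            raise ValidationError("amplified entries must have finite CT values")
        # un-amplified cells are stored as NaN regardless of input value
        self.ct = np.where(self.amplified, self.ct, np.nan)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.sample_ids, columns=self.mirna_ids)


@dataclass
class ExpressionMatrix:
    """Global-mean normalized −∆CT matrix (samples × miRNAs).

    ``dct[i, j] = mean_CT(sample i, amplified) − CT[i, j]``, so higher −∆CT
    means higher expression relative to the sample's global level. By
    construction each sample's non-missing values average to zero.
    """

    sample_ids: list[str]
    mirna_ids: list[str]
    dct: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA ids")
        self.dct = np.asarray(self.dct, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.sample_ids), len(self.mirna_ids))
        if self.dct.shape != shape or self.missing.shape != shape:
            raise ValidationError("dct/missing shape does not match ids")
        self.dct = np.where(self.missing, np.nan, self.dct)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dct, index=self.sample_ids, columns=self.mirna_ids)

    def detection_counts(self) -> pd.Series:
        """Number of samples in which each miRNA was detected."""
        return pd.Series((~self.missing).sum(axis=0), index=self.mirna_ids)

    def subset_mirnas(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.mirna_ids.index(m) for m in keep]
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            mirna_ids=[self.mirna_ids[i] for i in idx],
            dct=self.dct[:, idx].copy(),
            missing=self.missing[:, idx].copy(),
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            mirna_ids=list(self.mirna_ids),
            dct=self.dct[idx, :].copy(),
            missing=self.missing[idx, :].copy(),
        )


@dataclass(frozen=True)
class MirnaAnnotation:
    """Genomic location of one miRNA (1-based inclusive coordinates)."""

    mirna_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError(f"{self.mirna_id}: empty chromosome")
        if self.start > self.end:
            raise ValidationError(
                f"{self.mirna_id}: start {self.start} > end {self.end}"
            )


TERM = "term"
PTB = "PTB"


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates for the matched term/PTB design."""

    table: pd.DataFrame

    REQUIRED = ["sample_id", "group", "pair_id"]
    OUTCOMES = ["gestational_age_birth", "birth_weight", "head_circumference"]
    COVARIATES = ["bmi", "gravida", "history_ptb", "fetal_sex"]

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        bad = set(df["group"]) - {TERM, PTB}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        counts = df["pair_id"].value_counts()
        if (counts > 2).any():
            raise ValidationError(
                f"pair_id occurring more than twice: "
                f"{sorted(counts[counts > 2].index.tolist())}"
            )
        for pid, sub in df.groupby("pair_id"):
            if len(sub) == 2 and set(sub["group"]) != {TERM, PTB}:
                raise ValidationError(
                    f"pair {pid!r} does not contain one term and one PTB member"
                )
        # label is authoritative; the 37-week rule is only sanity-checked
        if "gestational_age_birth" in df.columns:
            ga = pd.to_numeric(df["gestational_age_birth"], errors="coerce")
            implied_ptb = ga <= 37.0
            mismatch = df.loc[
                ga.notna() & (implied_ptb != (df["group"] == PTB)), "sample_id"
            ]
            if len(mismatch):
                warnings.warn(
                    "group label disagrees with the 37-week rule for samples: "
                    f"{mismatch.tolist()}",
                    stacklevel=2,
                )
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_samples(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Metadata rows reindexed to the given sample order."""
        df = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")
        return df.loc[list(sample_ids)].reset_index()


# ---------------------------------------------------------------------------
# readers / writers


def read_ct_matrix(
    path: str | Path,
    unamplified_ct: float = DEFAULT_UNAMPLIFIED_CT,
    *,
    sep: str | None = None,
    transpose: bool = False,
) -> CtMatrix:
    """Read a rectangular CT table (first column sample IDs, header miRNA IDs).

    Empty cells and cells with CT strictly greater than ``unamplified_ct``
    are marked un-amplified. ``transpose=True`` handles vendor exports with
    miRNAs in rows.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    width = len(header)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != width:
            raise ParseError(
                f"{path}: row {lineno} has {len(cells)} cells, expected {width}"
            )
        rows.append(cells)
    col_ids = [c.strip() for c in header[1:]]
    row_ids = [r[0].strip() for r in rows]
    values = np.full((len(rows), len(col_ids)), np.nan)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2}"
                ) from exc
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    amplified = np.isfinite(values) & (values <= unamplified_ct)
    return CtMatrix(
        sample_ids=row_ids, mirna_ids=col_ids, ct=values, amplified=amplified
    )


def write_ct_matrix(ct: CtMatrix, path: str | Path, *, sep: str | None = None) -> None:
    """Write a CT matrix; un-amplified cells become empty cells."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path, "w") as fh:
        fh.write(sep.join(["sample_id", *ct.mirna_ids]) + "\n")
        for i, sid in enumerate(ct.sample_ids):
            cells = [
                repr(float(ct.ct[i, j])) if ct.amplified[i, j] else ""
                for j in range(ct.n_mirnas)
            ]
            fh.write(sep.join([sid, *cells]) + "\n")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a −∆CT matrix mirroring the CT input layout (empty = missing)."""
    expr.to_frame().to_csv(path, index_label="sample_id", na_rep="")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        mirna_ids=[str(m) for m in df.columns],
        dct=values,
        missing=~np.isfinite(values),
    )


_MIRNA_FEATURE_TYPES = {"miRNA", "miRNA_primary_transcript"}


def read_annotations(
    path: str | Path,
    family_table: Mapping[str, str] | None = None,
) -> list[MirnaAnnotation]:
    """Read miRBase-style GFF3 annotations.

    One annotation is returned per feature of type ``miRNA`` or
    ``miRNA_primary_transcript`` carrying a ``Name`` attribute; features
    without a Name are skipped with a logged warning. ``family_table`` maps
    miRNA names to named-family labels (e.g. pooling the chr13 and chrX
    paralog loci of miR-17/92 into one group).
    """
    import gffutils

    family_table = dict(family_table or {})
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    annotations: list[MirnaAnnotation] = []
    for feat in db.all_features():
        if feat.featuretype not in _MIRNA_FEATURE_TYPES:
            continue
        names = feat.attributes.get("Name", [])
        if not names:
            logger.warning(
                "skipping %s feature at %s:%s-%s without Name attribute",
                feat.featuretype,
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        name = names[0]
        annotations.append(
            MirnaAnnotation(
                mirna_id=name,
                chromosome=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand or ".",
                family=family_table.get(name),
            )
        )
    return annotations


def read_family_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (mirna_id, family) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna_id", "family"])
    return dict(zip(df["mirna_id"].astype(str), df["family"].astype(str)))


def write_annotations_gff3(
    annotations: Sequence[MirnaAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.chromosome}\t.\tmiRNA_primary_transcript\t{a.start}\t{a.end}"
                f"\t.\t{a.strand}\t.\tID={a.mirna_id};Name={a.mirna_id}\n"
            )


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path)
    if "history_ptb" in df.columns:
        df["history_ptb"] = df["history_ptb"].astype(bool)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index=False)
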