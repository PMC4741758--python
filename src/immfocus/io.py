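"""Reading, validating, merging and aligning expression and clinical inputs.

The in-memory containers are plain pandas objects:

* an *expression matrix* is a ``DataFrame`` of nonnegative floats with gene
  identifiers on the index and sample identifiers on the columns (RSEM
  normalized-count scale);
* a *clinical table* is a ``DataFrame`` indexed by sample identifier with
  columns ``os_time`` (days), ``event`` (1 = death observed, 0 = censored),
  ``age`` (years), ``gender`` (``male``/``female``/``unknown``) and
  ``stage`` (``I``/``II``/``III``/``IV``/``unknown``).

TCGA Level-3 "rsem.gene.normalized_results" per-sample files and merged
tab-delimited matrices are both supported.  Gene identifiers of the form
``SYMBOL|entrezid`` are reduced to the symbol; the raw identifiers are
preserved in ``DataFrame.attrs["raw_gene_ids"]``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")
GENDERS = ("male", "female")

# header aliases accepted by read_clinical_table, lowercase
_CLINICAL_ALIASES = {
    "sample_id": ["sample_id", "sample", "bcr_patient_barcode", "patient_id",
                  "barcode", "sampleid"],
    "os_time": ["os_time", "os_days", "overall_survival_days", "time"],
    "event": ["event", "os_event", "status"],
    "vital_status": ["vital_status"],
    "days_to_death": ["days_to_death"],
    "days_to_last_followup": ["days_to_last_followup", "days_to_last_follow_up"],
    "age": ["age", "age_at_initial_pathologic_diagnosis", "age_at_diagnosis"],
    "gender": ["gender", "sex"],
    "stage": ["stage", "pathologic_stage", "ajcc_pathologic_stage",
              "ajcc_pathologic_tumor_stage", "tumor_stage"],
}


class ExpressionInputError(ValueError):
    """Raised when an expression input violates the matrix contract."""


def _canonicalize_gene_ids(raw_ids: Iterable[str]) -> tuple[list[str], dict[str, str]]:
    """Map ``SYMBOL|id`` identifiers to symbols.

    The first occurrence of a symbol wins; later collisions keep their full
    raw identifier so that the index stays unique.
    """
    seen: set[str] = set()
    canonical: list[str] = []
    raw_map: dict[str, str] = {}
    for raw in raw_ids:
        raw = str(raw).strip()
        symbol = raw.split("|", 1)[0] if "|" in raw else raw
        if not symbol or symbol == "?":
            symbol = raw
        if symbol in seen:
            symbol = raw  # collision: keep the full raw id for later duplicates
        if symbol in seen:
            raise ExpressionInputError(f"duplicated gene identifier {raw!r}")
        seen.add(symbol)
        canonical.append(symbol)
        raw_map[symbol] = raw
    return canonical, raw_map


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract, returning the (float) matrix.

    Raises :class:`ExpressionInputError` on negative entries, missing
    entries, or duplicated gene/sample identifiers, naming the offending
    coordinate.
    """
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ExpressionInputError(f"duplicated gene identifier {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ExpressionInputError(f"duplicated sample identifier {dup!r}")
    values = expr.to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ExpressionInputError(
            f"missing expression value for gene {expr.index[g]!r}, "
            f"sample {expr.columns[s]!r}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ExpressionInputError(
            f"negative expression value {values[g, s]} for gene "
            f"{expr.index[g]!r}, sample {expr.columns[s]!r}")
    out = pd.DataFrame(values, index=expr.index, columns=expr.columns)
    out.attrs = dict(expr.attrs)
    return out


def read_expression_matrix(path_or_dir: str | os.PathLike,
                           format: str = "merged_tsv") -> pd.DataFrame:
    """Load an expression matrix.

    Parameters
    ----------
    path_or_dir:
        A merged tab-delimited matrix (first column gene id, header row of
        sample ids) when ``format="merged_tsv"``; a directory of per-sample
        two-column RSEM ``*.normalized_results``-style files when
        ``format="rsem_per_sample_dir"`` (the file stem is the sample id).
    """
    path = Path(path_or_dir)
    if format == "merged_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "rsem_per_sample_dir":
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ExpressionInputError(f"no per-sample files in {path}")
        columns = {}
        reference_genes: pd.Index | None = None
        for f in files:
            col = pd.read_csv(f, sep="\t", index_col=0).iloc[:, 0]
            if reference_genes is None:
                reference_genes = col.index
            elif not col.index.equals(reference_genes):
                mism = next(iter(set(col.index) ^ set(reference_genes)))
                raise ExpressionInputError(
                    f"inconsistent gene lists across per-sample files: "
                    f"{f.name} disagrees at {mism!r}")
            columns[f.stem] = col.to_numpy()
        df = pd.DataFrame(columns, index=reference_genes)
    else:
        raise ValueError(f"unknown format {format!r}")

    canonical, raw_map = _canonicalize_gene_ids(df.index)
    df.index = pd.Index(canonical, name="gene_id")
    df.columns = df.columns.astype(str)
    df = validate_expression_matrix(df)
    df.attrs["raw_gene_ids"] = raw_map
    return df


def write_expression_matrix(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a matrix in the merged-TSV dialect accepted by the reader."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def _normalize_stage(value) -> str:
    if pd.isna(value):
        return "unknown"
    s = str(value).strip().upper()
    if s.startswith("STAGE"):
        s = s[len("STAGE"):].strip()
    for stage in ("IV", "III", "II", "I"):  # longest prefix first
        if s.startswith(stage):
            return stage
    return "unknown"


def _normalize_gender(value) -> str:
    if pd.isna(value):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    return "unknown"


def _find_column(df: pd.DataFrame, key: str) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for alias in _CLINICAL_ALIASES[key]:
        if alias in lower:
            return lower[alias]
    return None


def read_clinical_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a clinical table from TSV/CSV.

    Overall-survival time and event are taken from ``os_time``/``event``
    columns when present; otherwise they are derived from
    ``vital_status`` + ``days_to_death``/``days_to_last_followup``
    (dead -> event 1, time days_to_death; otherwise event 0, time
    days_to_last_followup).  Rows with no usable time source are dropped
    with a warning.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    sid_col = _find_column(raw, "sample_id")
    if sid_col is None:
        raise ValueError("clinical table has no recognizable sample-id column")

    os_col = _find_column(raw, "os_time")
    ev_col = _find_column(raw, "event")
    vital_col = _find_column(raw, "vital_status")
    dtd_col = _find_column(raw, "days_to_death")
    dtf_col = _find_column(raw, "days_to_last_followup")

    records = []
    n_dropped = 0
    for _, row in raw.iterrows():
        sid = str(row[sid_col]).strip()
        os_time = event = None
        if os_col is not None and ev_col is not None and pd.notna(row[os_col]):
            os_time = pd.to_numeric(row[os_col], errors="coerce")
            event = pd.to_numeric(row[ev_col], errors="coerce")
        elif vital_col is not None:
            vital = str(row[vital_col]).strip().lower()
            dead = vital in ("dead", "deceased", "1")
            source = dtd_col if dead else dtf_col
            if source is not None and pd.notna(row[source]):
                os_time = pd.to_numeric(row[source], errors="coerce")
                event = 1.0 if dead else 0.0
        if os_time is None or pd.isna(os_time) or event is None or pd.isna(event):
            n_dropped += 1
            continue
        age_col = _find_column(raw, "age")
        age = pd.to_numeric(row[age_col], errors="coerce") if age_col else np.nan
        gender_col = _find_column(raw, "gender")
        stage_col = _find_column(raw, "stage")
        records.append({
            "sample_id": sid,
            "os_time": float(os_time),
            "event": int(event),
            "age": float(age) if pd.notna(age) else np.nan,
            "gender": _normalize_gender(row[gender_col]) if gender_col else "unknown",
            "stage": _normalize_stage(row[stage_col]) if stage_col else "unknown",
        })
    if n_dropped:
        logger.warning("dropped %d clinical rows with no usable survival time",
                       n_dropped)
    clin = pd.DataFrame.from_records(records).set_index("sample_id")
    clin.attrs["n_dropped"] = n_dropped
    return validate_clinical_table(clin)


def validate_clinical_table(clin: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table contract."""
    required = {"os_time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table missing required columns {sorted(missing)}")
    if (clin["os_time"] < 0).any():
        bad = clin.index[clin["os_time"] < 0][0]
        raise ValueError(f"negative survival time for sample {bad!r}")
    if not clin["event"].isin([0, 1]).all():
        bad = clin.index[~clin["event"].isin([0, 1])][0]
        raise ValueError(f"event flag not in {{0,1}} for sample {bad!r}")
    clin = clin.copy()
    for col, default in (("age", np.nan), ("gender", "unknown"), ("stage", "unknown")):
        if col not in clin.columns:
            clin[col] = default
    allowed_stage = set(STAGES) | {"unknown"}
    if not clin["stage"].isin(allowed_stage).all():
        bad = clin.loc[~clin["stage"].isin(allowed_stage), "stage"].iloc[0]
        raise ValueError(f"stage value {bad!r} not in {sorted(allowed_stage)}")
    return clin


def _is_primary_tumor(sample_id: str) -> bool:
    """TCGA barcode rule: portion 4 starts with sample-type code 01."""
    parts = sample_id.split("-")
    if len(parts) >= 4 and len(parts[3]) >= 2 and parts[3][:2].isdigit():
        return parts[3][:2] == "01"
    return True  # non-barcode ids are kept


def align_cohort(expr: pd.DataFrame, clin: pd.DataFrame,
                 primary_tumor_only: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to their shared samples, in sorted sample order.

    With ``primary_tumor_only`` and TCGA-style barcodes, only sample-type
    code ``01`` (primary solid tumor) is retained.
    """
    expr_samples = set(expr.columns)
    clin_samples = set(clin.index)
    shared = expr_samples & clin_samples
    if primary_tumor_only:
        shared = {s for s in shared if _is_primary_tumor(s)}
    if not shared:
        raise ValueError("no shared samples between expression and clinical tables")
    order = sorted(shared)
    expr_out = expr.loc[:, order].copy()
    expr_out.attrs = dict(expr.attrs)
    clin_out = clin.loc[order].copy()
    return expr_out, clin_out


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Optional log2(x+1) transform; off by default throughout the pipeline."""
    out = np.log2(expr + 1.0)
    out.attrs = dict(expr.attrs)
    return out
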