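"""Expression preprocessing: probe collapsing, scale detection, fold changes.

Heterogeneous microarray matrices (typically GEO Series Matrix files from
different platforms) are cast to one common representation: linear-scale
fold change of each gene relative to the mean expression of the healthy
control samples *of the same dataset*.  This within-dataset normalization is
the only integration step; by construction the fold change of a control
sample averages to one, which puts every dataset on the same scale without
explicit batch correction.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ["sample_id", "class_label", "dataset_id", "is_control"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_series_matrix(path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read a GEO Series Matrix text file.

    Returns ``(matrix, metadata)`` where ``matrix`` is probes x samples and
    ``metadata`` maps the ``!``-prefixed header keys to their value lists.
    Only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is treated as data.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
            elif line.startswith("!series_matrix_table_end"):
                in_table = False
            elif in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                meta.setdefault(key, []).extend(values)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix_table_begin/end block found")
    df = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    return df, meta


def read_matrix_tsv(path) -> pd.DataFrame:
    """Genes-as-rows TSV with a header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, class_label, dataset_id, is_control."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    sheet = sheet.copy()
    sheet["is_control"] = sheet["is_control"].astype(bool)
    for ds, sub in sheet.groupby("dataset_id"):
        if not sub["is_control"].any():
            raise ValueError(f"dataset {ds!r} has no control samples")
    return sheet


def read_probe_map(path) -> pd.Series:
    """Probe map TSV (probe_id, gene_id) -> Series indexed by probe."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(pm.iloc[:, 1].values, index=pm.iloc[:, 0].values)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def collapse_probes(probe_matrix: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """Average multiple probe sets of a gene; drop unmapped probes.

    ``probe_to_gene`` is a mapping (dict or Series) from probe id to gene id.
    """
    probe_to_gene = pd.Series(dict(probe_to_gene)) if not isinstance(
        probe_to_gene, pd.Series
    ) else probe_to_gene
    mapped = probe_matrix.index.intersection(probe_to_gene.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix matches the probe->gene map")
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probe(s)", n_dropped)
    sub = probe_matrix.loc[mapped]
    genes = probe_to_gene.loc[mapped]
    collapsed = sub.groupby(genes.values).mean()
    collapsed.index.name = "gene_id"
    return collapsed.sort_index()


def detect_scale(matrix: pd.DataFrame) -> str:
    """Quantile heuristic deciding whether a matrix is already linear.

    The matrix is declared linear if its 99th percentile exceeds 100, or if
    its range exceeds 50 with a strictly positive lower quartile; otherwise
    it is taken to be log2 intensity.  This mirrors the quantile autocheck
    commonly used when reprocessing public array data.
    """
    x = matrix.to_numpy(dtype=float).ravel()
    q0, q25, q99, q100 = np.quantile(x, [0.0, 0.25, 0.99, 1.0])
    if q99 > 100 or ((q100 - q0) > 50 and q25 > 0):
        return "linear"
    return "log2"


def detect_and_linearize(
    matrix: pd.DataFrame, transform: str = "auto"
) -> tuple[pd.DataFrame, str]:
    """Bring an expression matrix to linear scale.

    ``transform`` is ``auto`` (quantile heuristic), or an explicit ``linear``,
    ``log2`` or ``log10``.  Returns ``(linear_matrix, decision)``.
    """
    if transform == "auto":
        decision = detect_scale(matrix)
    elif transform in ("linear", "log2", "log10"):
        decision = transform
    else:
        raise ValueError(f"unknown transform {transform!r}")

    if decision == "linear":
        if (matrix.to_numpy() < 0).any():
            raise ValueError(
                "matrix declared linear contains negative intensities"
            )
        out = matrix
    elif decision == "log2":
        out = np.power(2.0, matrix)
    else:  # log10
        out = np.power(10.0, matrix)
    logger.info("scale decision: %s", decision)
    return out, decision


def compute_fold_change(
    matrix: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene fold change versus the in-dataset control mean.

    ``matrix`` holds linear-scale expression (genes x samples); samples are
    grouped by ``dataset_id`` in the sheet and each is divided by the mean of
    that dataset's control samples.  Genes whose control mean is zero in a
    dataset are dropped (with a warning) from the output.
    """
    sheet = validate_sample_sheet(sheet)
    sheet = sheet[sheet["sample_id"].isin(matrix.columns)]
    if sheet.empty:
        raise ValueError("no sample sheet entry matches the matrix columns")

    blocks = []
    for ds, sub in sheet.groupby("dataset_id", sort=True):
        ctrl = sub.loc[sub["is_control"], "sample_id"].tolist()
        if not ctrl:
            raise ValueError(f"dataset {ds!r} has no control samples in matrix")
        block = matrix[sub["sample_id"].tolist()]
        ctrl_mean = block[ctrl].mean(axis=1)
        zero = ctrl_mean <= 0
        if zero.any():
            logger.warning(
                "dataset %s: dropping %d gene(s) with non-positive control mean",
                ds, int(zero.sum()),
            )
        fc = block.loc[~zero].div(ctrl_mean[~zero], axis=0)
        blocks.append(fc)

    # integrate datasets on their shared gene set
    out = pd.concat(blocks, axis=1, join="inner")
    return out[[s for s in matrix.columns if s in out.columns]]
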