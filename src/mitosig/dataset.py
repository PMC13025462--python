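"""Data model and file I/O for aptamer-proteomics RFU matrices.

The central container is :class:`ExpressionDataset`: a samples x analytes
matrix of relative fluorescence units (RFU) from a SomaScan-style assay,
together with per-analyte annotations (SeqId, gene symbol, mitochondrial
flag) and per-sample clinical metadata (tumor subtype, metastatic status,
prior therapy, IMDC risk, sarcomatoid/rhabdoid features, overall survival).

Two text formats are supported:

* a minimal ADAT dialect -- caret-prefixed section markers, tab delimiters,
  bang-prefixed header keys (``read_adat`` / ``write_adat``);
* a triple of plain TSV tables -- matrix, sample metadata, analyte metadata
  (``read_tsv_dataset`` / ``write_tsv_dataset``).

Cross-assay harmonization (11K -> 7K signal space) is a per-analyte
multiplicative rescaling by vendor-provided bridging scalars; analytes
without a scalar are dropped and the drop count is recorded in the dataset
provenance rather than silently passed through unscaled.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "ParseError",
    "ExpressionDataset",
    "BridgingTable",
    "read_adat",
    "write_adat",
    "read_tsv_dataset",
    "write_tsv_dataset",
    "read_bridging_table",
    "write_bridging_table",
    "read_gene_list",
    "flag_mitochondrial",
    "log2_transform",
    "harmonize",
    "restrict_to_flag",
    "SUBTYPES",
    "IMDC_LEVELS",
]

SUBTYPES = ("ChRCC", "ccRCC")
IMDC_LEVELS = ("favorable", "intermediate", "poor", "not_applicable", "missing")

SAMPLE_META_COLUMNS = (
    "subtype",
    "metastatic",
    "prior_therapy",
    "imdc",
    "sarcomatoid_rhabdoid",
    "os_time",
    "os_event",
)
ANALYTE_META_COLUMNS = ("gene_symbol", "protein_name", "is_mitochondrial")


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class ParseError(DatasetError):
    """Raised when a file cannot be parsed; the message names the line."""


class ExpressionDataset:
    """Samples x analytes RFU matrix with annotations and clinical metadata.

    Parameters
    ----------
    rfu : pandas.DataFrame
        Numeric matrix, index = sample ids, columns = SeqIds.  Strictly
        positive when ``scale == "raw"``; any real value on the log2 scale.
    analytes : pandas.DataFrame
        Indexed by SeqId; columns ``gene_symbol``, ``protein_name``,
        ``is_mitochondrial``.
    samples : pandas.DataFrame
        Indexed by sample id; columns ``subtype``, ``metastatic``,
        ``prior_therapy``, ``imdc``, ``sarcomatoid_rhabdoid``, ``os_time``
        (months, NaN if unknown) and ``os_event`` (0/1, NaN if unknown).
    scale : {"raw", "log2"}
    provenance : list of dict, optional
        Structured record of the operations applied so far.
    """

    def __init__(self, rfu, analytes, samples, scale="raw", provenance=None, validate=True):
        self.rfu = rfu
        self.analytes = analytes
        self.samples = samples
        self.scale = scale
        self.provenance = list(provenance) if provenance else []
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self):
        if self.scale not in ("raw", "log2"):
            raise DatasetError(f"unknown scale flag {self.scale!r}")
        if not self.rfu.columns.equals(self.analytes.index):
            raise DatasetError("matrix columns do not match analyte annotation index")
        if not self.rfu.index.equals(self.samples.index):
            raise DatasetError("matrix rows do not match sample metadata index")
        if self.rfu.columns.has_duplicates:
            dups = self.rfu.columns[self.rfu.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate SeqIds: {dups}")
        if self.rfu.index.has_duplicates:
            dups = self.rfu.index[self.rfu.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample ids: {dups}")
        values = self.rfu.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DatasetError("RFU matrix contains non-numeric values")
        bad = ~np.isfinite(values)
        if self.scale == "raw":
            bad |= values <= 0
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"invalid RFU for sample {self.rfu.index[i]!r}, analyte "
                f"{self.rfu.columns[j]!r}: {values[i, j]!r} "
                f"(cells must be finite{' and > 0' if self.scale == 'raw' else ''})"
            )
        missing = [c for c in ANALYTE_META_COLUMNS if c not in self.analytes.columns]
        if missing:
            raise DatasetError(f"analyte annotation missing columns: {missing}")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DatasetError(f"sample metadata missing columns: {missing}")
        bad_subtype = ~self.samples["subtype"].isin(SUBTYPES)
        if bad_subtype.any():
            raise DatasetError(
                "subtype must be one of %s for every sample; offending samples: %s"
                % (SUBTYPES, list(self.samples.index[bad_subtype]))
            )
        bad_imdc = ~self.samples["imdc"].isin(IMDC_LEVELS)
        if bad_imdc.any():
            raise DatasetError(
                "imdc must be one of %s; offending samples: %s"
                % (IMDC_LEVELS, list(self.samples.index[bad_imdc]))
            )
        t_na = self.samples["os_time"].isna()
        e_na = self.samples["os_event"].isna()
        mismatched = t_na != e_na
        if mismatched.any():
            raise DatasetError(
                "os_event must be present iff os_time is present; offending "
                f"samples: {list(self.samples.index[mismatched])}"
            )
        t = self.samples["os_time"]
        if (t.dropna() < 0).any():
            raise DatasetError("os_time must be >= 0")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self):
        return self.rfu.shape[0]

    @property
    def n_analytes(self):
        return self.rfu.shape[1]

    @property
    def seq_ids(self):
        return list(self.rfu.columns)

    @property
    def sample_ids(self):
        return list(self.rfu.index)

    def __repr__(self):
        return (
            f"<ExpressionDataset {self.n_samples} samples x {self.n_analytes} "
            f"analytes, scale={self.scale}>"
        )

    def copy(self):
        return ExpressionDataset(
            self.rfu.copy(), self.analytes.copy(), self.samples.copy(),
            scale=self.scale, provenance=list(self.provenance), validate=False,
        )

    def equals(self, other, rtol=1e-9):
        """Approximate equality: exact metadata, numeric matrix to ``rtol``."""
        return (
            self.scale == other.scale
            and self.rfu.index.equals(other.rfu.index)
            and self.rfu.columns.equals(other.rfu.columns)
            and np.allclose(self.rfu.to_numpy(), other.rfu.to_numpy(), rtol=rtol, atol=0)
            and self.analytes.equals(other.analytes)
            and _samples_equal(self.samples, other.samples)
        )

    def subset_samples(self, ids_or_mask):
        """Return a dataset restricted to the given sample ids / boolean mask."""
        sub_rfu = self.rfu.loc[ids_or_mask]
        sub_samples = self.samples.loc[sub_rfu.index]
        return ExpressionDataset(
            sub_rfu, self.analytes.copy(), sub_samples, scale=self.scale,
            provenance=self.provenance + [{"op": "subset_samples", "n": len(sub_rfu)}],
            validate=False,
        )

    # -- transforms (also available as module-level functions) --------------

    def log2(self):
        return log2_transform(self)

    def harmonize(self, bridging):
        return harmonize(self, bridging)

    def restrict_to_flag(self, flag="is_mitochondrial"):
        return restrict_to_flag(self, flag)


def _samples_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if not a.index.equals(b.index):
        return False
    for col in SAMPLE_META_COLUMNS:
        if col in ("os_time", "os_event"):
            xa, xb = a[col].astype(float), b[col].astype(float)
            if not ((xa.isna() == xb.isna()).all() and
                    np.allclose(xa.dropna(), xb.dropna(), rtol=1e-9, atol=1e-12)):
                return False
        else:
            if not (a[col] == b[col]).all():
                return False
    return True


# ---------------------------------------------------------------------------
# transforms


def log2_transform(dataset: ExpressionDataset) -> ExpressionDataset:
    """Replace every RFU cell by its base-2 logarithm.

    Raises
    ------
    DatasetError
        If the dataset is already on the log2 scale (no double transform).
    """
    if dataset.scale != "raw":
        raise DatasetError("dataset is already log2-transformed")
    out = dataset.rfu.apply(np.log2)
    return ExpressionDataset(
        out, dataset.analytes.copy(), dataset.samples.copy(), scale="log2",
        provenance=dataset.provenance + [{"op": "log2_transform"}], validate=False,
    )


def harmonize(dataset: ExpressionDataset, bridging: "BridgingTable") -> ExpressionDataset:
    """Rescale each analyte's RFU by its bridging scalar (11K -> 7K space).

    Analytes absent from the bridging table are dropped; the drop count is
    recorded as ``{"op": "harmonize", "n_scaled": ..., "n_dropped": ...}`` in
    the provenance of the returned dataset.
    """
    if dataset.scale != "raw":
        raise DatasetError("harmonization applies to raw RFU, not log2 data")
    keep = [s for s in dataset.rfu.columns if s in bridging]
    if not keep:
        raise DatasetError("no analyte in the dataset has a bridging scalar")
    n_dropped = dataset.n_analytes - len(keep)
    scalars = bridging.scalars.loc[keep]
    rfu = dataset.rfu.loc[:, keep] * scalars
    return ExpressionDataset(
        rfu, dataset.analytes.loc[keep].copy(), dataset.samples.copy(), scale="raw",
        provenance=dataset.provenance
        + [{"op": "harmonize", "n_scaled": len(keep), "n_dropped": n_dropped}],
        validate=False,
    )


def restrict_to_flag(dataset: ExpressionDataset, flag: str = "is_mitochondrial") -> ExpressionDataset:
    """Reduce the analyte set to those carrying a boolean annotation flag."""
    if flag not in dataset.analytes.columns:
        raise DatasetError(f"no analyte annotation column {flag!r}")
    mask = dataset.analytes[flag].astype(bool)
    if not mask.any():
        raise DatasetError(f"no analyte carries the flag {flag!r}")
    keep = dataset.analytes.index[mask]
    return ExpressionDataset(
        dataset.rfu.loc[:, keep], dataset.analytes.loc[keep].copy(),
        dataset.samples.copy(), scale=dataset.scale,
        provenance=dataset.provenance
        + [{"op": "restrict_to_flag", "flag": flag, "n_kept": int(mask.sum())}],
        validate=False,
    )


# ---------------------------------------------------------------------------
# bridging table


class BridgingTable:
    """Mapping SeqId -> strictly positive multiplicative bridging scalar."""

    def __init__(self, scalars):
        if isinstance(scalars, dict):
            scalars = pd.Series(scalars, dtype=float)
        scalars = scalars.astype(float).rename_axis("seq_id")
        if scalars.index.has_duplicates:
            raise DatasetError("duplicate SeqIds in bridging table")
        bad = ~np.isfinite(scalars.to_numpy()) | (scalars.to_numpy() <= 0)
        if bad.any():
            raise DatasetError(
                f"bridging scalars must be strictly positive; offending SeqIds: "
                f"{list(scalars.index[bad])}"
            )
        self.scalars = scalars

    def __contains__(self, seq_id):
        return seq_id in self.scalars.index

    def __len__(self):
        return len(self.scalars)

    def __getitem__(self, seq_id):
        return float(self.scalars[seq_id])


def read_bridging_table(path) -> BridgingTable:
    """Read a two-column TSV ``seq_id <tab> scalar`` (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: bridging table must have exactly 2 columns")
    if df.iloc[0, 0] in ("seq_id", "SeqId"):
        df = df.iloc[1:]
    try:
        scalars = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=df.iloc[:, 0])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric bridging scalar ({exc})") from exc
    return BridgingTable(scalars)


def write_bridging_table(table: BridgingTable, path):
    with open(path, "w") as fh:
        fh.write("seq_id\tscalar\n")
        for seq_id, scalar in table.scalars.items():
            fh.write(f"{seq_id}\t{scalar:.12g}\n")


def read_gene_list(path):
    """One gene symbol per line (blank lines and ``#`` comments skipped)."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line.upper())
    return symbols


def flag_mitochondrial(dataset: ExpressionDataset, symbols: Iterable[str]) -> ExpressionDataset:
    """Set ``is_mitochondrial`` from a list of gene symbols (case-insensitive)."""
    symbol_set = {s.upper() for s in symbols}
    analytes = dataset.analytes.copy()
    analytes["is_mitochondrial"] = (
        analytes["gene_symbol"].astype(str).str.upper().isin(symbol_set)
    )
    return ExpressionDataset(
        dataset.rfu, analytes, dataset.samples, scale=dataset.scale,
        provenance=dataset.provenance
        + [{"op": "flag_mitochondrial", "n_flagged": int(analytes["is_mitochondrial"].sum())}],
        validate=False,
    )


# ---------------------------------------------------------------------------
# minimal ADAT dialect
#
# ^HEADER          -- !Key <tab> Value lines (requires !Scale)
# ^COL_DATA        -- one line per analyte annotation field, first cell the
#                     field name (SeqId, GeneSymbol, ProteinName,
#                     IsMitochondrial), remaining cells one per analyte
# ^ROW_DATA        -- single line naming the per-sample metadata columns
# ^TABLE_BEGIN     -- one line per sample: metadata cells then RFU cells

_ROW_FIELDS = (
    "SampleId", "Subtype", "Metastatic", "PriorTherapy", "IMDC",
    "SarcomatoidRhabdoid", "OSTimeMonths", "OSEvent",
)


def write_adat(dataset: ExpressionDataset, path):
    """Write the minimal ADAT dialect (lossless to <=1e-9 relative)."""
    a = dataset.analytes
    s = dataset.samples
    with open(path, "w") as fh:
        fh.write("^HEADER\n")
        fh.write("!Format\tmitosig-adat-mini-1\n")
        fh.write(f"!Scale\t{dataset.scale}\n")
        fh.write("^COL_DATA\n")
        fh.write("SeqId\t" + "\t".join(str(x) for x in a.index) + "\n")
        fh.write("GeneSymbol\t" + "\t".join(str(x) for x in a["gene_symbol"]) + "\n")
        fh.write("ProteinName\t" + "\t".join(str(x) for x in a["protein_name"]) + "\n")
        fh.write("IsMitochondrial\t" + "\t".join(
            str(int(bool(x))) for x in a["is_mitochondrial"]) + "\n")
        fh.write("^ROW_DATA\n")
        fh.write("\t".join(_ROW_FIELDS) + "\n")
        fh.write("^TABLE_BEGIN\n")
        values = dataset.rfu.to_numpy()
        for i, sid in enumerate(dataset.rfu.index):
            row = s.loc[sid]
            t = "NA" if pd.isna(row["os_time"]) else f"{float(row['os_time']):.12g}"
            e = "NA" if pd.isna(row["os_event"]) else str(int(row["os_event"]))
            meta = [
                str(sid), str(row["subtype"]), str(int(bool(row["metastatic"]))),
                str(int(bool(row["prior_therapy"]))), str(row["imdc"]),
                str(int(bool(row["sarcomatoid_rhabdoid"]))), t, e,
            ]
            fh.write("\t".join(meta + [f"{v:.12g}" for v in values[i]]) + "\n")


def read_adat(path) -> ExpressionDataset:
    """Parse the minimal ADAT dialect into an :class:`ExpressionDataset`."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    def err(lineno, msg):
        raise ParseError(f"{path}, line {lineno}: {msg}")

    section = None
    header = {}
    col_data = {}
    row_fields = None
    table_start = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("^"):
            section = line.strip()
            if section not in ("^HEADER", "^COL_DATA", "^ROW_DATA", "^TABLE_BEGIN"):
                err(lineno, f"unknown section marker {section!r}")
            if section == "^TABLE_BEGIN":
                table_start = lineno
                break
            continue
        if section == "^HEADER":
            if not line.startswith("!"):
                err(lineno, "header lines must start with '!'")
            parts = line[1:].split("\t")
            if len(parts) != 2:
                err(lineno, "header line must be '!Key<TAB>Value'")
            header[parts[0]] = parts[1]
        elif section == "^COL_DATA":
            parts = line.split("\t")
            col_data[parts[0]] = parts[1:]
        elif section == "^ROW_DATA":
            row_fields = tuple(line.split("\t"))
        elif section is None:
            err(lineno, "content before any section marker")
    if table_start is None:
        raise ParseError(f"{path}: missing ^TABLE_BEGIN section")
    if "Scale" not in header:
        raise ParseError(f"{path}: header lacks !Scale")
    scale = header["Scale"]
    for field in ("SeqId", "GeneSymbol"):
        if field not in col_data:
            raise ParseError(f"{path}: ^COL_DATA lacks required field {field}")
    if row_fields != _ROW_FIELDS:
        raise ParseError(
            f"{path}: ^ROW_DATA must name fields {list(_ROW_FIELDS)}, got {row_fields}"
        )

    seq_ids = col_data["SeqId"]
    n_analytes = len(seq_ids)
    for field, vals in col_data.items():
        if len(vals) != n_analytes:
            raise ParseError(
                f"{path}: ^COL_DATA field {field} has {len(vals)} entries, "
                f"expected {n_analytes}"
            )
    analytes = pd.DataFrame(
        {
            "gene_symbol": col_data["GeneSymbol"],
            "protein_name": col_data.get("ProteinName", [""] * n_analytes),
            "is_mitochondrial": [
                bool(int(v)) for v in col_data.get("IsMitochondrial", ["0"] * n_analytes)
            ],
        },
        index=pd.Index(seq_ids, name="seq_id"),
    )

    meta_rows, rfu_rows, sample_ids = [], [], []
    n_meta = len(_ROW_FIELDS)
    for lineno, line in enumerate(lines[table_start:], start=table_start + 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_meta + n_analytes:
            err(lineno, f"expected {n_meta + n_analytes} cells, found {len(cells)}")
        sid = cells[0]
        try:
            meta_rows.append(_parse_sample_meta(cells))
        except ValueError as exc:
            err(lineno, str(exc))
        row = np.empty(n_analytes)
        for j, cell in enumerate(cells[n_meta:]):
            try:
                v = float(cell)
            except ValueError:
                raise DatasetError(
                    f"{path}, line {lineno}: non-numeric RFU for sample {sid!r}, "
                    f"analyte {seq_ids[j]!r}: {cell!r}"
                ) from None
            if not math.isfinite(v) or (scale == "raw" and v <= 0):
                raise DatasetError(
                    f"{path}, line {lineno}: invalid RFU for sample {sid!r}, "
                    f"analyte {seq_ids[j]!r}: {cell!r}"
                )
            row[j] = v
        rfu_rows.append(row)
        sample_ids.append(sid)

    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    rfu = pd.DataFrame(
        np.asarray(rfu_rows), index=samples.index,
        columns=pd.Index(seq_ids, name="seq_id"),
    )
    return ExpressionDataset(rfu, analytes, samples, scale=scale,
                             provenance=[{"op": "read_adat", "path": str(path)}])


def _parse_sample_meta(cells: Sequence[str]) -> dict:
    t = np.nan if cells[6] in ("NA", "") else float(cells[6])
    e = np.nan if cells[7] in ("NA", "") else float(int(cells[7]))
    return {
        "subtype": cells[1],
        "metastatic": bool(int(cells[2])),
        "prior_therapy": bool(int(cells[3])),
        "imdc": cells[4],
        "sarcomatoid_rhabdoid": bool(int(cells[5])),
        "os_time": t,
        "os_event": e,
    }


# ---------------------------------------------------------------------------
# TSV triple


def write_tsv_dataset(dataset: ExpressionDataset, matrix_path, sample_meta_path,
                      analyte_meta_path):
    rfu = dataset.rfu.copy()
    rfu.index.name = "sample_id"
    rfu.to_csv(matrix_path, sep="\t", float_format="%.12g")
    s = dataset.samples.copy()
    s.index.name = "sample_id"
    s = s.assign(
        metastatic=s["metastatic"].astype(int),
        prior_therapy=s["prior_therapy"].astype(int),
        sarcomatoid_rhabdoid=s["sarcomatoid_rhabdoid"].astype(int),
    )
    s.to_csv(sample_meta_path, sep="\t", float_format="%.12g", na_rep="NA")
    a = dataset.analytes.copy()
    a.index.name = "seq_id"
    a = a.assign(is_mitochondrial=a["is_mitochondrial"].astype(int))
    a.to_csv(analyte_meta_path, sep="\t")


def read_tsv_dataset(matrix_path, sample_meta_path, analyte_meta_path,
                     scale="raw") -> ExpressionDataset:
    """Assemble a dataset from matrix + sample metadata + analyte metadata TSVs.

    The sample and analyte orders of the returned dataset follow the two
    metadata tables; the matrix may list them in any order but must contain
    exactly the same keys.  The TSV triple does not record the scale, so pass
    ``scale="log2"`` when the matrix holds log2 intensities.
    """
    rfu = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    samples = pd.read_csv(sample_meta_path, sep="\t", index_col="sample_id",
                          na_values=["NA"], keep_default_na=True)
    analytes = pd.read_csv(analyte_meta_path, sep="\t", index_col="seq_id",
                           keep_default_na=False)

    matrix_samples, meta_samples = set(rfu.index), set(samples.index)
    matrix_analytes, meta_analytes = set(rfu.columns), set(analytes.index)
    problems = []
    if matrix_samples - meta_samples:
        problems.append(
            f"samples in matrix but not in metadata: {sorted(matrix_samples - meta_samples)}")
    if meta_samples - matrix_samples:
        problems.append(
            f"samples in metadata but not in matrix: {sorted(meta_samples - matrix_samples)}")
    if matrix_analytes - meta_analytes:
        problems.append(
            f"analytes in matrix but not in metadata: {sorted(matrix_analytes - meta_analytes)}")
    if meta_analytes - matrix_analytes:
        problems.append(
            f"analytes in metadata but not in matrix: {sorted(meta_analytes - matrix_analytes)}")
    if problems:
        raise DatasetError("key mismatch across TSV tables: " + "; ".join(problems))

    rfu = rfu.loc[samples.index, analytes.index]
    rfu.columns.name = "seq_id"
    samples = samples.assign(
        metastatic=samples["metastatic"].astype(int).astype(bool),
        prior_therapy=samples["prior_therapy"].astype(int).astype(bool),
        sarcomatoid_rhabdoid=samples["sarcomatoid_rhabdoid"].astype(int).astype(bool),
        os_time=samples["os_time"].astype(float),
        os_event=samples["os_event"].astype(float),
    )
    analytes = analytes.assign(
        is_mitochondrial=analytes["is_mitochondrial"].astype(int).astype(bool),
        gene_symbol=analytes["gene_symbol"].astype(str),
        protein_name=analytes["protein_name"].astype(str),
    )
    return ExpressionDataset(rfu, analytes, samples, scale=scale,
                             provenance=[{"op": "read_tsv_dataset", "path": str(matrix_path)}])
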