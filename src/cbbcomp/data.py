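"""Count-table containers, I/O and design-matrix construction.

Counts live in a G x S matrix (groups are rows, samples are columns).  A
(sample, group) pair absent from an input file is *missing* — it is dropped
from the likelihood — whereas an explicit 0 is a real observation: zeros are
informative in a Beta-binomial likelihood.

Design matrices are stored C x S (one column per sample, aligned with the
count-table sample order).  Categorical covariates are expanded with
treatment coding, the reference being the first level in sorted order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "DesignMatrix",
    "read_count_table",
    "count_table_from_frame",
    "write_count_table",
    "counts_from_cell_table",
    "build_design",
    "write_results",
    "read_results",
]


@dataclass
class CountTable:
    """G x S matrix of counts with per-sample totals and covariates.

    Attributes
    ----------
    counts : (G, S) int array; entries at missing pairs are 0 placeholders.
    totals : (S,) int array, the column sums over *observed* entries.
    group_ids, sample_ids : label lists (unique, in input order).
    covariates : per-sample table indexed by sample id (may be empty).
    missing_mask : (G, S) bool array, True where the pair was absent.
    """

    counts: np.ndarray
    totals: np.ndarray
    group_ids: list
    sample_ids: list
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing_mask: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (groups x samples) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.counts.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("group labels must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample labels must be unique")
        if self.totals is None:
            self.totals = self.observed_counts().sum(axis=0)
        self.totals = np.asarray(self.totals)
        observed = self.observed_counts()
        if np.any(observed > self.totals[None, :]):
            raise ValueError("counts may not exceed per-sample totals")

    @property
    def n_groups(self):
        return self.counts.shape[0]

    @property
    def n_samples(self):
        return self.counts.shape[1]

    def observed_counts(self):
        """Counts with missing entries zeroed (for sums only)."""
        return np.where(self.missing_mask, 0, self.counts)

    def proportions(self):
        """Observed proportions k/n with NaN at missing entries."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / self.totals[None, :].astype(float)
        return np.where(self.missing_mask, np.nan, p)

    def to_frame(self):
        """Long-format DataFrame with one row per observed pair."""
        rows = []
        for gi, g in enumerate(self.group_ids):
            for si, s in enumerate(self.sample_ids):
                if self.missing_mask[gi, si]:
                    continue
                rows.append({"sample": s, "group": g,
                             "count": int(self.counts[gi, si])})
        frame = pd.DataFrame(rows, columns=["sample", "group", "count"])
        if not self.covariates.empty:
            cov = self.covariates.reset_index().rename(
                columns={self.covariates.index.name or "index": "sample"})
            frame = frame.merge(cov, on="sample", how="left")
        return frame


@dataclass
class DesignMatrix:
    """C x S covariate matrix with named rows; full row rank by contract."""

    X: np.ndarray
    row_names: list
    column_map: dict = field(default_factory=dict)
    intercept_row: int = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if len(self.row_names) != self.X.shape[0]:
            raise ValueError("row_names length must match number of rows")

    @property
    def n_coef(self):
        return self.X.shape[0]

    @property
    def n_samples(self):
        return self.X.shape[1]

    def coef_index(self, name):
        try:
            return self.row_names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient named {name!r}; "
                           f"available: {self.row_names}") from None


def _read_delimited(path, delimiter=None):
    if delimiter is not None:
        return pd.read_csv(path, sep=delimiter)
    # auto-detect comma vs tab from the header line
    if isinstance(path, io.IOBase):
        return pd.read_csv(path, sep=None, engine="python")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, encoding="utf-8")


def count_table_from_frame(frame, sample_col="sample", group_col="group",
                           count_col="count"):
    """Build a :class:`CountTable` from a long-format DataFrame.

    Columns other than the three schema columns are treated as per-sample
    covariates and must be constant within each sample.
    """
    for col in (sample_col, group_col, count_col):
        if col not in frame.columns:
            raise ValueError(f"required column {col!r} not found "
                             f"(have {list(frame.columns)})")
    counts_raw = frame[count_col]
    numeric = pd.to_numeric(counts_raw, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"count column must hold non-negative integers; offending row "
            f"{row}: {counts_raw.iloc[row]!r}")
    dup = frame.duplicated(subset=[sample_col, group_col])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate (sample, group) pair at row {row}: "
            f"({frame[sample_col].iloc[row]!r}, {frame[group_col].iloc[row]!r})")

    sample_ids = list(pd.unique(frame[sample_col]))
    group_ids = list(pd.unique(frame[group_col]))
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    g_idx = {g: i for i, g in enumerate(group_ids)}
    G, S = len(group_ids), len(sample_ids)
    counts = np.zeros((G, S), dtype=np.int64)
    missing = np.ones((G, S), dtype=bool)
    for s, g, k in zip(frame[sample_col], frame[group_col], numeric):
        counts[g_idx[g], s_idx[s]] = int(k)
        missing[g_idx[g], s_idx[s]] = False

    cov_cols = [c for c in frame.columns
                if c not in (sample_col, group_col, count_col)]
    covariates = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
    for col in cov_cols:
        per_sample = frame.groupby(sample_col, sort=False)[col].agg(
            lambda v: v.iloc[0])
        n_distinct = frame.groupby(sample_col, sort=False)[col].nunique(
            dropna=False)
        if (n_distinct > 1).any():
            offender = n_distinct[n_distinct > 1].index[0]
            raise ValueError(f"covariate {col!r} is not constant within "
                             f"sample {offender!r}")
        covariates[col] = per_sample.reindex(sample_ids).to_numpy()

    totals = np.where(missing, 0, counts).sum(axis=0)
    return CountTable(counts=counts, totals=totals, group_ids=group_ids,
                      sample_ids=sample_ids, covariates=covariates,
                      missing_mask=missing)


def read_count_table(path, sample_col="sample", group_col="group",
                     count_col="count", delimiter=None):
    """Read a long-format delimited count table (CSV/TSV auto-detected)."""
    frame = _read_delimited(path, delimiter)
    return count_table_from_frame(frame, sample_col, group_col, count_col)


def write_count_table(table, path, delimiter="\t"):
    """Write a :class:`CountTable` in long format (observed pairs only)."""
    table.to_frame().to_csv(path, sep=delimiter, index=False)


def counts_from_cell_table(path_or_frame, sample_col="sample",
                           group_col="group", delimiter=None):
    """Tally a per-cell metadata table (one row per cell) into counts."""
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = _read_delimited(path_or_frame, delimiter)
    if frame.empty:
        raise ValueError("cell table is empty")
    for col in (sample_col, group_col):
        if col not in frame.columns:
            raise ValueError(f"required column {col!r} not found")
    blank = frame[group_col].isna() | (frame[group_col].astype(str).str.strip() == "")
    if blank.any():
        rows = np.flatnonzero(blank.to_numpy()).tolist()
        raise ValueError(f"empty group label in rows {rows}")
    blank_s = frame[sample_col].isna() | (frame[sample_col].astype(str).str.strip() == "")
    if blank_s.any():
        rows = np.flatnonzero(blank_s.to_numpy()).tolist()
        raise ValueError(f"empty sample label in rows {rows}")
    tallied = (frame.groupby([sample_col, group_col], sort=False)
               .size().reset_index(name="count"))
    cov_cols = [c for c in frame.columns if c not in (sample_col, group_col)]
    if cov_cols:
        cov = frame[[sample_col] + cov_cols].drop_duplicates(subset=[sample_col])
        tallied = tallied.merge(cov, on=sample_col, how="left")
    # per-cell tallies: every (sample, group) combination that occurs is
    # observed; combinations with no cells are genuine zeros, not missing
    table = count_table_from_frame(tallied, sample_col, group_col, "count")
    table.counts = np.where(table.missing_mask, 0, table.counts)
    table.missing_mask = np.zeros_like(table.missing_mask)
    return table


def _expand_term(term, covariates, sample_ids):
    """Expand one formula term into (rows, names) on the sample axis."""
    if term not in covariates.columns:
        raise ValueError(f"covariate {term!r} not found in count table "
                         f"(available: {list(covariates.columns)})")
    values = covariates[term].reindex(sample_ids)
    if values.isna().any():
        raise ValueError(f"covariate {term!r} missing for some samples")
    if pd.api.types.is_numeric_dtype(values):
        return [values.to_numpy(dtype=float)], [term]
    levels = sorted(map(str, pd.unique(values.astype(str))))
    rows, names = [], []
    for level in levels[1:]:  # treatment coding, sorted-first reference
        rows.append((values.astype(str) == level).to_numpy(dtype=float))
        names.append(f"{term}[{level}]")
    return rows, names


def build_design(table, spec="~ 1"):
    """Build a C x S design matrix from an additive formula string.

    Supports ``~ 1 + a + b`` style additive formulas: numeric covariates
    enter as-is, categorical covariates are expanded to indicator rows with
    treatment coding (reference = first level in sorted order).  ``~ 0 + a``
    or ``~ -1 + a`` suppresses the intercept.
    """
    spec = spec.strip()
    if spec.startswith("~"):
        spec = spec[1:]
    terms = [t.strip() for t in spec.replace("-1", "+ 0 +").split("+")]
    terms = [t for t in terms if t != ""]
    intercept = True
    covar_terms = []
    for t in terms:
        if t == "1":
            continue
        if t == "0":
            intercept = False
        else:
            covar_terms.append(t)

    rows, names = [], []
    intercept_row = None
    if intercept:
        rows.append(np.ones(table.n_samples))
        names.append("(Intercept)")
        intercept_row = 0
    column_map = {}
    for term in covar_terms:
        t_rows, t_names = _expand_term(term, table.covariates, table.sample_ids)
        column_map[term] = list(range(len(rows), len(rows) + len(t_rows)))
        rows.extend(t_rows)
        names.extend(t_names)
    if not rows:
        raise ValueError("empty design: formula specifies no terms")
    X = np.vstack(rows)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[0]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[0]} "
            f"rows); aliased covariates among {names}")
    return DesignMatrix(X=X, row_names=names, column_map=column_map,
                        intercept_row=intercept_row)


_RESULT_COLUMNS = ["group", "coefficient", "kind", "effect_mean", "ci_low",
                   "ci_high", "prob_null", "fdr", "significant", "n_outliers",
                   "rhat"]


def write_results(results, path, delimiter="\t"):
    """Write a results table (one row per group x contrast) as text."""
    frame = results if isinstance(results, pd.DataFrame) else results.to_frame()
    for col in _RESULT_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[_RESULT_COLUMNS]
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.9g")


def read_results(path, delimiter="\t"):
    return pd.read_csv(path, sep=delimiter)
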