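"""Expression data container and loaders.

The expression matrix is subjects x genes; gene identifiers must match
pathway node identifiers by exact string equality (no symbol mapping is
attempted).  Each subject carries a binary group label, 1 for cases and
0 for controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """Subjects x genes expression values with an aligned group vector.

    Parameters
    ----------
    values
        DataFrame indexed by subject, one column per gene.  No missing
        values are allowed; preprocessing (imputation, normalisation)
        happens upstream.
    group
        Per-subject label in {0, 1}; 1 = case, 0 = control.  Both
        groups must be non-empty.
    """

    values: pd.DataFrame
    group: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int).ravel()
        if len(self.group) != len(self.values):
            raise ValueError(
                f"group vector length {len(self.group)} does not match "
                f"{len(self.values)} subjects"
            )
        if not np.isin(self.group, (0, 1)).all():
            raise ValueError("group labels must be 0 (control) or 1 (case)")
        if (self.group == 1).sum() == 0 or (self.group == 0).sum() == 0:
            raise ValueError("both case and control groups must be non-empty")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate gene identifiers: {list(dups[:5])}")

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_cases(self) -> int:
        return int((self.group == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.group == 0).sum())

    def matrix(self, genes=None) -> np.ndarray:
        """Expression values as a float array, optionally for a gene subset."""
        df = self.values if genes is None else self.values[list(genes)]
        return df.to_numpy(dtype=float)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.group.copy())


def load_expression(data_path: str, group_path: str) -> ExpressionDataset:
    """Load expression data from TSV/CSV files.

    ``data_path``: delimited table, first column subject identifiers,
    header row of gene identifiers.  ``group_path``: one label (0/1) per
    line, in subject order; a single header line ``group`` is tolerated.
    Delimiters are sniffed from the file extension (.csv -> comma,
    otherwise tab/whitespace).
    """
    sep = "," if data_path.lower().endswith(".csv") else "\t"
    values = pd.read_csv(data_path, sep=sep, index_col=0)
    with open(group_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].lower() in ("group", "label", "class"):
        lines = lines[1:]
    try:
        group = np.array([int(x) for x in lines])
    except ValueError as exc:
        raise ValueError(f"{group_path}: group labels must be integers 0/1") from exc
    return ExpressionDataset(values, group)
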