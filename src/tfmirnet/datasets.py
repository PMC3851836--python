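"""Expression dataset containers and strict file readers.

Two kinds of experiment feed the network builders:

* **MPGE** (miRNA-perturbed gene expression): one miRNA is transfected into a
  cell line and per-gene expression log-ratios (after vs. before) are
  measured.  The file format is CSV: a header line, then one gene symbol and
  one log-ratio per line.
* **Parallel miRNA/mRNA expression**: two matrices over the identical ordered
  set of experimental conditions, one with miRNA rows and one with mRNA rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .names import consolidate_mirna_name

__all__ = ["MPGEDataset", "ParallelExpressionDataset"]


@dataclass(frozen=True)
class MPGEDataset:
    """Per-gene expression log-ratios from a single-miRNA perturbation.

    Parameters
    ----------
    perturbed_mirna : str
        Root-form identifier of the transfected miRNA.
    ratios : pandas.Series
        Gene symbol -> expression log-ratio (post- vs pre-transfection),
        dimensionless.  Symbols must be unique and values finite.
    """

    perturbed_mirna: str
    ratios: pd.Series

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbed_mirna", consolidate_mirna_name(self.perturbed_mirna))
        ratios = pd.Series(self.ratios, dtype=float)
        if ratios.index.has_duplicates:
            dups = ratios.index[ratios.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if len(ratios) < 2:
            raise ValueError("MPGE dataset needs at least 2 genes")
        if not np.isfinite(ratios.to_numpy()).all():
            raise ValueError("non-finite expression log-ratio")
        object.__setattr__(self, "ratios", ratios)

    @property
    def genes(self) -> pd.Index:
        return self.ratios.index

    def __len__(self) -> int:
        return len(self.ratios)

    @classmethod
    def read_csv(cls, path: str | Path, perturbed_mirna: str) -> "MPGEDataset":
        """Parse the MPGE CSV format.

        The first line is a column description and is skipped; every other
        line must contain a gene symbol and an expression log-ratio in the
        first and second comma-separated columns.
        """
        path = Path(path)
        genes: list[str] = []
        values: list[float] = []
        with path.open() as fh:
            lines = fh.readlines()
        if not lines:
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(lines[1:], start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) < 2 or not fields[0].strip():
                raise ValueError(f"{path}:{lineno}: expected 'gene,log_ratio', got {line!r}")
            try:
                value = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric log-ratio {fields[1]!r}") from None
            genes.append(fields[0].strip())
            values.append(value)
        try:
            return cls(perturbed_mirna, pd.Series(values, index=genes))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene_symbol,log_ratio\n")
            for gene, value in self.ratios.items():
                fh.write(f"{gene},{value:.10g}\n")


def _read_matrix(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


@dataclass(frozen=True)
class ParallelExpressionDataset:
    """Paired miRNA and mRNA expression matrices over shared conditions.

    Both matrices must carry the identical ordered condition columns; row
    identifiers are unique within and across the two matrices; at least three
    conditions are required for any regression to be attempted.  miRNA row
    names are consolidated to root form on construction.
    """

    mirna_matrix: pd.DataFrame
    mrna_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        mir = self.mirna_matrix.copy()
        mrna = self.mrna_matrix.copy()
        if list(mir.columns) != list(mrna.columns):
            raise ValueError("condition headers differ between miRNA and mRNA matrices")
        if mir.shape[1] < 3:
            raise ValueError("parallel dataset needs at least 3 conditions")
        mir.index = [consolidate_mirna_name(str(i)) for i in mir.index]
        if pd.Index(mir.index).has_duplicates:
            raise ValueError("duplicate miRNA rows after root-form consolidation")
        if mrna.index.has_duplicates:
            raise ValueError("duplicate mRNA rows")
        overlap = set(mir.index) & set(mrna.index)
        if overlap:
            raise ValueError(f"identifiers present in both matrices: {sorted(overlap)[:5]}")
        for name, frame in (("miRNA", mir), ("mRNA", mrna)):
            if not np.isfinite(frame.to_numpy()).all():
                raise ValueError(f"non-finite value in {name} matrix")
        object.__setattr__(self, "mirna_matrix", mir)
        object.__setattr__(self, "mrna_matrix", mrna)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.mirna_matrix.columns)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def mirnas(self) -> pd.Index:
        return self.mirna_matrix.index

    @property
    def genes(self) -> pd.Index:
        return self.mrna_matrix.index

    @classmethod
    def read(cls, mirna_path: str | Path, mrna_path: str | Path) -> "ParallelExpressionDataset":
        """Load the two matrices (TSV or CSV, autodetected by extension)."""
        return cls(_read_matrix(Path(mirna_path)), _read_matrix(Path(mrna_path)))

    def write(self, mirna_path: str | Path, mrna_path: str | Path) -> None:
        for frame, path in ((self.mirna_matrix, mirna_path), (self.mrna_matrix, mrna_path)):
            path = Path(path)
            sep = "," if path.suffix.lower() == ".csv" else "\t"
            frame.to_csv(path, sep=sep, float_format="%.10g")
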