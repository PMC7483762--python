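"""Analyte-by-sample intensity matrices with per-sample experimental metadata.

The central container shared by the simulation and differential modules: a
non-negative intensity table (rows = analytes, columns = samples; NaN marks a
missing measurement) paired with a metadata table describing each sample's
cell line, treatment arm (vehicle vs drug), exposure time in hours and
replicate index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VEHICLE = "vehicle"
DRUG = "drug"

#: metadata columns every sample table must carry
REQUIRED_SAMPLE_COLUMNS = ("cell_line", "treatment", "timepoint_h", "replicate")


@dataclass
class AnalyteMatrix:
    """Intensity matrix plus sample metadata.

    Parameters
    ----------
    values
        analytes x samples DataFrame of non-negative intensities; NaN encodes
        a missing (censored) measurement.
    samples
        DataFrame indexed by sample id with at least the columns
        ``cell_line``, ``treatment`` (``vehicle``/``drug``), ``timepoint_h``
        and ``replicate``. An optional ``tech_replicate`` column marks
        technical replicates of the same biological replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = set(self.values.columns) - set(self.samples.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        bad = self.samples.loc[~self.samples["treatment"].isin([VEHICLE, DRUG])]
        if len(bad):
            raise ValueError(
                f"unknown treatment labels: {sorted(bad['treatment'].unique())}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative where present")

    # -- selection ---------------------------------------------------------

    def subset(self, **criteria) -> "AnalyteMatrix":
        """Restrict to samples whose metadata match all keyword criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        ids = self.samples.index[mask]
        keep = [c for c in self.values.columns if c in set(ids)]
        return AnalyteMatrix(self.values[keep], self.samples.loc[keep])

    def group_columns(self, cell_line, timepoint_h, treatment) -> list[str]:
        m = self.samples
        mask = (
            (m["cell_line"] == cell_line)
            & (m["timepoint_h"] == timepoint_h)
            & (m["treatment"] == treatment)
        )
        return [c for c in self.values.columns if mask.get(c, False)]

    def average_technical_replicates(self) -> "AnalyteMatrix":
        """Average technical replicates into their biological replicate.

        No-op when the metadata has no ``tech_replicate`` column.
        """
        if "tech_replicate" not in self.samples.columns:
            return self
        keys = ["cell_line", "treatment", "timepoint_h", "replicate"]
        groups = self.samples.groupby(keys, sort=False).groups
        cols, meta_rows = {}, []
        for key, ids in groups.items():
            ids = list(ids)
            new_id = ids[0]
            cols[new_id] = self.values[ids].mean(axis=1)
            row = self.samples.loc[new_id].drop(labels=["tech_replicate"])
            meta_rows.append(row.rename(new_id))
        values = pd.DataFrame(cols)
        values.index = self.values.index
        return AnalyteMatrix(values, pd.DataFrame(meta_rows))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path, samples_path) -> None:
        out = self.values.copy()
        out.index.name = "analyte"
        out.to_csv(matrix_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path) -> "AnalyteMatrix":
        values = pd.read_csv(Path(matrix_path), sep="\t", index_col=0)
        samples = pd.read_csv(Path(samples_path), sep="\t", index_col=0)
        extra = set(values.columns) - set(samples.index)
        if extra:
            warnings.warn(f"dropping {len(extra)} samples without metadata")
            values = values.drop(columns=sorted(extra))
        return cls(values, samples.loc[list(values.columns)])


def strata(samples: pd.DataFrame) -> list[tuple]:
    """All (cell_line, timepoint_h) combinations present in a sample table."""
    pairs = samples[["cell_line", "timepoint_h"]].drop_duplicates()
    return [tuple(r) for r in pairs.itertuples(index=False)]
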