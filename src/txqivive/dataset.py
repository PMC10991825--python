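"""Concentration-response expression dataset container.

The central in-memory object of the pipeline: a genes x samples matrix of
(log2-scale) expression values where every sample column is annotated with a
nominal exposure concentration (µM; 0 denotes the vehicle control group) and a
replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConcentrationResponseDataset"]


@dataclass
class ConcentrationResponseDataset:
    """Gene x (concentration, replicate) expression matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression values (log2 scale after normalization). Rows are genes
        (index = gene ids), columns are a two-level MultiIndex
        ``(concentration, replicate)`` with concentrations in µM.
    timepoint : str
        Label of the exposure duration (e.g. ``"day10"``).

    Invariants (checked on construction): at least 4 distinct non-control
    concentrations, every concentration has at least one replicate, no
    negative concentrations, and columns sorted by ascending concentration.
    """

    values: pd.DataFrame
    timepoint: str = ""
    _concentrations: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError(
                "values must carry a (concentration, replicate) MultiIndex"
            )
        conc = np.asarray(
            self.values.columns.get_level_values(0), dtype=float
        )
        if (conc < 0).any():
            raise ValueError("negative concentrations are not allowed")
        if not np.isfinite(conc).all():
            raise ValueError("non-finite concentration labels")
        # re-sort columns by (concentration, replicate) so downstream group
        # logic can rely on ascending order
        order = np.lexsort(
            (self.values.columns.get_level_values(1), conc)
        )
        self.values = self.values.iloc[:, order]
        conc = conc[order]
        distinct = np.unique(conc)
        if (distinct > 0).sum() < 4:
            raise ValueError(
                "need at least 4 distinct non-control concentrations, got "
                f"{(distinct > 0).sum()}"
            )
        if self.values.index.duplicated().any():
            # duplicated probe ids are legal (collapsed later by GSEA) but
            # must be disambiguated in the index for positional safety
            raise ValueError("gene index contains duplicate ids")
        self._concentrations = distinct

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def concentrations(self) -> np.ndarray:
        """Distinct nominal concentrations (µM), ascending, incl. control."""
        return self._concentrations.copy()

    @property
    def treatment_concentrations(self) -> np.ndarray:
        """Distinct non-control concentrations (µM), ascending."""
        return self._concentrations[self._concentrations > 0]

    @property
    def sample_concentrations(self) -> np.ndarray:
        """Per-column concentration labels (µM)."""
        return np.asarray(
            self.values.columns.get_level_values(0), dtype=float
        )

    def has_control(self) -> bool:
        return bool((self._concentrations == 0).any())

    def gene_values(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(concentration_per_sample, values)`` for one gene."""
        row = self.values.loc[gene_id]
        return self.sample_concentrations, row.to_numpy(dtype=float)

    def group_means(self) -> pd.DataFrame:
        """Per-gene mean expression per concentration group."""
        return self.values.T.groupby(level=0).mean().T

    def drop_concentrations(
        self, exclude: list[float]
    ) -> "ConcentrationResponseDataset":
        """Return a copy without the listed nominal concentrations."""
        exclude_arr = np.asarray(exclude, dtype=float)
        conc = self.sample_concentrations
        keep = ~np.isclose(conc[:, None], exclude_arr[None, :]).any(axis=1)
        return ConcentrationResponseDataset(
            self.values.iloc[:, keep].copy(), timepoint=self.timepoint
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConcentrationResponseDataset(n_genes={self.n_genes}, "
            f"concentrations={self._concentrations.tolist()}, "
            f"timepoint={self.timepoint!r})"
        )
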