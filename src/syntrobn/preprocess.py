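"""From raw abundance/expression/environment tables to the modeling matrix.

The modeling matrix fed to structure learning is built in a fixed order:
core-taxon selection on raw relative abundances, column-wise combination of
the retained tables, then per-variable min-max rescaling to [0, 1]
(selection thresholds always apply to raw abundances, normalization to the
assembled matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable minima and maxima for the min-max transform."""

    minimum: pd.Series
    maximum: pd.Series

    def __post_init__(self) -> None:
        if not (self.maximum >= self.minimum).all():
            raise ValueError("max < min for some variable")

    def inverse(self, normalized: FeatureTable) -> FeatureTable:
        """Map normalized values back to the original scale.

        Constant columns (max == min) normalize to 0 and invert to their
        constant value.
        """
        span = self.maximum - self.minimum
        values = normalized.values * span + self.minimum
        return FeatureTable(values, normalized.metadata)


def minmax_normalize(table: FeatureTable) -> tuple[FeatureTable, NormalizationParams]:
    """Rescale every variable to [0, 1] via (v − min) / (max − min).

    A constant column is mapped to 0 for all samples (the transform is
    undefined there; 0 matches the knockout convention of silencing to
    zero) and a warning is logged.
    """
    vmin = table.values.min(axis=0)
    vmax = table.values.max(axis=0)
    span = vmax - vmin
    constant = span == 0
    if constant.any():
        logger.warning("constant column(s) normalized to 0: %s",
                       list(span.index[constant]))
    safe_span = span.replace(0, 1.0)
    values = (table.values - vmin) / safe_span
    values.loc[:, constant] = 0.0
    return (FeatureTable(values, table.metadata),
            NormalizationParams(vmin, vmax))


def select_core_taxa(dna: FeatureTable, rna: FeatureTable | None = None,
                     min_abundance: float = 0.005,
                     min_occurrence: float = 0.5,
                     scope: str = "both") -> list[str]:
    """Taxa passing the core-population rule.

    A taxon is core when its mean relative abundance exceeds
    ``min_abundance`` (default 0.5%) *and* it occurs (abundance > 0) in
    more than ``min_occurrence`` (default 50%) of samples — strict
    inequalities on both. With ``scope='both'`` the statistics pool the DNA
    and RNA samples; ``scope='per_table'`` applies the rule within each
    table and returns taxa passing in every table given.
    """
    if scope not in ("both", "per_table"):
        raise ValueError(f"unknown scope {scope!r}")
    tables = [dna] if rna is None else [dna, rna]
    if rna is not None and set(dna.variables) != set(rna.variables):
        raise ValueError("DNA and RNA tables have mismatched taxon namespaces")

    def passes(values: pd.DataFrame) -> pd.Series:
        mean_ok = values.mean(axis=0) > min_abundance
        occ_ok = (values > 0).mean(axis=0) > min_occurrence
        return mean_ok & occ_ok

    if scope == "both":
        pooled = pd.concat([t.values[dna.variables] for t in tables], axis=0)
        mask = passes(pooled)
    else:
        mask = passes(tables[0].values)
        for t in tables[1:]:
            mask &= passes(t.values[tables[0].variables])
    return [v for v in dna.variables if mask[v]]


def compute_rpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
                 library_sizes: pd.Series) -> FeatureTable:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / ((length_bp / 1000) · (library_size / 10⁶)), per gene
    (columns) and sample (rows).
    """
    genes = list(counts.columns)
    missing = set(genes) - set(gene_lengths_bp.index)
    if missing:
        raise ValueError(f"gene length missing for {sorted(missing)}")
    missing = set(counts.index) - set(library_sizes.index)
    if missing:
        raise ValueError(f"library size missing for {sorted(missing)}")
    lengths = gene_lengths_bp[genes].astype(float)
    libs = library_sizes[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = counts.astype(float).div(lengths / 1e3, axis=1).div(libs / 1e6,
                                                               axis=0)
    from .table import default_metadata

    meta = default_metadata(genes, role="gene")
    meta["length_bp"] = lengths
    return FeatureTable(rpkm, meta)


def assemble_model_matrix(tables: list[FeatureTable],
                          variable_selection: list[str] | None = None
                          ) -> FeatureTable:
    """Column-wise combination of tables sharing the same samples.

    Sample order is canonicalized to the (sorted) shared sample IDs;
    variable names must be unique across tables. ``variable_selection``
    restricts the result to the given variables, in that order.
    """
    if not tables:
        raise ValueError("no tables given")
    id_sets = [set(t.sample_ids) for t in tables]
    shared = set.intersection(*id_sets)
    offending = sorted(set.union(*id_sets) - shared)
    if offending:
        raise ValueError(f"sample IDs not shared by all tables: {offending}")
    order = sorted(shared)
    seen: set[str] = set()
    for t in tables:
        clash = seen & set(t.variables)
        if clash:
            raise ValueError(f"variable name(s) in several tables: {sorted(clash)}")
        seen |= set(t.variables)
    values = pd.concat([t.values.loc[order] for t in tables], axis=1)
    metadata = pd.concat([t.metadata for t in tables], axis=0)
    combined = FeatureTable(values, metadata)
    if variable_selection is not None:
        combined = combined.select(list(variable_selection))
    return combined


def drop_zero_variance(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Remove columns with zero sample variance; return their names."""
    variance = table.values.var(axis=0, ddof=0)
    dropped = [v for v in table.variables if variance[v] == 0]
    if dropped:
        logger.info("dropping zero-variance column(s): %s", dropped)
    kept = [v for v in table.variables if v not in set(dropped)]
    return table.select(kept), dropped
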