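"""Sample-by-variable feature tables with per-variable metadata.

The :class:`FeatureTable` is the currency of the whole pipeline: taxon
relative abundances (16S rRNA gene, "DNA"), taxon activities (16S rRNA,
"RNA"), gene expression (RPKM per MAG-derived functional gene) and
environmental/performance variables are all carried in the same structure —
a numeric matrix (samples in rows) plus a metadata record per variable.

Metadata fields
---------------
role
    One of ``taxon_dna``, ``taxon_rna``, ``gene``, ``environment``,
    ``output``.
tier
    Position in the inference ordering used to constrain network learning:
    ``fermenter``, ``geobacter``, ``methanogen``, ``environment`` or
    ``output``.
mechanism
    Electron-transfer mechanism label for gene variables: ``IHT``
    (interspecies hydrogen transfer), ``DIET`` (direct interspecies
    electron transfer) or ``other``.
length_bp
    Optional transcript length in base pairs (genes only), used by RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("taxon_dna", "taxon_rna", "gene", "environment", "output")
TIERS = ("fermenter", "geobacter", "methanogen", "environment", "output")
MECHANISMS = ("IHT", "DIET", "other")

#: Columns of the sidecar metadata table, in on-disk order.
METADATA_COLUMNS = ("variable", "role", "tier", "mechanism", "length_bp")


@dataclass
class FeatureTable:
    """Numeric samples × variables matrix with per-variable metadata.

    Parameters
    ----------
    values
        DataFrame with sample IDs as index and variable names as columns.
        All entries must be finite floats.
    metadata
        DataFrame indexed by variable name with columns ``role``, ``tier``,
        ``mechanism`` and optionally ``length_bp``. Must cover exactly the
        variables of ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.metadata is None:
            self.metadata = default_metadata(list(self.values.columns))
        self.metadata = self.metadata.copy()
        if "length_bp" not in self.metadata.columns:
            self.metadata["length_bp"] = np.nan
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        cols = list(self.values.columns)
        idx = list(self.values.index)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if len(set(idx)) != len(idx):
            dupes = sorted({str(s) for s in idx if idx.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("feature table contains non-finite values")
        missing = set(cols) - set(self.metadata.index)
        if missing:
            raise ValueError(f"variables missing from metadata: {sorted(missing)}")
        # keep metadata aligned to (and restricted to) the value columns
        self.metadata = self.metadata.loc[cols]
        for col in ("role", "tier", "mechanism"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
            bad = self.metadata.index[self.metadata[col].isna()]
            if len(bad):
                raise ValueError(
                    f"metadata column {col!r} undefined for variable(s) "
                    f"{list(bad)[:5]}"
                )
        bad_tier = sorted(set(self.metadata["tier"]) - set(TIERS))
        if bad_tier:
            raise ValueError(f"unknown tier label(s): {bad_tier}")
        bad_mech = sorted(set(self.metadata["mechanism"]) - set(MECHANISMS))
        if bad_mech:
            raise ValueError(f"unknown mechanism label(s): {bad_mech}")

    # -- accessors -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def tier_of(self, variable: str) -> str:
        return str(self.metadata.at[variable, "tier"])

    def variables_with(self, *, role: str | None = None, tier: str | None = None,
                       mechanism: str | None = None) -> list[str]:
        """Variables matching every given metadata filter."""
        mask = pd.Series(True, index=self.metadata.index)
        if role is not None:
            mask &= self.metadata["role"] == role
        if tier is not None:
            mask &= self.metadata["tier"] == tier
        if mechanism is not None:
            mask &= self.metadata["mechanism"] == mechanism
        return list(self.metadata.index[mask])

    # -- transforms ----------------------------------------------------

    def select(self, variables: list[str]) -> "FeatureTable":
        """Restrict to the given variables (order preserved as given)."""
        unknown = [v for v in variables if v not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown variable(s): {unknown}")
        return FeatureTable(self.values[variables], self.metadata.loc[variables])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.metadata.copy())

    def equals(self, other: "FeatureTable") -> bool:
        return self.values.equals(other.values) and _meta_equal(
            self.metadata, other.metadata
        )

    # -- I/O -----------------------------------------------------------

    def write(self, values_path: str | Path, metadata_path: str | Path) -> None:
        """Write value TSV (first column = sample ID) and metadata sidecar."""
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(values_path, sep="\t")
        meta = self.metadata.reset_index(names="variable")
        meta.to_csv(metadata_path, sep="\t", index=False,
                    columns=list(METADATA_COLUMNS))

    @classmethod
    def read(cls, values_path: str | Path,
             metadata_path: str | Path | None = None) -> "FeatureTable":
        sep = "," if str(values_path).endswith(".csv") else "\t"
        values = pd.read_csv(values_path, sep=sep, index_col=0,
                             float_precision="round_trip")
        values.index = values.index.astype(str)
        metadata = read_metadata(metadata_path) if metadata_path else None
        return cls(values, metadata)


def default_metadata(variables: list[str], role: str = "gene",
                     tier: str = "environment",
                     mechanism: str = "other") -> pd.DataFrame:
    """Uniform metadata for tables whose variables share one role."""
    return pd.DataFrame(
        {"role": role, "tier": tier, "mechanism": mechanism,
         "length_bp": np.nan},
        index=pd.Index(variables, name="variable"),
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"variable": str})
    missing_cols = {"variable", "role", "tier", "mechanism"} - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata file lacks column(s) {sorted(missing_cols)}")
    for col in ("role", "tier", "mechanism"):
        bad = meta.loc[meta[col].isna(), "variable"]
        if len(bad):
            raise ValueError(
                f"metadata column {col!r} missing for variable(s) {list(bad)[:5]}"
            )
    return meta.set_index("variable")


def _meta_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.index) != list(b.index):
        return False
    for col in ("role", "tier", "mechanism"):
        if not (a[col] == b[col]).all():
            return False
    la, lb = a["length_bp"].astype(float), b["length_bp"].astype(float)
    return bool(((la == lb) | (la.isna() & lb.isna())).all())
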