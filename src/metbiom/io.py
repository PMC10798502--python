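"""Plot-level data model and long-format CSV input/output.

The single input currency of the pipeline is a *trait table*: long-format
plot observations keyed by (genotype, environment, replicate, trait).
Environments are opaque labels (``"2019-20"`` style year tags are never
parsed as dates); genotype and trait codes are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TraitTable",
    "BalanceError",
    "IntegrityError",
    "read_trait_table",
    "write_trait_table",
    "genotype_env_means",
]

#: canonical column order of the long format
COLUMNS = ("genotype", "environment", "replicate", "trait", "value")

KEY = ["genotype", "environment", "replicate", "trait"]


class IntegrityError(ValueError):
    """Duplicate keys or non-finite values in a trait table."""


class BalanceError(ValueError):
    """The table is not a complete genotype x environment x replicate x trait grid."""


def _first_appearance(values) -> list:
    return list(pd.unique(np.asarray(values, dtype=object)))


@dataclass
class TraitTable:
    """Balanced long-format plot observations.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype, environment, replicate, trait,
        value``.  Row order is preserved; genotype/environment/trait
        ordering is first-appearance order.
    """

    data: pd.DataFrame
    genotypes: list = field(init=False)
    environments: list = field(init=False)
    traits: list = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise IntegrityError(f"missing required column(s): {missing}")
        df = self.data.loc[:, list(COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["environment"] = df["environment"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["replicate"] < 1).any():
            raise IntegrityError("replicate numbers must be >= 1")
        if not np.isfinite(df["value"]).all():
            bad = df.index[~np.isfinite(df["value"])].tolist()[:5]
            raise IntegrityError(f"non-finite trait values at rows {bad}")
        dup = df.duplicated(subset=KEY)
        if dup.any():
            first = df.loc[dup, KEY].iloc[0].tolist()
            raise IntegrityError(
                f"duplicate (genotype, environment, replicate, trait) key: {first}"
            )
        self.data = df
        self.genotypes = _first_appearance(df["genotype"])
        self.environments = _first_appearance(df["environment"])
        self.traits = _first_appearance(df["trait"])

    # -- design metadata ---------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique().tolist())

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def __len__(self) -> int:
        return len(self.data)

    # -- validation --------------------------------------------------------
    def validate_balance(self) -> None:
        """Raise :class:`BalanceError` unless every cell of the
        genotype x environment x replicate x trait grid is present exactly once."""
        expected = (
            self.n_genotypes * self.n_environments * self.n_replicates * self.n_traits
        )
        if len(self.data) == expected:
            # uniqueness already checked, so the count equality implies balance
            # only if the replicate labels form one common set; verify cheaply.
            counts = self.data.groupby(KEY[:3], observed=True)["trait"].count()
            if (counts == self.n_traits).all():
                return
        full = pd.MultiIndex.from_product(
            [self.genotypes, self.environments, self.replicates, self.traits],
            names=KEY,
        )
        present = pd.MultiIndex.from_frame(self.data[KEY])
        missing = full.difference(present)
        raise BalanceError(
            f"table is unbalanced: {len(missing)} missing cell(s), "
            f"first few: {list(missing[:5])}"
        )

    @property
    def is_balanced(self) -> bool:
        try:
            self.validate_balance()
        except BalanceError:
            return False
        return True

    def subset(self, trait: str, environment: str | None = None) -> pd.DataFrame:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}; have {self.traits}")
        df = self.data[self.data["trait"] == trait]
        if environment is not None:
            if environment not in self.environments:
                raise KeyError(
                    f"unknown environment {environment!r}; have {self.environments}"
                )
            df = df[df["environment"] == environment]
        return df


def read_trait_table(
    path,
    *,
    sep: str = ",",
    columns: dict | None = None,
    require_balance: bool = True,
) -> TraitTable:
    """Read a long-format CSV/TSV into a validated :class:`TraitTable`.

    ``columns`` maps canonical names (``genotype`` ...) to the file's header
    names when they differ.
    """
    df = pd.read_csv(path, sep=sep, dtype={"value": object})
    rename = {v: k for k, v in (columns or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required column(s): {missing}")
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["value"], errors="coerce")
        rows = df.index[bad.isna()].tolist()[:5]
        raise IntegrityError(f"{path}: non-numeric value(s) at rows {rows}") from None
    table = TraitTable(df)
    if require_balance:
        table.validate_balance()
    return table


def write_trait_table(table: TraitTable, path, *, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index=False)


def read_wide_table(path, *, sep: str = ",", id_columns=("genotype", "environment", "replicate")) -> TraitTable:
    """Convenience importer for a wide per-trait matrix; normalized to long."""
    df = pd.read_csv(path, sep=sep)
    traits = [c for c in df.columns if c not in id_columns]
    long = df.melt(
        id_vars=list(id_columns), value_vars=traits, var_name="trait", value_name="value"
    )
    return TraitTable(long)


def genotype_env_means(
    table: TraitTable, trait: str, *, environment: str | None = None
) -> pd.DataFrame:
    """Genotype x environment replicate means for one trait.

    Rows are genotypes, columns environments, both in first-appearance
    order.  An ``overall`` column holds the genotype mean across all
    environments and replicates.
    """
    df = table.subset(trait)
    mat = (
        df.pivot_table(
            index="genotype", columns="environment", values="value", aggfunc="mean"
        )
        .reindex(index=table.genotypes, columns=table.environments)
    )
    mat["overall"] = (
        df.groupby("genotype", observed=True)["value"].mean().reindex(table.genotypes)
    )
    if environment is not None:
        return mat[[environment]]
    return mat
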