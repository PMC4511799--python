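"""Multilocus diploid genotype tables.

A :class:`GenotypeTable` holds one sample set (a reference baseline or a
mixture of unknown-origin fish) typed at one shared panel of loci with a
single marker type.  Alleles are opaque string labels; a genotype at one
locus is an unordered allele pair, and a locus is either fully typed or
missing for a fish (half-calls are rejected at read time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, MalformedGenotypeError

#: metadata columns carried alongside genotypes, in canonical order
META_COLUMNS = [
    "fish_id", "origin_label", "reporting_group", "date", "lat", "lon",
    "vessel_id", "length_mm", "technique", "cwt_group",
]

MARKER_TYPES = ("microsat", "snp")


@dataclass
class GenotypeTable:
    marker_type: str
    loci: list[str]
    data: pd.DataFrame  # META_COLUMNS + f"{locus}_1"/f"{locus}_2" per locus

    def __post_init__(self):
        if self.marker_type not in MARKER_TYPES:
            raise ValueError(f"marker_type must be one of {MARKER_TYPES}")
        for col in META_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = pd.NA
        ids = self.data["fish_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise DuplicateIdError(f"duplicate fish_id(s): {sorted(set(dup))}")
        self._validate_pairs()
        self.data = self.data.reset_index(drop=True)

    def _validate_pairs(self):
        for locus in self.loci:
            a = self.data[f"{locus}_1"]
            b = self.data[f"{locus}_2"]
            half = a.isna() ^ b.isna()
            if half.any():
                fish = self.data.loc[half, "fish_id"].iloc[0]
                raise MalformedGenotypeError(
                    f"fish {fish!r}, locus {locus!r}: exactly one allele typed"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_fish(self) -> int:
        return len(self.data)

    @property
    def fish_ids(self) -> pd.Series:
        return self.data["fish_id"]

    def allele_columns(self, locus: str) -> tuple[pd.Series, pd.Series]:
        return self.data[f"{locus}_1"], self.data[f"{locus}_2"]

    def typed_mask(self) -> np.ndarray:
        """(n_fish, n_loci) boolean array: True where the locus is typed."""
        cols = [self.data[f"{l}_1"].notna().to_numpy() for l in self.loci]
        return np.column_stack(cols) if cols else np.zeros((self.n_fish, 0), bool)

    def n_typed(self) -> np.ndarray:
        return self.typed_mask().sum(axis=1)

    def het_fraction(self) -> np.ndarray:
        """Observed heterozygosity per fish: heterozygous / typed loci.

        NaN for fish with zero typed loci.
        """
        typed = self.typed_mask()
        het = np.zeros_like(typed, dtype=bool)
        for j, locus in enumerate(self.loci):
            a, b = self.allele_columns(locus)
            het[:, j] = typed[:, j] & (a != b).to_numpy(dtype=bool, na_value=False)
        n_typed = typed.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_typed > 0, het.sum(axis=1) / n_typed, np.nan)

    # -- registry-coded view (for likelihood computations) -----------------

    def allele_registry(self) -> dict[str, list[str]]:
        """Sorted distinct allele labels observed per locus."""
        reg = {}
        for locus in self.loci:
            a, b = self.allele_columns(locus)
            vals = set(a.dropna()) | set(b.dropna())
            reg[locus] = sorted(vals)
        return reg

    def coded(self, registry: dict[str, list[str]]) -> tuple[np.ndarray, np.ndarray]:
        """Integer-coded alleles: two (n_fish, n_loci) arrays, -1 = missing.

        Pairs are canonicalised (code1 <= code2) so unordered equality is a
        plain elementwise comparison.  Raises KeyError if an observed allele
        is absent from the registry.
        """
        n, L = self.n_fish, len(self.loci)
        c1 = np.full((n, L), -1, dtype=np.int32)
        c2 = np.full((n, L), -1, dtype=np.int32)
        for j, locus in enumerate(self.loci):
            lookup = {lab: k for k, lab in enumerate(registry[locus])}
            a, b = self.allele_columns(locus)
            typed = a.notna().to_numpy()
            try:
                ca = np.array([lookup[x] for x in a[typed]], dtype=np.int32)
                cb = np.array([lookup[x] for x in b[typed]], dtype=np.int32)
            except KeyError as e:
                raise KeyError(
                    f"allele {e.args[0]!r} at locus {locus!r} not in registry"
                ) from None
            c1[typed, j] = np.minimum(ca, cb)
            c2[typed, j] = np.maximum(ca, cb)
        return c1, c2

    # -- manipulation ------------------------------------------------------

    def subset(self, keep) -> "GenotypeTable":
        """New table restricted to a boolean mask or index list."""
        sub = self.data.loc[keep].reset_index(drop=True).copy()
        return GenotypeTable(self.marker_type, list(self.loci), sub)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.marker_type, list(self.loci), self.data.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.marker_type != other.marker_type or self.loci != other.loci:
            return False
        cols = META_COLUMNS + [f"{l}_{i}" for l in self.loci for i in (1, 2)]
        a = self.data[cols].reset_index(drop=True)
        b = other.data[cols].reset_index(drop=True)
        if len(a) != len(b):
            return False
        # normalise the various missing markers (pd.NA, NaN, NaT) to None
        ao = a.astype(object).where(a.notna(), None).to_numpy()
        bo = b.astype(object).where(b.notna(), None).to_numpy()
        return bool((ao == bo).all())
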