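"""Domain types shared by every analysis stage.

Inbred lines are represented as ONE haploid allele copy per sample: calls are
coded ``0``/``1`` for the two alleles of a biallelic SNP and ``MISSING``
(``-1``) for no-calls.  All downstream statistics use this haploid coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in ``GenotypeMatrix.calls``.
MISSING: int = -1

VALID_STATES = ("NSW", "QLD", "VIC", "SA", "WA")


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Haploid biallelic genotype calls for a panel of inbred samples.

    Parameters
    ----------
    sample_ids
        Row labels, unique.
    snp_ids
        Column labels, unique.
    calls
        ``int8`` array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, MISSING}``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.snp_ids = list(map(str, self.snp_ids))
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def snp_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def take_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.snp_ids), self.calls[idx]
        )

    def take_snps(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.snp_index(ids)
        return GenotypeMatrix(
            list(self.sample_ids), [self.snp_ids[j] for j in idx], self.calls[:, idx]
        )

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per SNP over non-missing calls (NaN if none)."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        ones = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, ones / np.maximum(n, 1), np.nan)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class GeneticMap:
    """Per-SNP chromosome and centimorgan position on a consensus map."""

    table: pd.DataFrame  # index snp_id; columns chrom, cm

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = {"chrom", "cm"} - set(t.columns)
        if missing_cols:
            raise ValidationError(f"map missing columns: {sorted(missing_cols)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate SNP id in map: {dup!r}")
        if (t["cm"] < 0).any():
            raise ValidationError("map cM positions must be non-negative")
        self.table = t.assign(chrom=t["chrom"].astype(str), cm=t["cm"].astype(float))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "GeneticMap":
        df = pd.DataFrame(records, columns=["snp_id", "chrom", "cm"])
        return cls(df.set_index("snp_id"))

    @property
    def snp_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chrom"].unique())

    def has(self, snp_ids: Iterable[str]) -> np.ndarray:
        return np.isin(np.asarray(list(snp_ids)), self.table.index)

    def positions(self, snp_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(snp_ids), "cm"].to_numpy()

    def chrom_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(snp_ids), "chrom"].to_numpy()

    def sorted_snps(self, chrom: str) -> list[str]:
        """SNP ids on ``chrom`` in increasing cM order (stable for ties)."""
        sub = self.table[self.table["chrom"] == chrom]
        return [str(s) for s in sub.sort_values("cm", kind="stable").index]

    def order_matrix(self, g: GenotypeMatrix) -> list[tuple[str, list[str]]]:
        """Group a matrix's SNPs by chromosome, each group map-ordered.

        SNPs without a map entry are dropped (map-aware operations require a
        position).
        """
        present = set(g.snp_ids)
        out = []
        for chrom in self.chromosomes:
            ids = [s for s in self.sorted_snps(chrom) if s in present]
            if ids:
                out.append((chrom, ids))
        return out


@dataclass
class SampleMetadata:
    """Per-sample role, donor subpopulation, and release year/State.

    Donors must carry a ``subpop_id``; recipients should carry a
    ``year_of_release`` (samples with no year are excluded from period
    analyses, with a warning at assignment time).
    """

    table: pd.DataFrame  # index sample_id; columns role, subpop_id, country, year, state
    _REQUIRED = ("role",)

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "role" not in t.columns:
            raise ValidationError("metadata missing required column: role")
        for col in ("subpop_id", "country", "year", "state", "period"):
            if col not in t.columns:
                t[col] = pd.NA
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
        bad_role = ~t["role"].isin(("donor", "recipient"))
        if bad_role.any():
            raise ValidationError(
                f"invalid role for sample {t.index[bad_role][0]!r} "
                f"(expected donor/recipient)"
            )
        donors = t["role"] == "donor"
        if (donors & t["subpop_id"].isna()).any():
            missing = t.index[donors & t["subpop_id"].isna()][0]
            raise ValidationError(f"donor {missing!r} lacks subpop_id")
        t["subpop_id"] = t["subpop_id"].astype("Int64")
        t["year"] = pd.to_numeric(t["year"], errors="coerce").astype("Int64")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def donors(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "donor"]

    def recipients(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "recipient"]

    def subpop_of(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(sample_ids), "subpop_id"].to_numpy()

    def subpop_members(self) -> dict[int, list[str]]:
        d = self.donors()
        out: dict[int, list[str]] = {}
        for sid, pop in d["subpop_id"].items():
            out.setdefault(int(pop), []).append(str(sid))
        return out
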