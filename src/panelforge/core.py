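"""Core in-memory containers shared by every stage of the pipeline.

Genotypes are stored as alternate-allele dosages on the 4-symbol alphabet
``{0, 1, 2, MISSING}`` where ``MISSING`` is the sentinel ``-1``.  Whether the
counted allele is the minor one is irrelevant here: minor-allele frequency is
computed downstream, so allele orientation never corrupts statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel code for a missing genotype call.
MISSING: int = -1

#: Valid genotype codes (alternate-allele dosage) plus the missing sentinel.
VALID_CODES = frozenset({-1, 0, 1, 2})

#: Recognised sample roles in a population map.
ROLES = ("control", "unknown", "outgroup", "ntc")


def _as_code_array(codes) -> np.ndarray:
    arr = np.asarray(codes)
    if arr.ndim != 2:
        raise ValueError(f"genotype codes must be 2-D, got shape {arr.shape}")
    arr = arr.astype(np.int8, copy=True)
    bad = set(np.unique(arr)) - VALID_CODES
    if bad:
        raise ValueError(f"invalid genotype codes {sorted(bad)}; allowed: 0,1,2,{MISSING}")
    return arr


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci genotype matrix with optional call metadata.

    Parameters
    ----------
    sample_ids, locus_ids
        Ordered, unique labels for rows and columns.
    codes
        ``(n_samples, n_loci)`` int array of alternate-allele dosages, with
        ``-1`` for missing calls.
    depth, quality
        Optional per-call read depth and phred-scaled genotype quality,
        same shape as ``codes``.
    allele_depths
        Optional ``(n_samples, n_loci, 2)`` array of (ref, alt) read counts.
    loci
        Optional per-locus metadata frame indexed like ``locus_ids`` with any
        of the columns ``contig``, ``pos`` (1-based), ``ref``, ``alt``,
        ``position_in_locus`` (1-based offset within the RAD locus).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray
    depth: np.ndarray | None = None
    quality: np.ndarray | None = None
    allele_depths: np.ndarray | None = None
    loci: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.codes = _as_code_array(self.codes)
        n, l = self.codes.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != l:
            raise ValueError("sample/locus label lengths do not match codes shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.locus_ids)) != l:
            raise ValueError("locus ids must be unique")
        for name in ("depth", "quality"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.codes.shape:
                    raise ValueError(f"{name} shape {arr.shape} != codes shape")
                setattr(self, name, arr)
        if self.allele_depths is not None:
            ad = np.asarray(self.allele_depths, dtype=float)
            if ad.shape != (n, l, 2):
                raise ValueError("allele_depths must have shape (n_samples, n_loci, 2)")
            self.allele_depths = ad
        if self.loci is not None:
            if len(self.loci) != l:
                raise ValueError("loci metadata length does not match locus count")
            self.loci = self.loci.copy()
            self.loci.index = pd.Index(self.locus_ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def call_rate_per_sample(self) -> np.ndarray:
        """Fraction of non-missing calls per sample, in [0, 1]."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def call_rate_per_locus(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting -----------------------------------------------------
    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def locus_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            return np.array([lookup[str(l)] for l in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"unknown locus id {exc.args[0]!r}") from None

    def subset(self, samples: Sequence[str] | None = None,
               loci: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample and/or locus ids."""
        si = self.sample_index(samples) if samples is not None else np.arange(self.n_samples)
        li = self.locus_index(loci) if loci is not None else np.arange(self.n_loci)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            locus_ids=[self.locus_ids[j] for j in li],
            codes=self.codes[np.ix_(si, li)],
            depth=None if self.depth is None else self.depth[np.ix_(si, li)],
            quality=None if self.quality is None else self.quality[np.ix_(si, li)],
            allele_depths=None if self.allele_depths is None
            else self.allele_depths[np.ix_(si, li)],
            loci=None if self.loci is None else self.loci.iloc[li],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()


@dataclass
class PopulationMap:
    """Sample -> group label and role mapping.

    Roles: ``control`` (ascertainment/reference sample), ``unknown``
    (sample to be assigned), ``outgroup``, ``ntc`` (no-template control).
    """

    table: pd.DataFrame  # columns: sample, group, role

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table).copy()
        required = {"sample", "group", "role"}
        missing = required - set(t.columns)
        if "role" in missing:
            t["role"] = "control"
            missing.discard("role")
        if missing:
            raise ValueError(f"population map missing columns: {sorted(missing)}")
        t["sample"] = t["sample"].astype(str)
        t["group"] = t["group"].astype(str)
        t["role"] = t["role"].astype(str)
        if t["sample"].duplicated().any():
            dupes = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids in population map: {dupes}")
        bad = set(t["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {ROLES}")
        ctrl = t[t["role"] == "control"]
        if (ctrl["group"] == "").any():
            raise ValueError("every control sample must carry a group label")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_items(cls, items: Mapping[str, str] | Iterable[tuple[str, str, str]],
                   role: str = "control") -> "PopulationMap":
        if isinstance(items, Mapping):
            rows = [(s, g, role) for s, g in items.items()]
        else:
            rows = [tuple(r) if len(r) == 3 else (*r, role) for r in items]
        return cls(pd.DataFrame(rows, columns=["sample", "group", "role"]))

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def groups(self) -> list[str]:
        """Distinct non-empty group labels in first-appearance order."""
        return [g for g in dict.fromkeys(self.table["group"]) if g]

    def group_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == str(sample)]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in population map")
        return row["group"].iloc[0]

    def samples_in_group(self, group: str, roles: Sequence[str] | None = None) -> list[str]:
        t = self.table
        sel = t["group"] == str(group)
        if roles is not None:
            sel &= t["role"].isin(roles)
        return t.loc[sel, "sample"].tolist()

    def controls_by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.groups():
            ctrls = self.samples_in_group(g, roles=["control"])
            if ctrls:
                out[g] = ctrls
        return out

    def with_roles(self, roles: Mapping[str, str]) -> "PopulationMap":
        t = self.table.copy()
        t["role"] = [roles.get(s, r) for s, r in zip(t["sample"], t["role"])]
        return PopulationMap(t)

    def restrict(self, samples: Iterable[str]) -> "PopulationMap":
        keep = set(str(s) for s in samples)
        return PopulationMap(self.table[self.table["sample"].isin(keep)])


@dataclass
class ReplicateSet:
    """Per-sample stacks of repeated genotype calls over a fixed locus panel.

    ``codes`` has shape ``(n_samples, n_replicates, n_loci)``; replicate slots
    that were never run (ragged input) are filled with ``MISSING``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray
    replicate_meta: pd.DataFrame | None = None  # columns: sample, replicate, chip, partition

    def __post_init__(self) -> None:
        arr = np.asarray(self.codes)
        if arr.ndim != 3:
            raise ValueError("replicate codes must have shape (samples, replicates, loci)")
        flat = _as_code_array(arr.reshape(arr.shape[0] * arr.shape[1], arr.shape[2]))
        self.codes = flat.reshape(arr.shape)
        if len(self.sample_ids) != arr.shape[0] or len(self.locus_ids) != arr.shape[2]:
            raise ValueError("label lengths do not match replicate codes shape")
        if arr.shape[1] < 1:
            raise ValueError("at least one replicate required")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.codes.shape[1]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[2]

    def subset_loci(self, loci: Sequence[str]) -> "ReplicateSet":
        lookup = {l: i for i, l in enumerate(self.locus_ids)}
        li = [lookup[str(l)] for l in loci]
        return ReplicateSet(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in li],
            codes=self.codes[:, :, li],
            replicate_meta=self.replicate_meta,
        )
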