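"""Shared domain types for the paired sexual/parthenogenetic pipeline.

Coordinate conventions: VCF positions are 1-based; callable masks and all
internal interval arithmetic are 0-based half-open. Conversion happens at the
format boundary, nowhere else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

SEXUAL = "sexual"
PARTHENOGENETIC = "parthenogenetic"
MODES = (SEXUAL, PARTHENOGENETIC)

SV_TYPES = ("DEL", "INS", "DUP", "INV")


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SpeciesEntry:
    """One species of a study: its pair, reproductive mode and samples."""

    species_id: str
    pair_id: str
    mode: str
    individuals: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown reproductive mode {self.mode!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Species <-> pair <-> reproductive-mode mapping.

    Each pair holds exactly one sexual and one parthenogenetic species; this
    structure drives every piece of paired inference downstream.
    """

    species: tuple[SpeciesEntry, ...]

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("species_id values must be unique")
        samples = [i for s in self.species for i in s.individuals]
        if len(set(samples)) != len(samples):
            raise ValueError("sample labels must be unique study-wide")
        for pid in {s.pair_id for s in self.species}:
            modes = sorted(s.mode for s in self.species if s.pair_id == pid)
            if modes != sorted(MODES):
                raise ValueError(
                    f"pair {pid!r} must contain exactly one sexual and one "
                    f"parthenogenetic species, got {modes}"
                )

    @property
    def pair_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.species:
            if s.pair_id not in seen:
                seen.append(s.pair_id)
        return tuple(seen)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def species_by_id(self, species_id: str) -> SpeciesEntry:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def pair_members(self, pair_id: str) -> tuple[SpeciesEntry, SpeciesEntry]:
        """Return the (sexual, parthenogenetic) members of a pair."""
        members = [s for s in self.species if s.pair_id == pair_id]
        if not members:
            raise KeyError(pair_id)
        sexual = next(s for s in members if s.mode == SEXUAL)
        asex = next(s for s in members if s.mode == PARTHENOGENETIC)
        return sexual, asex

    def sample_to_species(self) -> dict[str, str]:
        return {i: s.species_id for s in self.species for i in s.individuals}


@dataclass
class VariantRecord:
    """A single SNP call with per-sample genotype and depth."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: dict[str, Genotype]
    depths: dict[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        if not self.genotypes:
            raise ValueError("at least one sample column required")
        for smp, d in self.depths.items():
            if d < 0:
                raise ValueError(f"negative depth for sample {smp!r}")


@dataclass
class SVRecord:
    """A structural-variant call (Manta-like) for one sample.

    ``start``/``end`` are 1-based breakpoint positions; for insertions
    ``end == start`` is allowed and ``length`` is the insertion length.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    strand_pair: str
    support_sr: int
    support_pe: int
    sample: str
    genotype: str  # "het" | "hom"
    sample_coverage: float

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type != "INS" and self.end < self.start:
            raise ValueError("end must be >= start")
        if self.length < 0 or self.support_sr < 0 or self.support_pe < 0:
            raise ValueError("length and support counts must be >= 0")


class CallableMask:
    """Genomic intervals (0-based half-open) over which rates are denominated.

    Intervals are normalized on construction: per chromosome they are sorted,
    with overlaps and bookends merged.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        from intervaltree import IntervalTree

        self._ivals: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = list(ivs)
            for s, e in ivs:
                if e <= s:
                    raise ValueError(
                        f"interval end must exceed start, got ({s}, {e}) on {chrom}"
                    )
            if not ivs:
                continue
            tree = IntervalTree.from_tuples(ivs)
            tree.merge_overlaps(strict=False)  # strict=False also joins bookends
            arr = np.array(sorted((iv.begin, iv.end) for iv in tree), dtype=np.int64)
            self._ivals[chrom] = arr

    @property
    def intervals(self) -> dict[str, np.ndarray]:
        return self._ivals

    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._ivals))

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._ivals.values())
        )

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        arr = self._ivals.get(chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < arr[i, 1]

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of 0-based positions."""
        arr = self._ivals.get(chrom)
        if arr is None or arr.size == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < arr[idx[ok], 1]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallableMask):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals)


def callable_length(mask: CallableMask) -> int:
    """Total number of callable sites (denominator of all rate statistics)."""
    return mask.total_length()


@dataclass
class BranchScore:
    """Per-gene, per-terminal-branch likelihood-ratio evidence for selection.

    ``delta_lnl`` is stored on the scale to which the null distribution applies
    (the doubled log-likelihood difference of the branch-site test).
    """

    gene_id: str
    species_id: str
    delta_lnl: float
    pvalue: float | None = None
    qvalue: float | None = None
    prop_sites_selected: float | None = None

    def __post_init__(self) -> None:
        if self.delta_lnl < 0:
            raise ValueError("delta_lnl must be >= 0")
        for name in ("pvalue", "qvalue", "prop_sites_selected"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SelectionSummary:
    """Per-species count of positively selected branches at a q cutoff."""

    species_id: str
    n_tested: int
    n_selected: int
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_selected <= max(self.n_tested, 0)):
            raise ValueError("need 0 <= n_selected <= n_tested")


@dataclass
class HetEstimate:
    """Per-individual heterozygosity rate: het variants / callable sites."""

    species_id: str
    sample: str
    n_het: int
    n_callable: int
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_callable <= 0:
            raise ValueError("n_callable must be > 0")
        self.rate = self.n_het / self.n_callable
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must lie in [0, 1]")


@dataclass(frozen=True)
class CoverageWindow:
    """Per-sample acceptable depth range for SV calls."""

    sample: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError("need 0 <= lo <= hi")


@dataclass
class MergedSV:
    """A population-level SV cluster across samples."""

    representative: SVRecord
    members: list[tuple[str, SVRecord]]
    n_samples: int


@dataclass
class PermTestResult:
    """Outcome of a permutation test.

    ``B`` is the number of Monte-Carlo draws or the string ``"exact"``;
    ``null_stats`` optionally stores the full null distribution.
    """

    statistic_name: str
    observed: float
    B: int | str
    scheme: str
    side: str
    pvalue: float
    null_stats: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "B": self.B,
            "scheme": self.scheme,
            "side": self.side,
            "pvalue": self.pvalue,
        }
        d.update({k: v for k, v in self.extras.items()})
        if include_null and self.null_stats is not None:
            d["null_stats"] = [float(x) for x in self.null_stats]
        return d
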