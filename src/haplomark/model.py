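"""Core data model shared by all pipeline stages.

Allele calls are stored as single characters: ``A/C/G/T`` for homozygous
nucleotide calls, :data:`HET` for heterozygous diploid calls and
:data:`MISSING` for uncalled data.  Positions are 1-based at the API surface;
interval arithmetic is done on 0-based half-open regions internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

HET = "H"
MISSING = "N"
NUCLEOTIDES = frozenset("ACGT")
SPECIAL_CALLS = frozenset({HET, MISSING})


class PanelError(ValueError):
    """Base class for panel-validation failures."""


class EmptyPanelError(PanelError):
    """Raised when a filtering step leaves no usable data."""


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single-nucleotide variant site on a reference assembly.

    ``pos`` is the 1-based physical coordinate; ``alleles`` the set of
    nucleotide alleles observed at the site.
    """

    chrom: str
    pos: int
    alleles: frozenset = field(compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"site position must be >= 1, got {self.pos}")
        bad = set(self.alleles) - NUCLEOTIDES
        if bad:
            raise PanelError(f"non-nucleotide alleles at {self.chrom}:{self.pos}: {sorted(bad)}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def site_id_pos(site_id: str) -> int:
    """1-based position encoded in a ``chrom:pos`` site identifier."""
    return int(site_id.rsplit(":", 1)[1])


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of single-character allele calls.

    ``calls`` has shape ``(len(samples), len(sites))`` with dtype ``<U1``.
    ``region`` is the 0-based half-open interval the sites fall in (or
    ``None`` when no region was requested).
    """

    samples: list
    sites: list
    calls: np.ndarray
    region: tuple | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = list(self.sites)
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise PanelError(
                f"calls shape {self.calls.shape} != ({len(self.samples)}, {len(self.sites)})"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise PanelError(f"duplicate sample IDs: {dupes}")
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate site IDs in matrix")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise PanelError("sites must be sorted by (chrom, pos)")
        for j, site in enumerate(self.sites):
            column = self.calls[:, j]
            observed = set(column.tolist()) - SPECIAL_CALLS
            extra = observed - set(site.alleles)
            if extra:
                raise PanelError(
                    f"calls {sorted(extra)} at {site.id} not among declared alleles {sorted(site.alleles)}"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list:
        return [s.id for s in self.sites]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def site_index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def row(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    # -- derived matrices ----------------------------------------------------

    def subset_sites(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[j] for j in keep],
            calls=self.calls[:, keep].copy(),
            region=self.region,
        )

    def subset_samples(self, keep_samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep_samples]
        return GenotypeMatrix(
            samples=list(keep_samples),
            sites=list(self.sites),
            calls=self.calls[idx, :].copy(),
            region=self.region,
        )

    def with_calls(self, calls: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples), sites=list(self.sites), calls=calls, region=self.region
        )


def matrix_from_vectors(
    vectors: Mapping[str, str],
    positions: Sequence[int],
    chrom: str = "Chr8",
    region: tuple | None = None,
) -> GenotypeMatrix:
    """Build a matrix from per-sample allele strings over ``positions``.

    ``vectors`` maps sample ID to an allele string aligned with ``positions``
    (which need not be sorted; columns are reordered as required).
    """
    order = np.argsort(np.asarray(positions, dtype=int), kind="stable")
    samples = list(vectors)
    raw = np.array([list(vectors[s]) for s in samples], dtype="<U1")
    if raw.shape[1] != len(positions):
        raise PanelError("vector length does not match number of positions")
    calls = raw[:, order]
    sites = []
    for j in order:
        column = raw[:, j]
        alleles = frozenset(set(column.tolist()) - SPECIAL_CALLS)
        sites.append(VariantSite(chrom=chrom, pos=int(positions[j]), alleles=alleles))
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls, region=region)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: subpopulation label plus free-form attributes."""

    sample_id: str
    subpopulation: str
    attributes: Mapping = field(default_factory=dict)


def meta_index(meta: Iterable[SampleMeta]) -> dict:
    out = {}
    for m in meta:
        if m.sample_id in out:
            raise PanelError(f"duplicate sample ID in metadata: {m.sample_id}")
        out[m.sample_id] = m
    return out


@dataclass
class PhenotypePanel:
    """Replicated quantitative phenotype for one sample (concentration, ppm)."""

    sample_id: str
    replicate_values: list

    def __post_init__(self) -> None:
        self.replicate_values = [float(v) for v in self.replicate_values]
        if not self.replicate_values:
            raise PanelError(f"no replicate values for {self.sample_id}")
        if any(v < 0 for v in self.replicate_values):
            raise PanelError(f"negative concentration for {self.sample_id}")

    @property
    def mean_value(self) -> float:
        return float(np.mean(self.replicate_values))


def parse_region(text: str) -> tuple:
    """Parse a 1-based inclusive ``CHR:START-END`` region into the internal
    0-based half-open ``(chrom, start, end)`` convention."""
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start, end = int(lo), int(hi)
    except ValueError as exc:
        raise PanelError(f"cannot parse region {text!r}; expected CHR:START-END") from exc
    if start < 1 or end < start:
        raise PanelError(f"invalid region bounds in {text!r}")
    return (chrom, start - 1, end)
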