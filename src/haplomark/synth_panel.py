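"""Synthetic diversity-panel generator with a recoverable truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes: a handful of well-separated founder haplotypes over a gene region,
subpopulation-specific founder frequencies, low-frequency recombinant
vectors filling the residual frequency mass, per-call heterozygous/missing
noise, one founder carrying a functional deletion together with a private
allele at a flanking diagnostic site, and a bimodal phenotype.

Design notes
------------
* Founders are built from a random base vector plus disjoint blocks of
  alternate alleles, so pairwise separation is guaranteed by construction.
  The deletion-carrying founder's block is additionally shared half-and-half
  with two other founders, so no gene-internal site is private to it — the
  only strictly diagnostic site is the planted flanking one.
* Mutation flips skip the diagnostic site (the validated marker is modeled
  as error-free; assay discordance is modeled separately in
  :func:`simulate_jobs`), and noise never touches the reference-marker
  table.
* Recombinant samples cross two founders other than the deletion carrier,
  so they can never appear as carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import refpanel
from .model import (
    HET,
    MISSING,
    GenotypeMatrix,
    PanelError,
    PhenotypePanel,
    SampleMeta,
    VariantSite,
)
from .valmark import AMBIGUOUS, FAILED

DELETION = "del"
NO_DELETION = "nodel"


class ConfigError(PanelError):
    """Invalid simulation configuration."""


@dataclass
class FounderHaplotype:
    """A founder allele vector with its per-subpopulation frequency map."""

    vector: str
    frequencies: Mapping[str, float]


@dataclass
class PhenotypeModel:
    carrier_range: tuple = refpanel.CARRIER_2AP_RANGE
    noncarrier_range: tuple = refpanel.NONCARRIER_2AP_RANGE


@dataclass
class SimulationConfig:
    chrom: str = "Chr8"
    gene_start: int = 20_380_000
    gene_end: int = 20_385_000
    n_sites: int = 255
    flank_sites: int = 12  # per side
    flank_span: int = 10_000
    founder_haplotypes: list = field(default_factory=list)
    subpop_sizes: dict = field(default_factory=dict)
    mutation_noise: float = 0.001
    het_rate: float = 0.005
    missing_rate: float = 0.01
    high_missing_rate: float = 0.0  # fraction of samples forced to ~60% missing
    indel_haplotype: int = 5
    diagnostic_offset: int = 7_908  # bp upstream of the gene start
    cluster_radius: int = 3
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    n_replicates: int = 3
    replicate_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_noise", "het_rate", "missing_rate", "high_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        by_subpop: dict = {}
        for fh in self.founder_haplotypes:
            for sp, f in fh.frequencies.items():
                by_subpop[sp] = by_subpop.get(sp, 0.0) + f
        for sp, total in by_subpop.items():
            if total > 1 + 1e-9:
                raise ConfigError(f"founder frequencies exceed 1 within subpopulation {sp!r}")

    # -- site geometry -------------------------------------------------------

    def positions(self) -> list:
        """All simulated site positions, sorted ascending (1-based)."""
        gene = np.linspace(self.gene_start, self.gene_end, self.n_sites)
        gene = sorted({int(round(p)) for p in gene})
        while len(gene) < self.n_sites:  # collisions after rounding
            gene.append(max(gene) + 1)
        up = np.linspace(self.gene_start - self.flank_span, self.gene_start - 1,
                         self.flank_sites + 1)[:-1]
        down = np.linspace(self.gene_end + 1, self.gene_end + self.flank_span,
                           self.flank_sites)
        flank = sorted({int(round(p)) for p in up} | {int(round(p)) for p in down})
        diag = self.diagnostic_position()
        flank = sorted((set(flank) - {min(flank, key=lambda p: abs(p - diag))}) | {diag})
        return sorted(set(gene[: self.n_sites]) | set(flank))

    def diagnostic_position(self) -> int:
        return self.gene_start - self.diagnostic_offset

    def gene_site_mask(self, positions: Sequence[int]) -> np.ndarray:
        p = np.asarray(positions)
        return (p >= self.gene_start) & (p <= self.gene_end)

    def validate_founders(self, positions: Sequence[int]) -> None:
        if len(self.founder_haplotypes) < 2:
            raise ConfigError("need at least two founder haplotypes")
        lengths = {len(f.vector) for f in self.founder_haplotypes}
        if lengths != {len(positions)}:
            raise ConfigError("founder vectors must cover every simulated site")
        gene_mask = self.gene_site_mask(positions)
        vectors = np.array([list(f.vector) for f in self.founder_haplotypes])
        n = len(vectors)
        floor = 2 * self.cluster_radius
        for i in range(n):
            for j in range(i + 1, n):
                d = int((vectors[i, gene_mask] != vectors[j, gene_mask]).sum())
                if d <= floor:
                    raise ConfigError(
                        f"founders {i} and {j} are only {d} mismatches apart "
                        f"(need > {floor})"
                    )


@dataclass
class TruthLedger:
    """Ground truth emitted alongside a simulated panel."""

    samples: list
    founder_index: np.ndarray  # -1 for recombinants
    carrier: np.ndarray  # bool
    reference_calls: dict  # sample -> del/nodel
    flip_count: np.ndarray
    het_count: np.ndarray
    missing_count: np.ndarray
    high_missing: np.ndarray  # bool, forced high-missingness samples
    diagnostic_site_id: str
    diagnostic_alleles: tuple  # (carrier allele, background allele)
    gene_interval: tuple  # (chrom, start, end), 1-based inclusive

    def founder_of(self, sample: str) -> int:
        return int(self.founder_index[self.samples.index(sample)])

    def to_dict(self) -> dict:
        return {
            "samples": list(self.samples),
            "founder_index": self.founder_index.tolist(),
            "carrier": self.carrier.astype(bool).tolist(),
            "reference_calls": dict(self.reference_calls),
            "flip_count": self.flip_count.tolist(),
            "het_count": self.het_count.tolist(),
            "missing_count": self.missing_count.tolist(),
            "high_missing": self.high_missing.astype(bool).tolist(),
            "diagnostic_site_id": self.diagnostic_site_id,
            "diagnostic_alleles": list(self.diagnostic_alleles),
            "gene_interval": list(self.gene_interval),
        }


# ---------------------------------------------------------------------------
# default configuration mirroring the published global panel
# ---------------------------------------------------------------------------

def _build_founders(config: SimulationConfig, rng: np.random.Generator,
                    frequencies: Sequence[Mapping[str, float]]) -> list:
    """Founder vectors over all simulated sites (see module design notes)."""
    positions = config.positions()
    n_founders = len(frequencies)
    gene_mask = config.gene_site_mask(positions)
    gene_idx = np.flatnonzero(gene_mask)
    n_all = len(positions)
    bases = np.array(list("ACGT"))
    base_vec = bases[rng.integers(0, 4, size=n_all)]
    alt_vec = np.array([_other_allele(a, rng) for a in base_vec])

    block = 2 * config.cluster_radius + 4  # comfortably above the radius floor
    if (n_founders - 1) * block > gene_idx.size:
        raise ConfigError("gene region too small for the requested founder count")
    vectors = np.tile(base_vec, (n_founders, 1))
    # every founder except the deletion carrier gets a private block of
    # alternate alleles; the carrier keeps the base vector in the gene, so
    # each of its gene alleles is shared with every founder outside that
    # founder's own block -- no gene-internal site can be private to it
    k = config.indel_haplotype
    others = [i for i in range(n_founders) if i != k]
    for bi, i in enumerate(others):
        blk = gene_idx[bi * block : (bi + 1) * block]
        vectors[i, blk] = alt_vec[blk]

    # diagnostic flank site: private alternate allele on the carrier founder
    diag_idx = positions.index(config.diagnostic_position())
    vectors[:, diag_idx] = base_vec[diag_idx]
    vectors[k, diag_idx] = alt_vec[diag_idx]
    # one shared polymorphic flank site for realism (never private)
    flank_idx = np.flatnonzero(~gene_mask)
    other_flank = [i for i in flank_idx if i != diag_idx]
    if len(other_flank) >= 1 and len(others) >= 2:
        shared = other_flank[0]
        for i in (others[0], others[-1]):
            vectors[i, shared] = alt_vec[shared]

    return [
        FounderHaplotype(vector="".join(vectors[i].tolist()), frequencies=dict(freq))
        for i, freq in enumerate(frequencies)
    ]


def _other_allele(allele: str, rng: np.random.Generator) -> str:
    choices = [a for a in "ACGT" if a != allele]
    return choices[int(rng.integers(0, 3))]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default simulation: 11 founders at the published global-panel
    subpopulation frequencies, panel sizes matching the 2,932-accession
    panel, residual mass emitted as recombinants."""
    counts = refpanel.GLOBAL_COUNTS
    subpops = refpanel.SUBPOPULATIONS
    column_totals = [
        sum(counts[g][i] for g in counts) for i in range(len(subpops))
    ]
    frequencies = []
    for g in refpanel.GLOBAL_CONSENSUS:  # groups 1..11 in order
        freq = {
            sp: counts[g][i] / column_totals[i]
            for i, sp in enumerate(subpops)
            if column_totals[i]
        }
        frequencies.append(freq)
    kwargs = {
        "subpop_sizes": {sp: column_totals[i] for i, sp in enumerate(subpops)},
        "indel_haplotype": list(refpanel.GLOBAL_CONSENSUS).index(refpanel.AROMATIC_GROUP),
        "seed": seed,
    }
    kwargs.update(overrides)
    config = SimulationConfig(**kwargs)
    rng = np.random.default_rng([seed, 0xF0])
    config.founder_haplotypes = _build_founders(config, rng, frequencies)
    config.validate_founders(config.positions())
    return config


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig):
    """Generate ``(GenotypeMatrix, metadata, reference-marker table, ledger)``.

    Deterministic under a fixed config (the seed lives in the config).
    """
    positions = config.positions()
    config.validate_founders(positions)
    rng = np.random.default_rng([config.seed, 1])
    founders = np.array([list(f.vector) for f in config.founder_haplotypes])
    n_founders, n_all = founders.shape
    gene_mask = config.gene_site_mask(positions)
    diag_idx = positions.index(config.diagnostic_position())
    k = config.indel_haplotype
    diag_carrier = str(founders[k, diag_idx])
    diag_background = str(founders[(k + 1) % n_founders, diag_idx])

    samples, subpop_of, founder_idx, rows = [], [], [], []
    recomb_parents = [i for i in range(n_founders) if i != k]
    for sp, size in config.subpop_sizes.items():
        freqs = np.array([f.frequencies.get(sp, 0.0) for f in config.founder_haplotypes])
        residual = max(0.0, 1.0 - freqs.sum())
        p = np.append(freqs, residual)
        p = p / p.sum()
        draws = rng.choice(n_founders + 1, size=size, p=p)
        for d in draws:
            sid = f"S{len(samples):05d}"
            samples.append(sid)
            subpop_of.append(sp)
            if d < n_founders:
                founder_idx.append(d)
                rows.append(founders[d].copy())
            else:
                founder_idx.append(-1)
                # redraw until the recombinant is safely outside the carrier
                # founder's cluster radius (a near-end cut of two block-free
                # segments could otherwise reproduce its gene vector)
                floor = 2 * config.cluster_radius
                for _ in range(200):
                    a, b = rng.choice(recomb_parents, size=2, replace=False)
                    cut = int(rng.integers(1, n_all))
                    vec = np.concatenate([founders[a, :cut], founders[b, cut:]])
                    d = int((vec[gene_mask] != founders[k, gene_mask]).sum())
                    if d > floor:
                        break
                else:
                    raise ConfigError("could not draw a recombinant away from the carrier founder")
                vec[diag_idx] = diag_background  # recombinants are never carriers
                rows.append(vec)
    calls = np.array(rows, dtype="<U1")
    founder_idx = np.array(founder_idx)
    carrier = founder_idx == k
    n = len(samples)

    # noise: flips, then het, then missing (missing wins); the diagnostic
    # site is exempt from flips, and forced high-missingness samples get a
    # dense extra missing mask
    flip_mask = rng.random((n, n_all)) < config.mutation_noise
    flip_mask[:, diag_idx] = False
    for i, j in zip(*np.nonzero(flip_mask)):
        calls[i, j] = _other_allele(calls[i, j], rng)
    het_mask = rng.random((n, n_all)) < config.het_rate
    calls[het_mask] = HET
    missing_mask = rng.random((n, n_all)) < config.missing_rate
    high_missing = np.zeros(n, dtype=bool)
    if config.high_missing_rate > 0:
        high_missing = rng.random(n) < config.high_missing_rate
        dense = rng.random((n, n_all)) < 0.6
        missing_mask |= dense & high_missing[:, None]
    calls[missing_mask] = MISSING
    het_mask &= ~missing_mask
    flip_mask &= ~missing_mask & ~het_mask

    sites = []
    for j, pos in enumerate(positions):
        observed = frozenset(set(calls[:, j].tolist()) & set("ACGT"))
        declared = observed | {str(founders[0, j])}
        sites.append(VariantSite(chrom=config.chrom, pos=pos, alleles=frozenset(declared)))
    matrix = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    meta = [
        SampleMeta(sample_id=s, subpopulation=sp) for s, sp in zip(samples, subpop_of)
    ]
    reference_calls = {
        s: (DELETION if c else NO_DELETION) for s, c in zip(samples, carrier)
    }
    ledger = TruthLedger(
        samples=samples,
        founder_index=founder_idx,
        carrier=carrier,
        reference_calls=reference_calls,
        flip_count=flip_mask.sum(axis=1),
        het_count=het_mask.sum(axis=1),
        missing_count=missing_mask.sum(axis=1),
        high_missing=high_missing,
        diagnostic_site_id=f"{config.chrom}:{config.diagnostic_position()}",
        diagnostic_alleles=(diag_carrier, diag_background),
        gene_interval=(config.chrom, config.gene_start, config.gene_end),
    )
    return matrix, meta, reference_calls, ledger


def simulate_phenotypes(ledger: TruthLedger, config: SimulationConfig) -> list:
    """Bimodal replicated phenotypes: carrier means drawn uniformly inside
    the carrier range, non-carriers inside the non-carrier range.  Replicates
    are re-centered on the drawn mean and truncated at zero."""
    rng = np.random.default_rng([config.seed, 2])
    model = config.phenotype_model
    panels = []
    for sample, is_carrier in zip(ledger.samples, ledger.carrier):
        lo, hi = model.carrier_range if is_carrier else model.noncarrier_range
        mean = float(rng.uniform(lo, hi))
        noise = rng.normal(0.0, config.replicate_sd, size=config.n_replicates)
        noise -= noise.mean()  # replicates average exactly to the drawn mean
        reps = np.clip(mean + noise, 0.0, None)
        panels.append(PhenotypePanel(sample_id=sample, replicate_values=reps.tolist()))
    return panels


def simulate_jobs(
    samples: Sequence[str],
    n_jobs: int = 3,
    fail_rate: float = 0.0,
    ambiguous_rate: float = 0.0,
    discordance_rate: float = 0.0,
    seed: int = 0,
    true_calls: Mapping[str, str] | None = None,
    n_failed: int | None = None,
    n_ambiguous: int | None = None,
) -> pd.DataFrame:
    """Per-job call table for a repeated genotyping experiment.

    Each (sample, job) reaction either fails, comes back ambiguous, or
    yields the sample's call; non-missing repeat calls are identical unless
    ``discordance_rate`` plants discordances.  Exact counts ``n_failed`` /
    ``n_ambiguous`` override the corresponding rates when given.
    """
    for name, v in (("fail_rate", fail_rate), ("ambiguous_rate", ambiguous_rate),
                    ("discordance_rate", discordance_rate)):
        if not 0 <= v <= 1:
            raise ConfigError(f"{name} must lie in [0, 1], got {v}")
    rng = np.random.default_rng([seed, 3])
    samples = list(samples)
    base = dict(true_calls) if true_calls else {s: "G" for s in samples}
    alphabet = sorted(set(base.values()) | {"G", "T"})
    n = len(samples) * n_jobs
    status = np.zeros(n, dtype=int)  # 0 called, 1 failed, 2 ambiguous
    if n_failed is not None or n_ambiguous is not None:
        n_failed = n_failed or 0
        n_ambiguous = n_ambiguous or 0
        picks = rng.choice(n, size=n_failed + n_ambiguous, replace=False)
        status[picks[:n_failed]] = 1
        status[picks[n_failed:]] = 2
    else:
        u = rng.random(n)
        status[u < fail_rate] = 1
        status[(u >= fail_rate) & (u < fail_rate + ambiguous_rate)] = 2
    discord = rng.random(n) < discordance_rate
    records = []
    r = 0
    for s in samples:
        for job in range(1, n_jobs + 1):
            if status[r] == 1:
                call = FAILED
            elif status[r] == 2:
                call = AMBIGUOUS
            else:
                call = base[s]
                if discord[r]:
                    others = [a for a in alphabet if a != call] or [call + "*"]
                    call = others[int(rng.integers(0, len(others)))]
            records.append((s, job, call))
            r += 1
    return pd.DataFrame(records, columns=["sample", "job", "call"])
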