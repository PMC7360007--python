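"""Haplotype characterization of a gene-region genotype matrix.

The procedure treats inbred-line genotypes as haplotypes:

1. heterozygous calls are recoded to missing and high-missingness sites
   dropped (:func:`preprocess`);
2. identical call vectors are collapsed, then greedy leader clustering
   groups vectors within a Hamming radius of a group founder
   (:func:`group_haplotypes`);
3. small groups are set aside as rare (:func:`label_rare`), samples with
   too much missing data over key sites as unclassified
   (:func:`flag_unclassified`);
4. groups are summarized by consensus vectors, subgroup labels and a
   group x subpopulation cross-tabulation.

All steps are deterministic and invariant to input sample order: distinct
vectors are processed in order of descending carrier count with
lexicographic tie-breaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    HET,
    MISSING,
    EmptyPanelError,
    GenotypeMatrix,
    PanelError,
    SampleMeta,
    meta_index,
)


@dataclass
class GroupingParams:
    """Tuning knobs of the classification procedure.

    ``max_missing_per_site`` and ``min_overlap`` accept either an absolute
    count (value > 1) or a fraction of the relevant dimension (value <= 1).
    """

    max_missing_per_site: float = 100
    max_mismatch: int = 3
    min_group_fraction: float = 0.01
    min_subgroup_fraction: float = 0.01
    min_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise PanelError("max_mismatch must be >= 0")
        for name in ("min_group_fraction", "min_subgroup_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PanelError(f"{name} must lie in [0, 1], got {v}")

    def missing_threshold(self, n_samples: int) -> float:
        v = self.max_missing_per_site
        return v * n_samples if 0 < v < 1 else v

    def overlap_threshold(self, n_sites: int) -> int:
        v = self.min_overlap
        return math.ceil(v * n_sites) if 0 < v <= 1 else int(v)


@dataclass
class HaplotypeGroup:
    group_id: int
    founder_vector: str
    consensus_vector: str
    members: list
    subgroups: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeClassification:
    """Partition of panel samples into haplotype groups, rare (R) and
    unclassified (U) classes."""

    groups: list
    rare: list
    unclassified: list
    params: GroupingParams
    site_ids: list

    def group(self, group_id: int) -> HaplotypeGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"no haplotype group {group_id}")

    def all_samples(self) -> list:
        out = [s for g in self.groups for s in g.members]
        return out + list(self.rare) + list(self.unclassified)

    def membership(self) -> dict:
        """sample -> label ('1', '2', ..., 'R', 'U')."""
        out = {}
        for g in self.groups:
            for s in g.members:
                out[s] = str(g.group_id)
        for s in self.rare:
            out[s] = "R"
        for s in self.unclassified:
            out[s] = "U"
        return out

    def group_members(self) -> dict:
        return {str(g.group_id): list(g.members) for g in self.groups}

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(g.consensus_vector) for g in self.groups],
            index=[str(g.group_id) for g in self.groups],
            columns=self.site_ids,
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "site_ids": list(self.site_ids),
            "groups": [
                {
                    "group_id": g.group_id,
                    "founder_vector": g.founder_vector,
                    "consensus_vector": g.consensus_vector,
                    "members": list(g.members),
                    "subgroups": {k: list(v) for k, v in g.subgroups.items()},
                }
                for g in self.groups
            ],
            "rare": list(self.rare),
            "unclassified": list(self.unclassified),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "HaplotypeClassification":
        return cls(
            groups=[
                HaplotypeGroup(
                    group_id=g["group_id"],
                    founder_vector=g["founder_vector"],
                    consensus_vector=g["consensus_vector"],
                    members=list(g["members"]),
                    subgroups={k: list(v) for k, v in g.get("subgroups", {}).items()},
                )
                for g in payload["groups"]
            ],
            rare=list(payload["rare"]),
            unclassified=list(payload["unclassified"]),
            params=GroupingParams(**payload["params"]),
            site_ids=list(payload["site_ids"]),
        )


# ---------------------------------------------------------------------------
# step 1: preprocessing
# ---------------------------------------------------------------------------

def preprocess(matrix: GenotypeMatrix, params: GroupingParams) -> GenotypeMatrix:
    """Recode heterozygous calls to missing, then drop sites whose missing
    count exceeds ``max_missing_per_site`` (strictly greater than)."""
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise EmptyPanelError("cannot preprocess an empty matrix")
    calls = matrix.calls.copy()
    calls[calls == HET] = MISSING
    missing_per_site = (calls == MISSING).sum(axis=0)
    threshold = params.missing_threshold(matrix.n_samples)
    keep = [j for j in range(matrix.n_sites) if missing_per_site[j] <= threshold]
    if not keep:
        raise EmptyPanelError(
            "every site exceeds the missing-data threshold; raise max_missing_per_site"
        )
    out = matrix.with_calls(calls)
    return out.subset_sites(keep)


# ---------------------------------------------------------------------------
# step 2: leader clustering on collapsed vectors
# ---------------------------------------------------------------------------

def _collapse(calls: np.ndarray):
    """Distinct row vectors ordered by (count desc, vector lex asc)."""
    vectors, inverse, counts = np.unique(
        calls, axis=0, return_inverse=True, return_counts=True
    )
    # np.unique sorts rows lexicographically, so index order is the tie-break
    order = np.argsort(-counts, kind="stable")
    return vectors[order], counts[order], {int(o): r for r, o in enumerate(order)}, inverse


def masked_hamming(v: np.ndarray, w: np.ndarray) -> tuple:
    """(mismatches, overlap) over mutually non-missing sites."""
    both = (v != MISSING) & (w != MISSING)
    return int(((v != w) & both).sum()), int(both.sum())


def group_haplotypes(
    matrix: GenotypeMatrix, params: GroupingParams
) -> HaplotypeClassification:
    """Greedy leader clustering of collapsed call vectors.

    Each distinct vector, visited in order of descending carrier count,
    joins the first existing group whose founder vector lies within
    ``max_mismatch`` over mutually non-missing sites (requiring at least
    ``min_overlap`` shared sites), otherwise it founds a new group.
    Vectors too sparse to found a group are deferred to the unclassified
    pool.  Groups are numbered 1..k by descending final size.
    """
    if matrix.n_samples == 0:
        raise EmptyPanelError("cannot group an empty matrix")
    calls = matrix.calls
    n_sites = matrix.n_sites
    overlap_min = params.overlap_threshold(n_sites)
    vectors, counts, _, _ = _collapse(calls)
    founders = []  # list of founder vectors (np arrays)
    founder_matrix = np.empty((0, n_sites), dtype="<U1")
    assignment = np.full(len(vectors), -1, dtype=int)  # vector rank -> group idx
    lowdata = np.zeros(len(vectors), dtype=bool)

    for rank, vec in enumerate(vectors):
        nonmiss = vec != MISSING
        if founder_matrix.shape[0]:
            both = nonmiss[None, :] & (founder_matrix != MISSING)
            mism = ((founder_matrix != vec[None, :]) & both).sum(axis=1)
            overlap = both.sum(axis=1)
            eligible = np.flatnonzero((overlap >= overlap_min) & (mism <= params.max_mismatch))
            if eligible.size:
                assignment[rank] = int(eligible[0])
                continue
        if int(nonmiss.sum()) < overlap_min:
            lowdata[rank] = True
            continue
        assignment[rank] = len(founders)
        founders.append(vec)
        founder_matrix = np.vstack([founder_matrix, vec[None, :]])

    # map samples onto groups via their distinct-vector rank
    lex_to_rank = {vec.tobytes(): rank for rank, vec in enumerate(vectors)}
    group_members = [[] for _ in founders]
    unclassified = []
    for i, sample in enumerate(matrix.samples):
        rank = lex_to_rank[calls[i].tobytes()]
        if lowdata[rank]:
            unclassified.append(sample)
        else:
            group_members[assignment[rank]].append(sample)

    groups = []
    for gi, members in enumerate(group_members):
        vec = "".join(founders[gi].tolist())
        groups.append(
            HaplotypeGroup(
                group_id=0,
                founder_vector=vec,
                consensus_vector=vec,
                members=members,
            )
        )
    groups = _renumber(groups)
    for g in groups:
        g.consensus_vector = consensus(g, matrix)
    return HaplotypeClassification(
        groups=groups,
        rare=[],
        unclassified=unclassified,
        params=params,
        site_ids=matrix.site_ids,
    )


def _renumber(groups: Sequence[HaplotypeGroup]) -> list:
    ordered = sorted(groups, key=lambda g: (-g.size, g.founder_vector))
    for i, g in enumerate(ordered, start=1):
        g.group_id = i
    return list(ordered)


# ---------------------------------------------------------------------------
# step 3: rare and unclassified labeling
# ---------------------------------------------------------------------------

def label_rare(
    classification: HaplotypeClassification,
    params: GroupingParams | None = None,
    n_total: int | None = None,
) -> HaplotypeClassification:
    """Move groups below ``min_group_fraction`` of the panel (strictly
    less than) wholesale into the rare class; renumber the rest."""
    params = params or classification.params
    if n_total is None:
        n_total = len(classification.all_samples())
    kept, rare = [], list(classification.rare)
    for g in classification.groups:
        if n_total and g.size / n_total < params.min_group_fraction:
            rare.extend(g.members)
        else:
            kept.append(g)
    return HaplotypeClassification(
        groups=_renumber(kept),
        rare=rare,
        unclassified=list(classification.unclassified),
        params=params,
        site_ids=list(classification.site_ids),
    )


def flag_unclassified(
    matrix: GenotypeMatrix,
    classification: HaplotypeClassification,
    key_sites: Sequence[str] | None = None,
    max_missing_key: int = 0,
) -> HaplotypeClassification:
    """Move samples whose missing count over ``key_sites`` exceeds
    ``max_missing_key`` into the unclassified (U) class.

    ``key_sites`` defaults to all retained sites.  Heterozygous calls count
    as missing, matching the preprocessing recode.
    """
    site_ids = matrix.site_ids
    if key_sites is None:
        key_sites = site_ids
    unknown = sorted(set(key_sites) - set(site_ids))
    if unknown:
        raise PanelError(f"unknown key sites: {unknown}")
    cols = [site_ids.index(s) for s in key_sites]
    sub = matrix.calls[:, cols]
    n_missing = ((sub == MISSING) | (sub == HET)).sum(axis=1)
    to_u = {
        matrix.samples[i] for i in np.flatnonzero(n_missing > max_missing_key)
    }

    groups = []
    moved = []
    for g in classification.groups:
        members = [s for s in g.members if s not in to_u]
        moved.extend(s for s in g.members if s in to_u)
        if members:
            groups.append(
                HaplotypeGroup(
                    group_id=g.group_id,
                    founder_vector=g.founder_vector,
                    consensus_vector=g.consensus_vector,
                    members=members,
                    subgroups={
                        k: [s for s in v if s not in to_u] for k, v in g.subgroups.items()
                    },
                )
            )
        else:
            pass  # emptied group vanishes
    rare = [s for s in classification.rare if s not in to_u]
    moved.extend(s for s in classification.rare if s in to_u)
    unclassified = list(classification.unclassified) + moved
    return HaplotypeClassification(
        groups=_renumber(groups),
        rare=rare,
        unclassified=unclassified,
        params=classification.params,
        site_ids=list(classification.site_ids),
    )


# ---------------------------------------------------------------------------
# step 4: summaries
# ---------------------------------------------------------------------------

def consensus(group: HaplotypeGroup, matrix: GenotypeMatrix) -> str:
    """Majority non-missing allele per site (alphabetical tie-break);
    all-missing sites yield the missing code."""
    if not group.members:
        raise PanelError("consensus of an empty group")
    idx = [matrix.sample_index(s) for s in group.members]
    sub = matrix.calls[idx, :]
    out = []
    for j in range(sub.shape[1]):
        column = sub[:, j]
        valid = column[(column != MISSING) & (column != HET)]
        if valid.size == 0:
            out.append(MISSING)
            continue
        alleles, counts = np.unique(valid, return_counts=True)
        # np.unique sorts alphabetically, so argmax keeps the first (alphabetical) tie
        out.append(str(alleles[np.argmax(counts)]))
    return "".join(out)


def _subgroup_labels():
    import itertools
    import string

    for size in (1, 2):
        for letters in itertools.product(string.ascii_uppercase, repeat=size):
            label = "".join(letters)
            if label != "X" * size:
                yield label


def assign_subgroups(
    group: HaplotypeGroup, matrix: GenotypeMatrix, params: GroupingParams
) -> HaplotypeGroup:
    """Partition a group into identical-vector subgroups.

    Vector classes holding at least ``min_subgroup_fraction`` of the group
    get letters A, B, C, ... in order of descending size; the remainder is
    pooled under 'X'.
    """
    if not group.members:
        raise PanelError("cannot subgroup an empty group")
    idx = [matrix.sample_index(s) for s in group.members]
    sub = matrix.calls[idx, :]
    vectors, counts, _, _ = _collapse(sub)
    by_vector = {}
    for s, row in zip(group.members, sub):
        by_vector.setdefault(row.tobytes(), []).append(s)
    labels = _subgroup_labels()
    subgroups, pooled = {}, []
    for vec, count in zip(vectors, counts):
        members = by_vector[vec.tobytes()]
        if count / group.size >= params.min_subgroup_fraction:
            subgroups[next(labels)] = members
        else:
            pooled.extend(members)
    if pooled:
        subgroups["X"] = pooled
    group.subgroups = subgroups
    return group


def crosstab(
    classification: HaplotypeClassification, meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Group x subpopulation count table with R/U rows and margins."""
    index = meta_index(meta)
    missing = sorted(set(classification.all_samples()) - set(index))
    if missing:
        raise PanelError(f"samples without metadata: {missing[:5]}")
    subpops = sorted({m.subpopulation for m in index.values()})
    rows = {}
    for g in classification.groups:
        rows[str(g.group_id)] = g.members
    rows["R"] = classification.rare
    rows["U"] = classification.unclassified
    table = pd.DataFrame(0, index=list(rows), columns=subpops, dtype=int)
    for label, samples in rows.items():
        for s in samples:
            table.loc[label, index[s].subpopulation] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def classify(
    matrix: GenotypeMatrix,
    params: GroupingParams | None = None,
    key_sites: Sequence[str] | None = None,
    max_missing_key: int | None = None,
) -> HaplotypeClassification:
    """Run the full pipeline: preprocess, group, label rare, flag
    unclassified, and attach subgroup labels."""
    params = params or GroupingParams()
    pre = preprocess(matrix, params)
    cls = group_haplotypes(pre, params)
    cls = label_rare(cls, params, n_total=matrix.n_samples)
    if max_missing_key is None:
        # whole-vector mode: reuse the per-site missing budget per sample
        max_missing_key = int(params.missing_threshold(pre.n_sites))
    cls = flag_unclassified(pre, cls, key_sites=key_sites, max_missing_key=max_missing_key)
    for g in cls.groups:
        assign_subgroups(g, pre, params)
    return cls
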