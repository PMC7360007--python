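"""Minimal discriminating tag-SNP selection over group consensus vectors.

Discrimination is exact-match: a site resolves a pair of groups when their
consensus alleles differ at it.  :func:`greedy_select` mirrors the
sequential pick-the-most-informative-site procedure; :func:`brute_force_min`
is an exhaustive oracle for small site counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .model import HET, MISSING, GenotypeMatrix, PanelError, site_id_pos


def _pair(a: str, b: str) -> tuple:
    return tuple(sorted((a, b), key=_label_key))


def _label_key(label: str):
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


@dataclass
class TagSet:
    """An ordered tag-site selection with pairwise-resolution bookkeeping."""

    selected_sites: list
    resolved_pairs: frozenset
    unresolved_pairs: frozenset
    codes: dict

    def __post_init__(self) -> None:
        if len(set(self.selected_sites)) != len(self.selected_sites):
            raise PanelError("duplicate sites in tag set")

    @property
    def size(self) -> int:
        return len(self.selected_sites)

    def merged_labels(self) -> dict:
        """code string -> merged group label ('7/9' for colliding codes)."""
        by_code: dict = {}
        for label, code in self.codes.items():
            by_code.setdefault(code, []).append(label)
        return {
            code: "/".join(sorted(labels, key=_label_key))
            for code, labels in by_code.items()
        }

    def to_dict(self) -> dict:
        return {
            "selected_sites": list(self.selected_sites),
            "resolved_pairs": sorted(map(list, self.resolved_pairs)),
            "unresolved_pairs": sorted(map(list, self.unresolved_pairs)),
            "codes": dict(self.codes),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TagSet":
        return cls(
            selected_sites=list(payload["selected_sites"]),
            resolved_pairs=frozenset(map(tuple, payload["resolved_pairs"])),
            unresolved_pairs=frozenset(map(tuple, payload["unresolved_pairs"])),
            codes=dict(payload["codes"]),
        )


def _candidate_sites(cm: pd.DataFrame) -> list:
    """Sites eligible for selection: no missing consensus allele."""
    return [c for c in cm.columns if not (cm[c].isin([MISSING, HET])).any()]


def _pairs_resolved_by(cm: pd.DataFrame, site: str) -> frozenset:
    col = cm[site]
    return frozenset(
        _pair(a, b)
        for a, b in combinations(cm.index, 2)
        if col[a] != col[b]
    )


def group_maf(cm: pd.DataFrame) -> pd.Series:
    """Per-site minor-allele frequency across group consensus vectors,
    unweighted by group size.  Monomorphic sites get 0 (uninformative)."""
    if len(cm.index) < 2:
        raise PanelError("need at least two groups for a MAF")
    out = {}
    for site in cm.columns:
        col = [a for a in cm[site] if a not in (MISSING, HET)]
        if not col:
            out[site] = float("nan")
            continue
        _, counts = np.unique(col, return_counts=True)
        if len(counts) < 2:
            out[site] = 0.0  # monomorphic: kept but uninformative
        else:
            out[site] = float(sorted(counts)[-2] / len(col))
    return pd.Series(out)


def greedy_select(cm: pd.DataFrame, prune: bool = True) -> TagSet:
    """Iteratively add the site resolving most still-unresolved group pairs.

    Ties break toward higher group-MAF, then smaller genomic position.  When
    ``prune`` is set, a post-pass removes selected sites whose omission
    leaves the resolved-pair set unchanged.
    """
    labels = list(cm.index)
    if len(labels) < 2:
        return TagSet([], frozenset(), frozenset(), {g: "" for g in labels})
    all_pairs = frozenset(_pair(a, b) for a, b in combinations(labels, 2))
    candidates = _candidate_sites(cm)
    site_pairs = {s: _pairs_resolved_by(cm, s) for s in candidates}
    resolvable = frozenset().union(*site_pairs.values()) if site_pairs else frozenset()
    maf = group_maf(cm)

    selected: list = []
    unresolved = set(resolvable)
    while unresolved:
        best, best_key = None, None
        for s in candidates:
            if s in selected:
                continue
            gain = len(site_pairs[s] & unresolved)
            if gain == 0:
                continue
            key = (-gain, -maf[s], site_id_pos(s))
            if best_key is None or key < best_key:
                best, best_key = s, key
        if best is None:
            break
        selected.append(best)
        unresolved -= site_pairs[best]

    if prune:
        target = frozenset().union(*(site_pairs[s] for s in selected)) if selected else frozenset()
        for s in list(selected):
            rest = [t for t in selected if t != s]
            covered = frozenset().union(*(site_pairs[t] for t in rest)) if rest else frozenset()
            if covered == target:
                selected.remove(s)

    resolved = (
        frozenset().union(*(site_pairs[s] for s in selected)) if selected else frozenset()
    )
    codes = {g: "".join(cm.loc[g, s] for s in selected) for g in labels}
    return TagSet(
        selected_sites=selected,
        resolved_pairs=resolved,
        unresolved_pairs=all_pairs - resolvable,
        codes=codes,
    )


def brute_force_min(cm: pd.DataFrame, max_size: int | None = None) -> TagSet:
    """Exhaustive minimal tag set (test oracle; feasible for ~25 sites).

    Returns the smallest subset whose resolution equals that of the full
    candidate-site set; ties go to the subset whose position tuple is
    lexicographically first.  If ``max_size`` caps the search below full
    resolution, the best-covering subset of that size is returned.
    """
    labels = list(cm.index)
    if len(labels) < 2:
        return TagSet([], frozenset(), frozenset(), {g: "" for g in labels})
    all_pairs = frozenset(_pair(a, b) for a, b in combinations(labels, 2))
    candidates = sorted(_candidate_sites(cm), key=site_id_pos)
    site_pairs = {s: _pairs_resolved_by(cm, s) for s in candidates}
    resolvable = frozenset().union(*site_pairs.values()) if site_pairs else frozenset()
    limit = len(candidates) if max_size is None else min(max_size, len(candidates))

    best_partial, best_cover = (), frozenset()
    for k in range(0, limit + 1):
        for combo in combinations(candidates, k):
            covered = (
                frozenset().union(*(site_pairs[s] for s in combo)) if combo else frozenset()
            )
            if covered == resolvable:
                codes = {g: "".join(cm.loc[g, s] for s in combo) for g in labels}
                return TagSet(
                    selected_sites=list(combo),
                    resolved_pairs=covered,
                    unresolved_pairs=all_pairs - resolvable,
                    codes=codes,
                )
            if len(covered) > len(best_cover):
                best_partial, best_cover = combo, covered
    codes = {g: "".join(cm.loc[g, s] for s in best_partial) for g in labels}
    return TagSet(
        selected_sites=list(best_partial),
        resolved_pairs=best_cover,
        unresolved_pairs=all_pairs - resolvable,
        codes=codes,
    )


@dataclass(frozen=True)
class TagCall:
    """Per-sample haplotype call from tag-site alleles.

    ``status`` is one of ``unique`` (single matching group), ``merged``
    (several groups share the matching code), ``ambiguous`` (missing calls
    leave several codes compatible) or ``novel`` (no code matches).
    """

    sample: str
    status: str
    groups: tuple
    label: str


def apply_tags(matrix: GenotypeMatrix, tagset: TagSet) -> list:
    """Score each sample's tag-site alleles against the group codes."""
    missing_sites = [s for s in tagset.selected_sites if s not in matrix.site_ids]
    if missing_sites:
        raise PanelError(f"tag sites absent from matrix: {missing_sites}")
    cols = [matrix.site_index(s) for s in tagset.selected_sites]
    code_items = sorted(tagset.codes.items(), key=lambda kv: _label_key(kv[0]))
    calls = []
    for i, sample in enumerate(matrix.samples):
        alleles = matrix.calls[i, cols]
        observed = "".join(alleles)
        has_missing = any(a in (MISSING, HET) for a in alleles)
        matches = [
            g
            for g, code in code_items
            if all(a in (MISSING, HET) or a == c for a, c in zip(alleles, code))
        ]
        groups = tuple(matches)
        if not matches:
            calls.append(TagCall(sample, "novel", (), "novel"))
        elif has_missing:
            label = "?" + "/".join(matches)
            calls.append(TagCall(sample, "ambiguous" if len(matches) > 1 else "unique", groups,
                                 matches[0] if len(matches) == 1 else label))
        elif len(matches) == 1:
            calls.append(TagCall(sample, "unique", groups, matches[0]))
        else:
            calls.append(TagCall(sample, "merged", groups, "/".join(matches)))
    return calls
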