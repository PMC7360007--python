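"""Marker validation: concordance with a reference functional marker,
genotyping-job QC, and haplotype-phenotype association."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import HET, MISSING, PanelError, PhenotypePanel
from .hapgroup import HaplotypeClassification

#: sentinel call values in job tables
FAILED = "FAIL"
AMBIGUOUS = "AMBIG"
_MISSING_CALLS = {None, "", ".", "NA", MISSING, HET, FAILED, AMBIGUOUS}


@dataclass
class ConcordanceReport:
    n_samples: int
    n_compared: int
    n_concordant: int
    concordance: float
    perfect_ld: bool
    confusion: dict  # (mapped candidate state, reference state) -> count

    def __post_init__(self) -> None:
        off_diagonal = sum(v for (a, b), v in self.confusion.items() if a != b)
        if self.perfect_ld and off_diagonal:
            raise PanelError("perfect_ld set with off-diagonal confusion")


def concordance(
    candidate_calls: Mapping[str, str],
    reference_calls: Mapping[str, str],
    mapping: Mapping[str, str],
    min_compared: int = 30,
) -> ConcordanceReport:
    """Compare allele calls against reference functional-marker states.

    ``mapping`` declares the allele -> state correspondence (e.g.
    ``{"T": "del", "G": "nodel"}``).  Samples missing either call are
    excluded from ``n_compared`` but still counted in ``n_samples``.
    """
    shared = [s for s in candidate_calls if s in reference_calls]
    if not shared:
        raise PanelError("candidate and reference call sets share no samples")
    n_compared = n_concordant = 0
    confusion: dict = {}
    for s in shared:
        cand, ref = candidate_calls[s], reference_calls[s]
        if cand in _MISSING_CALLS or ref in _MISSING_CALLS:
            continue
        if cand not in mapping:
            raise PanelError(f"allele {cand!r} for {s} has no declared state mapping")
        state = mapping[cand]
        n_compared += 1
        confusion[(state, ref)] = confusion.get((state, ref), 0) + 1
        if state == ref:
            n_concordant += 1
    rate = n_concordant / n_compared if n_compared else 0.0
    return ConcordanceReport(
        n_samples=len(shared),
        n_compared=n_compared,
        n_concordant=n_concordant,
        concordance=rate,
        perfect_ld=(n_compared >= min_compared and n_concordant == n_compared),
        confusion=confusion,
    )


@dataclass
class AssayQC:
    n_lines: int
    n_jobs: int
    n_reactions: int
    n_failed: int
    n_ambiguous: int
    call_rate: float
    reproducibility: float

    @property
    def n_missing(self) -> int:
        return self.n_failed + self.n_ambiguous


def assay_qc(job_calls: pd.DataFrame) -> AssayQC:
    """QC summary of a per-job call table (columns ``sample``, ``job``,
    ``call``; failed and ambiguous reactions both count as missing).

    Reproducibility is the fraction of samples with >=2 non-missing calls
    whose calls are all identical; order of rows is irrelevant.
    """
    required = {"sample", "job", "call"}
    if not required <= set(job_calls.columns):
        raise PanelError(f"job table needs columns {sorted(required)}")
    samples = job_calls["sample"].unique()
    jobs = job_calls["job"].unique()
    n_lines, n_jobs = len(samples), len(jobs)
    n_reactions = n_lines * n_jobs
    if len(job_calls) != n_reactions:
        raise PanelError("job table is not a complete samples x jobs design")
    calls = job_calls["call"]
    n_failed = int((calls == FAILED).sum())
    n_ambiguous = int((calls == AMBIGUOUS).sum())
    n_missing = int(calls.isin(list(_MISSING_CALLS - {None})).sum() + calls.isna().sum())
    call_rate = (n_reactions - n_missing) / n_reactions if n_reactions else 0.0

    multi = concordant = 0
    for _, grp in job_calls.groupby("sample"):
        ok = grp["call"][~grp["call"].isna() & ~grp["call"].isin(list(_MISSING_CALLS - {None}))]
        if len(ok) >= 2:
            multi += 1
            if ok.nunique() == 1:
                concordant += 1
    reproducibility = concordant / multi if multi else 1.0
    return AssayQC(
        n_lines=n_lines,
        n_jobs=n_jobs,
        n_reactions=n_reactions,
        n_failed=n_failed,
        n_ambiguous=n_ambiguous,
        call_rate=call_rate,
        reproducibility=reproducibility,
    )


@dataclass
class GroupPhenotype:
    label: str
    n: int
    min: float
    max: float
    mean: float
    se: float
    verdict: str  # aromatic / non-aromatic / mixed


@dataclass
class AromaAssociation:
    threshold: float
    per_group: dict  # label -> GroupPhenotype
    perfect_association: bool


def _group_map(groups) -> dict:
    if isinstance(groups, HaplotypeClassification):
        return groups.group_members()
    return {str(k): list(v) for k, v in dict(groups).items()}


def aroma_association(
    groups,
    phenotypes: Iterable[PhenotypePanel] | Mapping[str, float],
    threshold_ppm: float = 0.2,
) -> AromaAssociation:
    """Per-group phenotype summary and aromatic/non-aromatic verdicts.

    ``groups`` is a classification or a ``label -> member list`` mapping.
    A group is aromatic when every phenotyped member exceeds the threshold,
    non-aromatic when none does, otherwise mixed.  ``perfect_association``
    requires exactly one aromatic group and no mixed group.
    """
    members = _group_map(groups)
    if isinstance(phenotypes, Mapping):
        values = {s: float(v) for s, v in phenotypes.items()}
    else:
        values = {p.sample_id: p.mean_value for p in phenotypes}
    per_group: dict = {}
    for label, samples in members.items():
        obs = np.array([values[s] for s in samples if s in values], dtype=float)
        if obs.size == 0:
            warnings.warn(f"group {label} has no phenotyped members; excluded", stacklevel=2)
            continue
        if np.all(obs > threshold_ppm):
            verdict = "aromatic"
        elif np.all(obs <= threshold_ppm):
            verdict = "non-aromatic"
        else:
            verdict = "mixed"
        se = float(np.std(obs, ddof=1) / np.sqrt(obs.size)) if obs.size > 1 else 0.0
        per_group[label] = GroupPhenotype(
            label=label,
            n=int(obs.size),
            min=float(obs.min()),
            max=float(obs.max()),
            mean=float(obs.mean()),
            se=se,
            verdict=verdict,
        )
    verdicts = [g.verdict for g in per_group.values()]
    perfect = verdicts.count("aromatic") == 1 and verdicts.count("mixed") == 0
    return AromaAssociation(
        threshold=threshold_ppm, per_group=per_group, perfect_association=perfect
    )
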