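import numpy as np
import pytest

from haplomark import refpanel
from haplomark.hapgroup import GroupingParams, HaplotypeClassification, HaplotypeGroup
from haplomark.model import MISSING, matrix_from_vectors


def make_matrix(rows, positions=None, chrom="Chr1", samples=None):
    """Matrix from a list of allele strings (H/N allowed)."""
    rows = [str(r) for r in rows]
    n_sites = len(rows[0])
    if positions is None:
        positions = [100 + 10 * j for j in range(n_sites)]
    if samples is None:
        samples = [f"s{i}" for i in range(len(rows))]
    return matrix_from_vectors(dict(zip(samples, rows)), positions, chrom=chrom)


def random_matrix(rng, n_samples=20, n_sites=10, missing_rate=0.1, het_rate=0.05,
                  chrom="Chr1"):
    """Random biallelic-ish matrix with noise, guaranteed valid."""
    bases = np.array(list("ACGT"))
    alleles = bases[rng.integers(0, 4, size=(2, n_sites))]
    pick = rng.integers(0, 2, size=(n_samples, n_sites))
    calls = alleles[pick, np.arange(n_sites)]
    calls[rng.random((n_samples, n_sites)) < het_rate] = "H"
    calls[rng.random((n_samples, n_sites)) < missing_rate] = MISSING
    rows = ["".join(r) for r in calls]
    return make_matrix(rows, positions=[50 + 7 * j for j in range(n_sites)], chrom=chrom)


def classification_from_members(members_by_group, site_ids=None, consensus=None):
    """Build a classification directly from a {group_id: [samples]} map."""
    groups = []
    for gid, members in members_by_group.items():
        vec = (consensus or {}).get(gid, "")
        groups.append(
            HaplotypeGroup(
                group_id=int(gid), founder_vector=vec, consensus_vector=vec,
                members=list(members),
            )
        )
    return HaplotypeClassification(
        groups=groups, rare=[], unclassified=[], params=GroupingParams(),
        site_ids=site_ids or [],
    )


@pytest.fixture
def consensus_fixture():
    """The bundled 11-group consensus matrix as a GenotypeMatrix plus a
    one-sample-per-group classification."""
    matrix = refpanel.consensus_genotypes()
    cls = classification_from_members(
        {g: [f"Hap{g}"] for g in refpanel.GLOBAL_CONSENSUS},
        site_ids=matrix.site_ids,
    )
    return matrix, cls


@pytest.fixture(scope="session")
def small_panel():
    """A small zero-noise simulated panel shared across tests."""
    from haplomark import synth_panel

    cfg = synth_panel.default_config(
        seed=7,
        subpop_sizes={"indica": 120, "aromatic": 40, "tropical japonica": 60},
        mutation_noise=0.0,
        het_rate=0.0,
        missing_rate=0.0,
    )
    matrix, meta, reference, ledger = synth_panel.simulate_panel(cfg)
    return cfg, matrix, meta, reference, ledger
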