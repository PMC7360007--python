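"""Readers and writers for all external file representations.

Formats
-------
* VCF v4.x (plain text; read via :mod:`cyvcf2`, written by a minimal
  site-level writer). Only single-nucleotide records enter the matrix;
  indels are left to the separate reference-marker table.
* Allele-call matrix TSV: first column ``sample``, one column per site
  (header ``chrom:pos``), cells ``A/C/G/T``, ``H`` for heterozygous and
  ``.``/``N`` for missing.
* Metadata TSV: ``sample`` and ``subpopulation`` columns plus free extras.
* Phenotype TSV: ``sample`` plus one or more replicate columns.
* Haplotype report TSV mirroring the group x subpopulation summary layout.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import (
    HET,
    MISSING,
    GenotypeMatrix,
    PanelError,
    PhenotypePanel,
    SampleMeta,
    VariantSite,
    meta_index,
)

_TSV_MISSING = {".", "N", "", "NA"}


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_genotypes(path, region=None, format=None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or matrix TSV.

    ``region`` is the internal 0-based half-open ``(chrom, start, end)``
    triple (see :func:`haplomark.model.parse_region`).  ``format`` is
    ``"vcf"`` or ``"tsv"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        matrix = _read_vcf(path)
    elif format in {"tsv", "matrix-tsv"}:
        matrix = _read_matrix_tsv(path)
    else:
        raise PanelError(f"unknown genotype format {format!r}")
    if region is not None:
        matrix = _filter_region(matrix, region)
    return matrix


def _filter_region(matrix: GenotypeMatrix, region) -> GenotypeMatrix:
    chrom, start, end = region
    keep = [
        j
        for j, s in enumerate(matrix.sites)
        if s.chrom == chrom and start <= s.pos - 1 < end
    ]
    out = matrix.subset_sites(keep)
    out.region = (chrom, start, end)
    return out


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise PanelError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise PanelError(f"VCF {path} carries no genotype columns")
    sites, columns = [], []
    for record in vcf:
        alleles = [record.REF] + list(record.ALT)
        if any(len(a) != 1 or a not in "ACGT" for a in alleles):
            continue  # indel / symbolic allele: excluded from the SNP matrix
        column = np.empty(len(samples), dtype="<U1")
        for i, gt in enumerate(record.genotypes):
            a, b = gt[0], gt[1] if len(gt) > 2 else gt[0]
            if a < 0 or b < 0:
                column[i] = MISSING
            elif a != b:
                column[i] = HET
            else:
                column[i] = alleles[a]
        observed = frozenset(set(column.tolist()) & set("ACGT"))
        sites.append(VariantSite(chrom=record.CHROM, pos=record.POS, alleles=observed))
        columns.append(column)
    vcf.close()
    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype="<U1")
    )
    order = sorted(range(len(sites)), key=lambda j: (sites[j].chrom, sites[j].pos))
    sites = [sites[j] for j in order]
    calls = calls[:, order] if sites else calls
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal single-sample-per-column VCF (sites as unphased
    homozygous diploid genotypes; HET as 0/1, MISSING as ./.)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {s.chrom for s in matrix.sites}
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            column = matrix.calls[:, j]
            present = sorted(set(column.tolist()) & set("ACGT"))
            if not present:
                continue
            ref, alts = present[0], present[1:]
            if not alts and HET in column:
                # a het call needs a representable second allele
                alts = [next(a for a in "ACGT" if a != ref)]
            if not alts:
                alts = ["."]
            allele_code = {a: str(i) for i, a in enumerate(present)}
            gts = []
            for call in column:
                if call == MISSING:
                    gts.append("./.")
                elif call == HET:
                    gts.append("0/1")
                else:
                    code = allele_code[call]
                    gts.append(f"{code}/{code}")
            alt_field = ",".join(alts)
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id}\t{ref}\t{alt_field}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PanelError(f"{path}: empty matrix file") from None
        site_ids = header[1:]
        positions, chroms = [], []
        for lineno, sid in enumerate(site_ids, start=2):
            try:
                chrom, pos = sid.rsplit(":", 1)
                positions.append(int(pos))
                chroms.append(chrom)
            except ValueError:
                raise PanelError(f"{path}: malformed site ID {sid!r} in header") from None
        samples, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise PanelError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            samples.append(row[0])
            cells = []
            for sid, cell in zip(site_ids, row[1:]):
                cell = cell.strip().upper()
                if cell in _TSV_MISSING:
                    cells.append(MISSING)
                elif cell in {"H", HET}:
                    cells.append(HET)
                elif cell in "ACGT" and len(cell) == 1:
                    cells.append(cell)
                else:
                    raise PanelError(f"{path}:{lineno}: bad allele call {cell!r} at {sid}")
            rows.append(cells)
    raw = (
        np.array(rows, dtype="<U1") if rows else np.empty((0, len(site_ids)), dtype="<U1")
    )
    order = sorted(range(len(site_ids)), key=lambda j: (chroms[j], positions[j]))
    sites = []
    for j in order:
        observed = frozenset(set(raw[:, j].tolist()) & set("ACGT")) if len(rows) else frozenset()
        sites.append(VariantSite(chrom=chroms[j], pos=positions[j], alleles=observed))
    calls = raw[:, order] if len(site_ids) else raw
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample"] + matrix.site_ids)
        for i, sample in enumerate(matrix.samples):
            writer.writerow([sample] + matrix.calls[i].tolist())


# ---------------------------------------------------------------------------
# metadata and phenotypes
# ---------------------------------------------------------------------------

def read_metadata(path) -> list:
    """Read sample metadata (``sample``, ``subpopulation`` + extras)."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        lowered = {f.lower(): f for f in fields}
        sample_col = lowered.get("sample") or lowered.get("sample_id")
        subpop_col = lowered.get("subpopulation")
        if sample_col is None or subpop_col is None:
            raise PanelError(f"{path}: metadata needs 'sample' and 'subpopulation' columns")
        extras = [f for f in fields if f not in {sample_col, subpop_col}]
        records, seen = [], set()
        for row in reader:
            sid = row[sample_col]
            if sid in seen:
                raise PanelError(f"{path}: duplicate sample ID {sid!r}")
            seen.add(sid)
            attributes = {k: row[k] for k in extras if row.get(k) not in (None, "")}
            records.append(
                SampleMeta(sample_id=sid, subpopulation=row[subpop_col], attributes=attributes)
            )
    return records


def write_metadata(meta: Iterable[SampleMeta], path) -> None:
    meta = list(meta)
    extra_keys = sorted({k for m in meta for k in m.attributes})
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "subpopulation"] + extra_keys)
        for m in meta:
            writer.writerow(
                [m.sample_id, m.subpopulation] + [m.attributes.get(k, "") for k in extra_keys]
            )


def read_phenotypes(path) -> list:
    """Read a replicated phenotype table (``sample``, ``rep1``..``repN``).

    Missing replicate cells are ignored; the per-sample mean is the
    arithmetic mean of the replicates present.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        lowered = {f.lower(): f for f in fields}
        sample_col = lowered.get("sample") or lowered.get("sample_id")
        if sample_col is None:
            raise PanelError(f"{path}: phenotype table needs a 'sample' column")
        rep_cols = [f for f in fields if f != sample_col]
        if not rep_cols:
            raise PanelError(f"{path}: phenotype table needs >=1 replicate column")
        panels = []
        for row in reader:
            values = []
            for col in rep_cols:
                cell = (row.get(col) or "").strip()
                if cell in _TSV_MISSING:
                    continue
                values.append(float(cell))
            panels.append(PhenotypePanel(sample_id=row[sample_col], replicate_values=values))
    return panels


def write_phenotypes(panels: Iterable[PhenotypePanel], path) -> None:
    panels = list(panels)
    n_reps = max(len(p.replicate_values) for p in panels)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample"] + [f"rep{i + 1}" for i in range(n_reps)])
        for p in panels:
            row = [f"{v:.6g}" for v in p.replicate_values]
            row += [""] * (n_reps - len(row))
            writer.writerow([p.sample_id] + row)


# ---------------------------------------------------------------------------
# haplotype report
# ---------------------------------------------------------------------------

def write_haplotype_report(classification, meta: Sequence[SampleMeta], path) -> None:
    """Write a per-group TSV: counts per subpopulation, total, consensus
    string, plus R and U rows.  Row totals sum to the panel size."""
    index = meta_index(meta)
    missing = sorted(set(classification.all_samples()) - set(index))
    if missing:
        raise PanelError(f"samples missing from metadata: {missing[:5]}")
    subpops = sorted({m.subpopulation for m in index.values()})

    def tally(samples):
        counts = dict.fromkeys(subpops, 0)
        for s in samples:
            counts[index[s].subpopulation] += 1
        return counts

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group"] + subpops + ["total", "consensus"])
        for group in classification.groups:
            counts = tally(group.members)
            writer.writerow(
                [group.group_id]
                + [counts[s] for s in subpops]
                + [len(group.members), group.consensus_vector]
            )
        for label, samples in (("R", classification.rare), ("U", classification.unclassified)):
            counts = tally(samples)
            writer.writerow([label] + [counts[s] for s in subpops] + [len(samples), ""])
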