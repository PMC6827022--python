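"""The genotype matrix: consolidation of per-sample variant calls.

The analysis starts from a sites x samples table of diploid genotype call
strings ("AA", "AT", ..., "NN" for missing), built by taking the union of
all sites with a variant call in any input VCF.  A sample with no record at
a site is assigned "NN" — absence of a call is treated as *unknown*, not as
homozygous reference, because per-sample VCFs typically omit ref/ref sites.
This is conservative and affects which sites can become key sites: a site
only observed in one species' files will have a missing major genotype in
the other species and be filtered out.

Indels are excluded by default; the downstream segregation test and CAPS
design operate on SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .exceptions import (
    FormatError,
    InputConsistencyError,
    LabelingError,
)

MISSING = "NN"
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteCoord:
    """A single-nucleotide site on the reference, 1-based."""

    seqid: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> str:
        return f"{self.seqid}:{self.pos}"


def normalize_genotype(a: str, b: str) -> str:
    """Canonical genotype string: alphabetically sorted allele pair."""
    return a + b if a <= b else b + a


class GenotypeMatrix:
    """Sites x samples table of genotype call strings with species labels.

    ``calls`` is a pandas DataFrame indexed by site key ("seqid:pos"), one
    column per sample.  Exactly two species labels must be present.
    """

    def __init__(
        self,
        sites: Sequence[SiteCoord],
        samples: Sequence[str],
        labels: Mapping[str, str],
        calls: pd.DataFrame,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.labels = dict(labels)
        self.calls = calls

        if calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(self.sites)}, {len(self.samples)})"
            )
        unlabeled = [s for s in self.samples if s not in self.labels]
        if unlabeled:
            raise LabelingError(f"samples without species label: {unlabeled}")
        species = sorted({self.labels[s] for s in self.samples})
        if len(species) != 2:
            raise LabelingError(
                f"exactly two species labels required, got {species}"
            )
        self.species: tuple[str, str] = (species[0], species[1])
        self._by_species = {
            sp: [s for s in self.samples if self.labels[s] == sp] for sp in species
        }

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def samples_of(self, species: str) -> list[str]:
        return self._by_species[species]

    def site(self, key: str) -> SiteCoord:
        return self._site_map[key]

    @property
    def _site_map(self) -> dict[str, SiteCoord]:
        cached = getattr(self, "_site_map_cache", None)
        if cached is None:
            cached = {s.key: s for s in self.sites}
            self._site_map_cache = cached
        return cached

    def calls_at(self, key: str) -> pd.Series:
        return self.calls.loc[key]

    def validate_calls(self) -> None:
        """Check every call is "NN" or a two-base string over ACGT."""
        vals = pd.unique(self.calls.values.ravel())
        bad = [
            v
            for v in vals
            if v != MISSING and not (len(v) == 2 and set(v) <= _BASES)
        ]
        if bad:
            raise FormatError(f"invalid genotype strings: {bad[:5]}")


# ---------------------------------------------------------------------------
# label table
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a sample→species TSV (two columns, optional header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "species"]:
        # headerless file: first row is data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample_id", "species"])
    if df.shape[1] < 2 or df["sample_id"].isna().any() or df["species"].isna().any():
        raise FormatError(f"malformed label table: {path}")
    return dict(zip(df["sample_id"], df["species"]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\n")
        for s, sp in labels.items():
            fh.write(f"{s}\t{sp}\n")


# ---------------------------------------------------------------------------
# VCF consolidation
# ---------------------------------------------------------------------------

def _genotype_from_bases(gt: str) -> str:
    """Map a cyvcf2 gt_bases string ("T/T", "./.", "T") to a call string."""
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) == 1:  # haploid call represented as homozygous diploid
        alleles = alleles * 2
    if any(a in (".", "") for a in alleles):
        return MISSING
    if any(len(a) != 1 or a not in _BASES for a in alleles):
        return ""  # indel / symbolic allele: caller decides
    return normalize_genotype(alleles[0], alleles[1])


def consolidate(
    vcf_paths: Iterable[str | Path],
    labels: Mapping[str, str] | str | Path,
    *,
    keep_indels: bool = False,
) -> GenotypeMatrix:
    """Merge one or more VCFs into a genotype matrix.

    The site set is the union over all inputs; samples lacking a record at a
    site get "NN".  Multiallelic records contribute whatever allele pair each
    sample carries.  Records with non-SNP alleles are skipped unless
    ``keep_indels`` (then the genotype is kept as an opaque token only if it
    is a pair of single bases, otherwise the sample is set missing).
    """
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)

    site_ref: dict[tuple[str, int], str] = {}
    site_alts: dict[tuple[str, int], set[str]] = {}
    per_site_calls: dict[tuple[str, int], dict[str, str]] = {}
    all_samples: list[str] = []

    for path in vcf_paths:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        dup = set(samples) & set(all_samples)
        if dup:
            raise InputConsistencyError(f"sample(s) in more than one VCF: {sorted(dup)}")
        missing_labels = [s for s in samples if s not in labels]
        if missing_labels:
            raise LabelingError(f"unlabeled sample(s): {missing_labels}")
        all_samples.extend(samples)

        for var in vcf:
            ref = var.REF.upper()
            alts = [a.upper() for a in (var.ALT or [])]
            is_snp = len(ref) == 1 and ref in _BASES and all(
                len(a) == 1 and a in _BASES for a in alts
            )
            if not is_snp and not keep_indels:
                continue
            coord = (var.CHROM, var.POS)
            if coord in site_ref and site_ref[coord] != ref:
                raise InputConsistencyError(
                    f"conflicting REF alleles at {coord[0]}:{coord[1]}: "
                    f"{site_ref[coord]} vs {ref}"
                )
            site_ref.setdefault(coord, ref)
            alt_set = site_alts.setdefault(coord, set())
            calls = per_site_calls.setdefault(coord, {})
            for sample, gt in zip(samples, var.gt_bases):
                call = _genotype_from_bases(str(gt))
                if call == "":
                    call = MISSING
                calls[sample] = call
                for a in call:
                    if a in _BASES and a != ref:
                        alt_set.add(a)
        vcf.close()

    coords = sorted(site_ref)
    sites = [
        SiteCoord(c[0], c[1], site_ref[c], tuple(sorted(site_alts[c])))
        for c in coords
    ]
    data = np.full((len(sites), len(all_samples)), MISSING, dtype=object)
    for i, c in enumerate(coords):
        calls = per_site_calls[c]
        for j, s in enumerate(all_samples):
            if s in calls:
                data[i, j] = calls[s]
    frame = pd.DataFrame(data, index=[s.key for s in sites], columns=all_samples)
    used_labels = {s: labels[s] for s in all_samples}
    return GenotypeMatrix(sites, all_samples, used_labels, frame)


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Serialize the matrix as a multi-sample VCF 4.2 with GT fields."""
    contigs: dict[str, int] = {}
    for s in matrix.sites:
        contigs[s.seqid] = max(contigs.get(s.seqid, 0), s.pos)
    if contig_lengths:
        contigs.update(contig_lengths)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=capskit\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        order = sorted(range(matrix.n_sites),
                       key=lambda i: (matrix.sites[i].seqid, matrix.sites[i].pos))
        for i in order:
            site = matrix.sites[i]
            row = matrix.calls.iloc[i]
            observed = set("".join(g for g in row if g != MISSING))
            alts = sorted((observed | set(site.alt_alleles)) - {site.ref_allele})
            allele_idx = {site.ref_allele: 0}
            allele_idx.update({a: k + 1 for k, a in enumerate(alts)})
            gts = []
            for g in row:
                if g == MISSING:
                    gts.append("./.")
                else:
                    ia, ib = sorted((allele_idx[g[0]], allele_idx[g[1]]))
                    gts.append(f"{ia}/{ib}")
            alt_field = ",".join(alts) if alts else "."
            fh.write(
                f"{site.seqid}\t{site.pos}\t.\t{site.ref_allele}\t{alt_field}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write sites as rows: seqid, pos, ref, alts, then one column per sample."""
    df = pd.DataFrame(
        {
            "seqid": [s.seqid for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "ref": [s.ref_allele for s in matrix.sites],
            "alts": [",".join(s.alt_alleles) for s in matrix.sites],
        }
    )
    out = pd.concat([df, matrix.calls.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, labels: Mapping[str, str] | str | Path
                    ) -> GenotypeMatrix:
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)
    df = pd.read_csv(path, sep="\t", dtype={"seqid": str, "pos": int}, keep_default_na=False)
    meta_cols = ["seqid", "pos", "ref", "alts"]
    if list(df.columns[:4]) != meta_cols:
        raise FormatError(f"not a capskit matrix TSV: {path}")
    samples = [c for c in df.columns if c not in meta_cols]
    sites = [
        SiteCoord(r.seqid, int(r.pos), r.ref,
                  tuple(a for a in str(r.alts).split(",") if a))
        for r in df.itertuples()
    ]
    calls = df[samples].astype(str)
    calls.index = [s.key for s in sites]
    return GenotypeMatrix(sites, samples, {s: labels[s] for s in samples}, calls)


# ---------------------------------------------------------------------------
# major genotypes and the candidate-site filter
# ---------------------------------------------------------------------------

def major_genotypes(matrix: GenotypeMatrix, site_key: str) -> dict[str, str]:
    """Most frequent genotype per species at a site.

    "NN" competes as a category (the filter below must be able to see a
    missing major genotype).  Ties break to the lexicographically smallest
    genotype string.
    """
    row = matrix.calls_at(site_key)
    majors: dict[str, str] = {}
    for sp in matrix.species:
        counts = row[matrix.samples_of(sp)].value_counts()
        top = counts.max()
        majors[sp] = min(g for g, c in counts.items() if c == top)
    return majors


#: removal-rule tags used in the filter log
RULE_MISSING_MAJOR = "missing_major"
RULE_IDENTICAL_MAJOR = "identical_major"


def filter_candidate_sites(matrix: GenotypeMatrix
                           ) -> tuple[list[str], pd.DataFrame]:
    """Apply the candidate-site filter.

    A site is removed iff either species' major genotype is "NN", or the two
    species share the same major genotype.  Returns kept site keys (in input
    order) and a removal log with the triggering rule and the majors.
    """
    kept: list[str] = []
    removed: list[dict[str, object]] = []
    a, b = matrix.species
    for site in matrix.sites:
        majors = major_genotypes(matrix, site.key)
        g_a, g_b = majors[a], majors[b]
        if g_a == MISSING or g_b == MISSING:
            rule = RULE_MISSING_MAJOR
        elif g_a == g_b:
            rule = RULE_IDENTICAL_MAJOR
        else:
            kept.append(site.key)
            continue
        removed.append(
            {"seqid": site.seqid, "pos": site.pos, "rule": rule,
             "major_a": g_a, "major_b": g_b}
        )
    log = pd.DataFrame(removed, columns=["seqid", "pos", "rule", "major_a", "major_b"])
    return kept, log
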