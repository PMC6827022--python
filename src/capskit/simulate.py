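"""Synthetic genotype matrices, references, and annotations with ground truth.

The generator emulates the structure of a consolidated two-species genotype
matrix: two species with highly imbalanced sample counts (default 38 vs 5,
as in a quarantine setting where one species is densely resequenced), a
minority of perfectly species-segregating (diagnostic) sites, abundant
sample-specific polymorphism independent of species, missing calls ("NN"),
and genotyping noise.  A matching reference sequence and gene annotation
are generated so the whole pipeline — consolidation, segregation testing,
gene scoring, and CAPS design — runs end-to-end offline, and every stage
can be checked against recorded ground truth.

Diagnostic sites carry two distinct homozygous genotypes, one per species
(the fixed-difference pattern of between-species haplotypes); haploid males
are represented as homozygous diploids, as genotype callers do.  A chosen
subset of diagnostic sites is "implanted" as CAPS sites: the reference
context around them forms a restriction enzyme's recognition site under the
species-A allele and not under the species-B allele.  All other diagnostic
sites are scrubbed so no recognition site of any listed enzyme overlaps
them under either allele — implanted markers are therefore exactly the
recoverable ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caps import match_starts
from .enzymes import Enzyme, load_enzymes
from .exceptions import GenerationError, ParameterError
from .genes import GeneModel, write_gff3
from .iupac import expand
from .matrix import MISSING, GenotypeMatrix, SiteCoord, write_labels, write_vcf

_BASES = np.array(list("ACGT"))

#: reference margin left free of sites, so primers fit around any site
_MARGIN = 350
#: minimum spacing between simulated sites; keeps enzyme-motif windows disjoint
_MIN_GAP = 15

SEQID = "ctg1"
SPECIES_A = "speciesA"
SPECIES_B = "speciesB"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic dataset.

    Defaults mirror the consolidated fire-ant matrix at desk scale: 38 + 5
    samples, a small fraction of truly diagnostic sites among abundant
    sample-specific polymorphism, a few percent missing calls and a little
    genotyping noise.
    """

    n_species_a: int = 38
    n_species_b: int = 5
    n_sites: int = 5000
    frac_diagnostic: float = 0.05
    missing_rate: float = 0.02
    noise_rate: float = 0.01
    n_genes: int = 40
    genome_length: int = 500_000
    n_caps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species_a, self.n_species_b, self.n_sites,
               self.n_genes, self.genome_length, self.n_caps) < 0:
            raise ParameterError("counts must be non-negative")
        if self.n_species_a + self.n_species_b < 2:
            raise ParameterError("need at least two samples in total")
        for name in ("frac_diagnostic", "missing_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ImplantedCaps:
    """Ground truth for one implanted CAPS site."""

    site_key: str
    enzyme: str
    allele: str              # the allele creating the recognition site
    recognition_offset: int  # site position within the recognition motif


@dataclass(frozen=True)
class SiteRecord:
    """Per-site generation detail needed to build a consistent reference."""

    seqid: str
    pos: int
    ref: str
    allele_a: str | None
    allele_b: str | None
    diagnostic: bool

    @property
    def key(self) -> str:
        return f"{self.seqid}:{self.pos}"


@dataclass
class SyntheticTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    diagnostic_sites: set[str]
    site_to_gene: dict[str, str] = field(default_factory=dict)
    implanted_caps: list[ImplantedCaps] = field(default_factory=list)
    site_records: list[SiteRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def _sample_positions(rng: np.random.Generator, params: SimulationParams
                      ) -> np.ndarray:
    lo, hi = _MARGIN, params.genome_length - _MARGIN
    if hi - lo < params.n_sites * _MIN_GAP:
        raise ParameterError(
            f"genome_length {params.genome_length} too small for "
            f"{params.n_sites} sites at {_MIN_GAP} bp spacing"
        )
    pool = rng.choice(np.arange(lo, hi), size=min(hi - lo, 6 * params.n_sites),
                      replace=False)
    pool.sort()
    kept: list[int] = []
    last = -(10 * _MIN_GAP)
    for p in pool:
        if p - last >= _MIN_GAP:
            kept.append(int(p))
            last = p
        if len(kept) == params.n_sites:
            break
    if len(kept) < params.n_sites:
        raise GenerationError(
            f"could only place {len(kept)} of {params.n_sites} sites; "
            "increase genome_length"
        )
    return np.array(kept)


def _pick_other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def generate_matrix(
    params: SimulationParams,
    enzymes: list[Enzyme] | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate a genotype matrix and its ground truth.

    Diagnostic sites get one fixed homozygous genotype per species (before
    noise and missingness); other sites draw genotypes independently of
    species.  ``n_caps`` diagnostic sites are reserved as CAPS implants,
    with the species-A allele chosen to match a concrete base of the
    assigned enzyme's recognition motif.  Same params (and enzyme table)
    always produce identical output.
    """
    if enzymes is None:
        enzymes = load_enzymes()
    rng = np.random.default_rng(params.seed)
    n_a, n_b = params.n_species_a, params.n_species_b
    n = n_a + n_b

    samples = [f"A{i + 1:02d}" for i in range(n_a)] + \
              [f"B{i + 1:02d}" for i in range(n_b)]
    labels = {s: (SPECIES_A if s.startswith("A") else SPECIES_B) for s in samples}

    positions = _sample_positions(rng, params)
    n_diag = round(params.frac_diagnostic * params.n_sites)
    if params.n_caps > n_diag:
        raise ParameterError(
            f"n_caps={params.n_caps} exceeds diagnostic site count {n_diag}"
        )
    diag_idx = set(
        rng.choice(params.n_sites, size=n_diag, replace=False).tolist()
    ) if n_diag else set()
    implant_idx = sorted(diag_idx)[: params.n_caps] if params.n_caps else []

    # assign enzymes to implants round-robin; the species-A allele must be a
    # concrete base of the motif so the reference can realize it
    implant_plan: dict[int, tuple[Enzyme, int]] = {}
    usable = [e for e in enzymes if any(len(expand(c)) == 1 for c in e.recognition)]
    if implant_idx and not usable:
        raise GenerationError("no enzyme with a concrete recognition base")
    for k, i in enumerate(implant_idx):
        enz = usable[k % len(usable)]
        concrete = [j for j, c in enumerate(enz.recognition) if len(expand(c)) == 1]
        implant_plan[i] = (enz, concrete[int(rng.integers(len(concrete)))])

    calls = np.empty((params.n_sites, n), dtype=object)
    records: list[SiteRecord] = []
    truth = SyntheticTruth(diagnostic_sites=set())

    for i, pos in enumerate(positions):
        if i in diag_idx:
            if i in implant_plan:
                enz, off = implant_plan[i]
                allele_a = enz.recognition[off]
            else:
                allele_a = str(_BASES[rng.integers(4)])
            allele_b = _pick_other_base(rng, allele_a)
            calls[i, :n_a] = allele_a * 2
            calls[i, n_a:] = allele_b * 2
            rec = SiteRecord(SEQID, int(pos), allele_a, allele_a, allele_b, True)
            truth.diagnostic_sites.add(rec.key)
            if i in implant_plan:
                enz, off = implant_plan[i]
                truth.implanted_caps.append(
                    ImplantedCaps(rec.key, enz.name, allele_a, off)
                )
        else:
            ref = str(_BASES[rng.integers(4)])
            alt = _pick_other_base(rng, ref)
            gts = [ref + ref if ref <= ref else ref + ref,
                   min(ref, alt) + max(ref, alt), alt + alt]
            for _ in range(1000):
                draw = rng.choice(3, size=n, p=[0.6, 0.25, 0.15])
                if len(set(draw.tolist())) > 1:
                    break
            else:
                raise GenerationError("could not draw a polymorphic site")
            calls[i] = [gts[d] for d in draw]
            rec = SiteRecord(SEQID, int(pos), ref, None, None, False)
        records.append(rec)
    truth.site_records = records

    # missingness, then noise on the remaining calls
    clean_alphabets = [sorted(set(calls[i])) for i in range(params.n_sites)]
    if params.missing_rate > 0:
        miss = rng.random(calls.shape) < params.missing_rate
        calls[miss] = MISSING
    if params.noise_rate > 0:
        noisy = rng.random(calls.shape) < params.noise_rate
        for i, j in zip(*np.nonzero(noisy)):
            if calls[i, j] == MISSING:
                continue
            others = [g for g in clean_alphabets[i] if g != calls[i, j]]
            if others:
                calls[i, j] = others[int(rng.integers(len(others)))]

    sites = []
    for i, rec in enumerate(records):
        observed = set("".join(g for g in calls[i] if g != MISSING))
        alts = tuple(sorted(b for b in observed if b != rec.ref))
        sites.append(SiteCoord(rec.seqid, rec.pos, rec.ref, alts))
    frame = pd.DataFrame(calls, index=[s.key for s in sites], columns=samples)
    matrix = GenotypeMatrix(sites, samples, labels, frame)
    return matrix, truth


# ---------------------------------------------------------------------------
# reference sequence and annotation
# ---------------------------------------------------------------------------

def _overlapping(context: str, centre: int, enzyme: Enzyme) -> list[int]:
    length = len(enzyme.recognition)
    return [s for s in match_starts(context, enzyme)
            if s <= centre <= s + length - 1]


def _site_is_clean(seq: np.ndarray, idx: int, alleles: tuple[str, ...],
                   enzymes: list[Enzyme]) -> bool:
    """No recognition site of any enzyme overlaps the site under any allele."""
    for enz in enzymes:
        w = len(enz.recognition) - 1
        lo, hi = max(0, idx - w), min(len(seq), idx + w + 1)
        ctx = seq[lo:hi].copy()
        for allele in alleles:
            ctx[idx - lo] = allele
            if _overlapping("".join(ctx), idx - lo, enz):
                return False
    return True


def generate_reference(
    params: SimulationParams,
    truth: SyntheticTruth,
    enzymes: list[Enzyme] | None = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Build a reference and gene annotation consistent with the truth.

    The reference carries each site's ref allele; implanted CAPS sites sit
    inside a realized recognition motif (present under the discriminating
    allele, absent under the other), while all other diagnostic sites are
    scrubbed free of recognition sites under either allele.  Gene models
    are non-overlapping intervals tiling the sequence.  ``truth.site_to_gene``
    is filled in.  Deterministic for fixed params.
    """
    if enzymes is None:
        enzymes = load_enzymes()
    by_name = {e.name: e for e in enzymes}
    rng = np.random.default_rng([params.seed, 1])

    seq = rng.choice(_BASES, size=params.genome_length)
    protected: set[int] = set()
    for rec in truth.site_records:
        seq[rec.pos - 1] = rec.ref
        protected.add(rec.pos - 1)

    implanted_keys = {ic.site_key: ic for ic in truth.implanted_caps}

    # write the implanted motifs first and protect their footprints
    for ic in truth.implanted_caps:
        enz = by_name.get(ic.enzyme)
        if enz is None:
            raise GenerationError(f"unknown enzyme in truth: {ic.enzyme}")
        rec = next(r for r in truth.site_records if r.key == ic.site_key)
        idx = rec.pos - 1
        start = idx - ic.recognition_offset
        if start < 0 or start + len(enz.recognition) > len(seq):
            raise GenerationError(
                f"recognition motif does not fit around {ic.site_key}"
            )
        for j, sym in enumerate(enz.recognition):
            p = start + j
            if p == idx:
                continue  # the site itself holds the ref (= creating) allele
            bases = expand(sym)
            seq[p] = bases[int(rng.integers(len(bases)))] \
                if len(bases) > 1 else bases
            protected.add(p)

    max_w = max(len(e.recognition) for e in enzymes) - 1

    def resample_window(idx: int, keep: set[int]) -> None:
        for p in range(max(0, idx - max_w), min(len(seq), idx + max_w + 1)):
            if p not in keep and p not in protected:
                seq[p] = _BASES[rng.integers(4)]

    # scrub non-implanted diagnostic sites: no motif may overlap them
    for rec in truth.site_records:
        if not rec.diagnostic or rec.key in implanted_keys:
            continue
        idx = rec.pos - 1
        alleles = (rec.allele_a, rec.allele_b)
        for _ in range(200):
            if _site_is_clean(seq, idx, alleles, enzymes):
                break
            resample_window(idx, keep={idx})
        else:
            raise GenerationError(f"could not scrub enzyme motifs at {rec.key}")

    # verify implants: the assigned enzyme discriminates, and no other does
    for ic in truth.implanted_caps:
        enz = by_name[ic.enzyme]
        rec = next(r for r in truth.site_records if r.key == ic.site_key)
        idx = rec.pos - 1
        footprint = set(range(idx - ic.recognition_offset,
                              idx - ic.recognition_offset + len(enz.recognition)))
        for _ in range(200):
            if _implant_ok(seq, idx, rec, enz, enzymes):
                break
            resample_window(idx, keep=footprint)
        else:
            raise GenerationError(f"could not realize implant at {ic.site_key}")

    genes = _place_genes(params, rng)
    gene_starts = np.array([g.start for g in genes]) if genes else np.empty(0)
    truth.site_to_gene = {}
    for rec in truth.site_records:
        if not genes:
            continue
        k = int(np.searchsorted(gene_starts, rec.pos, side="right")) - 1
        if k >= 0 and genes[k].contains(rec.seqid, rec.pos):
            truth.site_to_gene[rec.key] = genes[k].gene_id

    return {SEQID: "".join(seq)}, genes


def _implant_ok(seq: np.ndarray, idx: int, rec: SiteRecord, enz: Enzyme,
                enzymes: list[Enzyme]) -> bool:
    for other in enzymes:
        w = len(other.recognition) - 1
        lo, hi = max(0, idx - w), min(len(seq), idx + w + 1)
        ctx = seq[lo:hi].copy()
        ctx[idx - lo] = rec.allele_a
        with_a = _overlapping("".join(ctx), idx - lo, other)
        ctx[idx - lo] = rec.allele_b
        with_b = _overlapping("".join(ctx), idx - lo, other)
        if other.name == enz.name:
            if len(with_a) == 0 or len(with_b) != 0:
                return False
        elif with_a != with_b:
            return False  # another enzyme would also discriminate
    return True


def _place_genes(params: SimulationParams, rng: np.random.Generator
                 ) -> list[GeneModel]:
    if params.n_genes == 0:
        return []
    block = params.genome_length // params.n_genes
    if block < 10:
        raise GenerationError(
            f"genome_length {params.genome_length} cannot hold "
            f"{params.n_genes} non-overlapping genes"
        )
    genes = []
    for i in range(params.n_genes):
        jitter = int(rng.integers(block // 10 + 1))
        start = i * block + 1 + jitter
        end = min(start + int(block * 0.7), (i + 1) * block)
        genes.append(GeneModel(f"gene{i + 1:04d}", SEQID, start, end))
    return genes


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_fasta(reference: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "diagnostic_sites": sorted(truth.diagnostic_sites),
        "site_to_gene": truth.site_to_gene,
        "implanted_caps": [
            {"site": ic.site_key, "enzyme": ic.enzyme, "allele": ic.allele,
             "recognition_offset": ic.recognition_offset}
            for ic in truth.implanted_caps
        ],
        "site_records": [
            {"seqid": r.seqid, "pos": r.pos, "ref": r.ref,
             "allele_a": r.allele_a, "allele_b": r.allele_b,
             "diagnostic": r.diagnostic}
            for r in truth.site_records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        diagnostic_sites=set(payload["diagnostic_sites"]),
        site_to_gene=dict(payload["site_to_gene"]),
        implanted_caps=[
            ImplantedCaps(d["site"], d["enzyme"], d["allele"],
                          d["recognition_offset"])
            for d in payload["implanted_caps"]
        ],
        site_records=[
            SiteRecord(d["seqid"], d["pos"], d["ref"], d["allele_a"],
                       d["allele_b"], d["diagnostic"])
            for d in payload["site_records"]
        ],
    )


def write_dataset(
    outdir: str | Path,
    matrix: GenotypeMatrix,
    truth: SyntheticTruth,
    reference: dict[str, str],
    genes: list[GeneModel],
) -> dict[str, Path]:
    """Write VCF + labels + FASTA + GFF3 + truth JSON into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "samples.vcf",
        "labels": out / "labels.tsv",
        "fasta": out / "reference.fa",
        "gff3": out / "genes.gff3",
        "truth": out / "truth.json",
    }
    contig_lengths = {name: len(seq) for name, seq in reference.items()}
    write_vcf(matrix, paths["vcf"], contig_lengths=contig_lengths)
    write_labels(matrix.labels, paths["labels"])
    write_fasta(reference, paths["fasta"])
    write_gff3(genes, paths["gff3"])
    write_truth(truth, paths["truth"])
    return paths
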