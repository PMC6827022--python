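"""Shared fixtures: hand-built matrices and an end-to-end synthetic run."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

import capskit as ck
from capskit.matrix import GenotypeMatrix, SiteCoord


def make_matrix(
    calls_by_sample: dict[str, list[str]],
    labels: dict[str, str],
    positions: list[int] | None = None,
    seqid: str = "chr1",
    refs: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-sample genotype call lists."""
    samples = list(calls_by_sample)
    n_sites = len(next(iter(calls_by_sample.values())))
    if positions is None:
        positions = list(range(1, n_sites + 1))
    sites = []
    for i, pos in enumerate(positions):
        observed = {
            b
            for s in samples
            for b in calls_by_sample[s][i]
            if b in "ACGT"
        }
        ref = refs[i] if refs else sorted(observed)[0]
        alts = tuple(sorted(observed - {ref}))
        sites.append(SiteCoord(seqid, pos, ref, alts))
    frame = pd.DataFrame(
        {s: calls_by_sample[s] for s in samples},
        index=[s.key for s in sites],
    )
    return GenotypeMatrix(sites, samples, labels, frame)


def two_species_labels(n_a: int, n_b: int) -> tuple[list[str], dict[str, str]]:
    samples = [f"A{i:02d}" for i in range(1, n_a + 1)] + \
              [f"B{i:02d}" for i in range(1, n_b + 1)]
    labels = {s: ("speciesA" if s.startswith("A") else "speciesB")
              for s in samples}
    return samples, labels


@pytest.fixture
def perfect_38_5() -> GenotypeMatrix:
    """38 species-A samples all TT, 5 species-B samples all CC at one site."""
    samples, labels = two_species_labels(38, 5)
    calls = {s: (["TT"] if labels[s] == "speciesA" else ["CC"])
             for s in samples}
    return make_matrix(calls, labels, refs=["T"])


@dataclass
class EndToEndRun:
    """One complete simulate -> consolidate -> test -> design run."""

    params: ck.SimulationParams
    matrix: ck.GenotypeMatrix          # consolidated from the written VCF
    truth: ck.SyntheticTruth
    reference: dict[str, str]
    genes: list[ck.GeneModel]
    results: list[ck.SiteTestResult]
    key_sites: set[str]


@pytest.fixture(scope="session")
def e2e(tmp_path_factory: pytest.TempPathFactory) -> EndToEndRun:
    """The clean-recovery study conditions: 38+5 samples, 5,000 sites,
    5% diagnostic, no noise, no missing calls, fixed seed."""
    params = ck.SimulationParams(
        n_species_a=38, n_species_b=5, n_sites=5000, frac_diagnostic=0.05,
        missing_rate=0.0, noise_rate=0.0, n_caps=3, seed=11,
    )
    matrix, truth = ck.generate_matrix(params)
    reference, genes = ck.generate_reference(params, truth)
    outdir = tmp_path_factory.mktemp("e2e")
    paths = ck.write_dataset(outdir, matrix, truth, reference, genes)
    consolidated = ck.consolidate([paths["vcf"]], paths["labels"])
    results, _ = ck.test_all_sites(consolidated)
    key_sites = {r.key for r in results if r.is_key}
    return EndToEndRun(
        params=params, matrix=consolidated, truth=truth,
        reference=reference, genes=genes, results=results,
        key_sites=key_sites,
    )
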