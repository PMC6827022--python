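"""Per-site chi-square segregation test and the key-site predicate.

For each candidate site the question is whether the major genotype of each
species is carried by exactly the samples of that species.  The test is a
two-category goodness of fit: take species A's major genotype g_a; among the
M non-missing samples at the site, count how many carry g_a (observed
O = [c_a, M - c_a]) and compare with the expectation that carriers occur at
the species-A sample ratio (E = [M * N_a / N, M * N_b / N], where N_a, N_b
are the species sample sizes and N = N_a + N_b).  The statistic is
chi2 = sum((O - E)^2 / E) with one degree of freedom; the same construction
is applied to species B's major genotype and the reported statistic is the
worse of the two (max chi2, min p).

A site is a "key site" when it segregates perfectly: every non-missing
species-A sample carries g_a, every non-missing species-B sample carries
g_b, and g_a != g_b.  Perfect segregation implies chi2 = 0 and p = 1 when
missingness is balanced, but p = 1 does not imply perfect segregation (a
symmetric swap of one sample per species keeps the carrier count at its
expectation); the strict combinatorial predicate is therefore the default,
with the p-based rule available as ``key_rule="p1"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSiteError, PreconditionError
from .matrix import MISSING, GenotypeMatrix, filter_candidate_sites, major_genotypes

#: chi-square values below this are treated as exactly zero
CHI2_ZERO_TOL = 1e-12


@dataclass
class SiteTestResult:
    """Chi-square goodness-of-fit result for one candidate site."""

    seqid: str
    pos: int
    g_a: str
    g_b: str
    observed_a: int
    observed_b: int
    expected_a: float
    expected_b: float
    chi2: float
    p_value: float
    is_key: bool

    @property
    def key(self) -> str:
        return f"{self.seqid}:{self.pos}"


def gof_chi_square(observed: np.ndarray, expected: np.ndarray
                   ) -> tuple[float, float]:
    """Two-category goodness-of-fit chi-square with df = 1.

    Returns (chi2, upper-tail p).  Statistics below ``CHI2_ZERO_TOL`` are
    snapped to exactly 0 (and p to exactly 1) so that perfectly segregating
    sites report p = 1 without floating-point fuzz.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != (2,) or expected.shape != (2,):
        raise ValueError("gof_chi_square expects two categories")
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    if chi2 < CHI2_ZERO_TOL:
        return 0.0, 1.0
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _site_counts(matrix: GenotypeMatrix, site_key: str
                 ) -> tuple[dict[str, str], pd.Series, pd.Series]:
    majors = major_genotypes(matrix, site_key)
    a, b = matrix.species
    if majors[a] == MISSING or majors[b] == MISSING or majors[a] == majors[b]:
        raise PreconditionError(
            f"site {site_key} did not pass the candidate filter "
            f"(majors: {majors[a]}, {majors[b]})"
        )
    row = matrix.calls_at(site_key)
    nonmissing = row[row != MISSING]
    return majors, row, nonmissing


def site_chi_square(matrix: GenotypeMatrix, site_key: str) -> SiteTestResult:
    """Run the goodness-of-fit construction at one filtered site."""
    majors, row, nonmissing = _site_counts(matrix, site_key)
    a, b = matrix.species
    g_a, g_b = majors[a], majors[b]
    n_a = len(matrix.samples_of(a))
    n_b = len(matrix.samples_of(b))
    n = n_a + n_b
    m = len(nonmissing)
    if m == 0:
        raise DegenerateSiteError(f"site {site_key} has no non-missing calls")

    c_a = int((nonmissing == g_a).sum())
    c_b = int((nonmissing == g_b).sum())
    e_a = m * n_a / n
    e_b = m * n_b / n

    chi2_a, p_a = gof_chi_square([c_a, m - c_a], [e_a, e_b])
    chi2_b, p_b = gof_chi_square([c_b, m - c_b], [e_b, e_a])
    chi2 = max(chi2_a, chi2_b)
    p = min(p_a, p_b)

    site = matrix.site(site_key)
    return SiteTestResult(
        seqid=site.seqid,
        pos=site.pos,
        g_a=g_a,
        g_b=g_b,
        observed_a=c_a,
        observed_b=c_b,
        expected_a=e_a,
        expected_b=e_b,
        chi2=chi2,
        p_value=p,
        is_key=_perfect_segregation(matrix, row, g_a, g_b),
    )


def _perfect_segregation(matrix: GenotypeMatrix, row: pd.Series,
                         g_a: str, g_b: str) -> bool:
    if g_a == g_b:
        return False
    a, b = matrix.species
    calls_a = row[matrix.samples_of(a)]
    calls_b = row[matrix.samples_of(b)]
    ok_a = (calls_a[calls_a != MISSING] == g_a).all()
    ok_b = (calls_b[calls_b != MISSING] == g_b).all()
    return bool(ok_a and ok_b)


def is_key_site(matrix: GenotypeMatrix, site_key: str) -> bool:
    """True iff the site segregates perfectly between the two species."""
    majors, row, _ = _site_counts(matrix, site_key)
    a, b = matrix.species
    return _perfect_segregation(matrix, row, majors[a], majors[b])


def test_all_sites(
    matrix: GenotypeMatrix,
    *,
    key_rule: str = "perfect",
    histogram_bins: int = 20,
) -> tuple[list[SiteTestResult], pd.DataFrame]:
    """Filter the matrix and test every kept site.

    Returns results sorted by (seqid, pos) plus a p-value histogram table
    (bin_left, bin_right, count) for plotting the p distribution.
    ``key_rule`` selects the key-site predicate: "perfect" (default, strict
    segregation) or "p1" (p = 1 alone).
    """
    if key_rule not in ("perfect", "p1"):
        raise ValueError(f"unknown key_rule: {key_rule!r}")
    kept, _ = filter_candidate_sites(matrix)
    results = [site_chi_square(matrix, k) for k in kept]
    if key_rule == "p1":
        for r in results:
            r.is_key = r.p_value >= 1.0 - CHI2_ZERO_TOL
    results.sort(key=lambda r: (r.seqid, r.pos))

    pvals = np.array([r.p_value for r in results]) if results else np.empty(0)
    edges = np.linspace(0.0, 1.0, histogram_bins + 1)
    counts, _ = np.histogram(pvals, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return results, hist


def results_to_frame(results: list[SiteTestResult]) -> pd.DataFrame:
    """Tabulate per-site results (the sites TSV written by the CLI)."""
    return pd.DataFrame(
        [
            {
                "seqid": r.seqid, "pos": r.pos, "g_a": r.g_a, "g_b": r.g_b,
                "observed_a": r.observed_a, "observed_b": r.observed_b,
                "expected_a": r.expected_a, "expected_b": r.expected_b,
                "chi2": r.chi2, "p_value": r.p_value, "is_key": r.is_key,
            }
            for r in results
        ],
        columns=["seqid", "pos", "g_a", "g_b", "observed_a", "observed_b",
                 "expected_a", "expected_b", "chi2", "p_value", "is_key"],
    )
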