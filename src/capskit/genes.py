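"""Gene-level scoring of tested sites and tail-based key-gene selection.

Each tested site inside a gene contributes +1 to that gene's score if it is
a key site and -1 otherwise, so score = n_key - n_nonkey.  The score
rewards genes dense in perfectly segregating sites while penalizing genes
whose polymorphism is mostly sample-specific.  "Key genes" are those whose
score exceeds a threshold chosen so that the upper tail of the score
distribution holds a target fraction (default 5%) of the mass — either of
the empirical distribution or of a Gaussian KDE fitted to it.

Sites are assigned to genes by coordinate containment in the gene feature's
span (1-based inclusive, introns included); a site inside two overlapping
genes scores both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import FormatError, ThresholdError
from .keysites import SiteTestResult


@dataclass(frozen=True)
class GeneModel:
    """A gene feature span from a GFF3 annotation (1-based inclusive)."""

    gene_id: str
    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: bad interval {self.start}-{self.end}")

    def contains(self, seqid: str, pos: int) -> bool:
        return seqid == self.seqid and self.start <= pos <= self.end


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models of one feature type from a GFF3 file."""
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes = [
        GeneModel(feat.id, feat.seqid, feat.start, feat.end)
        for feat in db.features_of_type(feature_type)
    ]
    if not genes:
        raise FormatError(f"no {feature_type!r} features in {path}")
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               source: str = "capskit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seqid}\t{source}\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )


def assign_sites_to_genes(
    sites: Sequence[SiteTestResult], genes: Sequence[GeneModel]
) -> dict[str, list[str]]:
    """Map each site key to the gene id(s) whose span contains it.

    Sites outside every gene are absent from the mapping.  Overlapping
    genes all receive the site.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the gene end inclusive
        trees.setdefault(g.seqid, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    mapping: dict[str, list[str]] = {}
    for s in sites:
        tree = trees.get(s.seqid)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.at(s.pos))
        if hits:
            mapping[s.key] = hits
    return mapping


@dataclass
class GeneScore:
    """Key/non-key site counts and the +1/-1 score for one gene."""

    gene_id: str
    seqid: str
    n_key: int = 0
    n_nonkey: int = 0
    site_free: bool = field(default=False)

    @property
    def score(self) -> int:
        return self.n_key - self.n_nonkey


def score_genes(
    mapping: Mapping[str, Sequence[str]],
    sites: Sequence[SiteTestResult],
    genes: Sequence[GeneModel],
) -> list[GeneScore]:
    """Count key / non-key assigned sites per gene and form the score.

    Genes with no assigned site score 0 and are flagged ``site_free``.
    """
    scores = {g.gene_id: GeneScore(g.gene_id, g.seqid) for g in genes}
    for s in sites:
        for gid in mapping.get(s.key, ()):
            gs = scores[gid]
            if s.is_key:
                gs.n_key += 1
            else:
                gs.n_nonkey += 1
    out = list(scores.values())
    for gs in out:
        gs.site_free = gs.n_key + gs.n_nonkey == 0
    return out


@dataclass(frozen=True)
class ThresholdResult:
    """An integer score cutoff and the tail mass actually above it."""

    threshold: int
    tail_mass: float
    method: str


def determine_threshold(
    scores: Sequence[GeneScore] | Sequence[int],
    tail_target: float = 0.05,
    method: str = "empirical",
) -> ThresholdResult:
    """Smallest integer cutoff whose upper tail holds <= ``tail_target`` mass.

    ``method="empirical"`` uses the fraction of scores strictly above t;
    ``method="kde"`` integrates a Gaussian KDE (Scott's bandwidth) above t.
    """
    if not 0.0 <= tail_target <= 1.0:
        raise ValueError(f"tail_target must be in [0, 1], got {tail_target}")
    values = np.array(
        [s.score if isinstance(s, GeneScore) else int(s) for s in scores],
        dtype=float,
    )
    if values.size < 2 or np.unique(values).size < 2:
        raise ThresholdError("need at least two distinct scores to set a threshold")

    lo = int(np.floor(values.min())) - 1
    hi = int(np.ceil(values.max()))
    if method == "empirical":
        def tail(t: int) -> float:
            return float((values > t).mean())
    elif method == "kde":
        kde = stats.gaussian_kde(values)  # Scott's rule by default

        def tail(t: int) -> float:
            return float(kde.integrate_box_1d(t, np.inf))
    else:
        raise ValueError(f"unknown threshold method: {method!r}")

    for t in range(lo, hi + 1):
        mass = tail(t)
        if mass <= tail_target:
            return ThresholdResult(threshold=t, tail_mass=mass, method=method)
    # tail(max) is 0 for empirical and < target eventually for kde, so this
    # is only reachable with pathological kde tails; fall back to the max.
    return ThresholdResult(threshold=hi, tail_mass=tail(hi), method=method)


def select_key_genes(
    scores: Sequence[GeneScore], threshold: int
) -> list[GeneScore]:
    """Genes scoring strictly above the threshold, best first."""
    chosen = [g for g in scores if g.score > threshold]
    chosen.sort(key=lambda g: (-g.score, g.gene_id))
    return chosen


def scores_to_frame(scores: Sequence[GeneScore],
                    threshold: int | None = None):
    """Tabulate gene scores (the gene-scores TSV written by the CLI)."""
    import pandas as pd

    rows = [
        {
            "gene_id": g.gene_id, "seqid": g.seqid, "n_key": g.n_key,
            "n_nonkey": g.n_nonkey, "score": g.score, "site_free": g.site_free,
        }
        for g in scores
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "seqid", "n_key", "n_nonkey",
                                     "score", "site_free"])
    if threshold is not None:
        df["is_key_gene"] = df["score"] > threshold
    return df
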