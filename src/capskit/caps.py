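"""CAPS marker design: motif scanning, in-silico PCR, restriction digestion.

A CAPS (cleaved amplified polymorphic sequences) marker turns a diagnostic
SNP into a gel assay: PCR-amplify the region, digest with a restriction
enzyme whose recognition site exists under one allele but not the other,
and read the genotype from the fragment pattern.  The classic fire-ant
example is BspHI (T^CATGA) at a mitochondrial T/C site: the T allele is
cut into 441 + 190 bp, the C allele leaves the 631 bp product intact.

Scanning reports one top-strand cut per recognition-site occurrence,
considering both orientations of the motif (NEBcutter-style); overhangs are
ignored because gel electrophoresis resolves fragment lengths only.
In-silico PCR is exact-match (validation primers are designed from the
reference, so mismatch tolerance adds nothing but nondeterminism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enzymes import Enzyme
from .exceptions import (
    AmbiguousPrimerError,
    CoordinateError,
    NoProductError,
    ParameterError,
)
from .iupac import find_matches, reverse_complement

#: fragments shorter than this are flagged as hard to see on an agarose gel
DEFAULT_MIN_FRAGMENT = 50


def _sequences(reference) -> dict[str, str]:
    """Normalize a reference (dict of str, or pyfaidx.Fasta) to {name: str}."""
    if isinstance(reference, Mapping):
        return {name: str(seq).upper() for name, seq in reference.items()}
    # pyfaidx.Fasta and similar: iterable of records with .name
    return {rec.name: str(rec[:]).upper() for rec in reference}


# ---------------------------------------------------------------------------
# recognition-site scanning
# ---------------------------------------------------------------------------

def match_starts(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of recognition-site occurrences on the top
    strand, in either orientation, deduplicated and sorted."""
    starts = set(find_matches(sequence, enzyme.recognition))
    if not enzyme.palindromic:
        starts.update(find_matches(sequence, reverse_complement(enzyme.recognition)))
    return sorted(starts)


def scan_recognition_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based top-strand cut positions for all recognition-site occurrences.

    A cut position c means the duplex is severed between sequence[c-1] and
    sequence[c].  Forward-orientation matches cut at start + cut_offset;
    matches of the reverse-complemented motif cut at the mirrored offset
    start + |motif| - cut_offset.  For a palindromic motif both orientations
    find the same occurrences and a single (forward) cut is reported per
    occurrence.
    """
    length = len(enzyme.recognition)
    fwd = set(find_matches(sequence, enzyme.recognition))
    cuts = {s + enzyme.cut_offset for s in fwd}
    if not enzyme.palindromic:
        rev = set(find_matches(sequence, reverse_complement(enzyme.recognition)))
        cuts.update(s + length - enzyme.cut_offset for s in rev - fwd)
    return sorted(cuts)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Amplicon:
    """A PCR product: its sequence and 1-based inclusive source coordinates."""

    sequence: str
    seqid: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("amplicon length disagrees with coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


def in_silico_pcr(reference, fwd_primer: str, rev_primer: str,
                  min_primer_length: int = 15) -> Amplicon:
    """Exact-match amplification: forward primer on the top strand, reverse
    primer's reverse complement downstream on the same strand.

    Raises ``NoProductError`` if nothing amplifies and
    ``AmbiguousPrimerError`` if a primer binds more than once or more than
    one product is possible.
    """
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < min_primer_length or len(rev) < min_primer_length:
        raise ParameterError(f"primers must be >= {min_primer_length} bp")
    rev_rc = reverse_complement(rev)

    fwd_hits: list[tuple[str, int]] = []
    rev_hits: list[tuple[str, int]] = []
    for name, seq in _sequences(reference).items():
        fwd_hits.extend((name, i) for i in _find_all(seq, fwd))
        rev_hits.extend((name, i) for i in _find_all(seq, rev_rc))

    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        raise AmbiguousPrimerError(
            f"primer binds multiple loci: fwd at {fwd_hits}, rev at {rev_hits}"
        )
    if not fwd_hits or not rev_hits:
        raise NoProductError("no amplification: a primer has no exact match")
    (f_seq, f_pos), (r_seq, r_pos) = fwd_hits[0], rev_hits[0]
    if f_seq != r_seq or r_pos + len(rev_rc) <= f_pos:
        raise NoProductError("primer sites do not face each other on one sequence")

    seqs = _sequences(reference)
    start = f_pos + 1                      # 1-based
    end = r_pos + len(rev_rc)              # 1-based inclusive
    return Amplicon(
        sequence=seqs[f_seq][f_pos:end],
        seqid=f_seq,
        start=start,
        end=end,
        fwd_primer=fwd,
        rev_primer=rev,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(amplicon: Amplicon | str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths (descending) after complete digestion of a linear
    amplicon.  No recognition site -> one full-length fragment."""
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    cuts = [c for c in scan_recognition_sites(seq, enzyme) if 0 < c < len(seq)]
    bounds = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(fragments, reverse=True)


# ---------------------------------------------------------------------------
# discriminating enzymes and marker assembly
# ---------------------------------------------------------------------------

def _substitute(seq: str, idx: int, base: str) -> str:
    return seq[:idx] + base + seq[idx + 1:]


def _overlapping_matches(context: str, centre: int, enzyme: Enzyme) -> tuple[int, ...]:
    length = len(enzyme.recognition)
    return tuple(
        s for s in match_starts(context, enzyme)
        if s <= centre <= s + length - 1
    )


def find_discriminating_enzymes(
    reference,
    seqid: str,
    pos: int,
    alleles: tuple[str, str],
    enzymes: Sequence[Enzyme],
    window: int | None = None,
) -> list[tuple[Enzyme, str]]:
    """Enzymes whose recognition matches overlapping a site depend on which
    allele is substituted there.

    For each enzyme, both alleles are substituted at the (1-based) position
    and a +-window context is scanned; the enzyme is reported iff the
    multiset of recognition matches overlapping the site differs between
    alleles.  The discriminating allele is the one creating the (extra)
    occurrence.  ``window`` defaults per enzyme to |recognition| - 1, the
    minimal span in which a substitution can alter a match.
    """
    seqs = _sequences(reference)
    if seqid not in seqs:
        raise CoordinateError(f"unknown sequence {seqid!r}")
    seq = seqs[seqid]
    if not 1 <= pos <= len(seq):
        raise CoordinateError(f"{seqid}:{pos} outside sequence of length {len(seq)}")
    a1, a2 = (a.upper() for a in alleles)
    if a1 == a2 or len(a1) != 1 or len(a2) != 1:
        raise ParameterError(f"need two distinct single-base alleles, got {alleles}")

    found: list[tuple[Enzyme, str]] = []
    for enz in enzymes:
        w = window if window is not None else len(enz.recognition) - 1
        lo = max(0, pos - 1 - w)
        hi = min(len(seq), pos + w)
        centre = pos - 1 - lo
        ctx = seq[lo:hi]
        m1 = _overlapping_matches(_substitute(ctx, centre, a1), centre, enz)
        m2 = _overlapping_matches(_substitute(ctx, centre, a2), centre, enz)
        if m1 == m2:
            continue
        if len(m1) != len(m2):
            creating = a1 if len(m1) > len(m2) else a2
        else:  # same count, different placement: credit the first allele
            creating = a1
        found.append((enz, creating))
    return found


@dataclass(frozen=True)
class PrimerParams:
    """Knobs for automatic validation-primer placement around a key site."""

    primer_length: int = 20
    amplicon_radius: int = 300
    min_fragment: int = DEFAULT_MIN_FRAGMENT

    def __post_init__(self) -> None:
        if self.primer_length < 15:
            raise ParameterError("primer_length must be >= 15")
        if self.amplicon_radius <= self.primer_length:
            raise ParameterError("amplicon_radius must exceed primer_length")


@dataclass
class CapsMarker:
    """A key site, a discriminating enzyme, and the predicted gel patterns."""

    seqid: str
    pos: int
    alleles: tuple[str, str]
    enzyme: Enzyme
    discriminating_allele: str
    amplicon: Amplicon
    fragments_by_allele: dict[str, list[int]]
    gel_invisible: dict[str, list[int]] = field(default_factory=dict)

    @property
    def site_key(self) -> str:
        return f"{self.seqid}:{self.pos}"


def design_caps(
    reference,
    key_sites: Sequence,
    enzymes: Sequence[Enzyme],
    primer_params: PrimerParams | None = None,
    window: int | None = None,
) -> tuple[list[CapsMarker], list[str]]:
    """Design CAPS markers for key sites.

    ``key_sites`` are site test results (or anything with seqid, pos, g_a,
    g_b); only sites whose two species major genotypes are homozygous for
    distinct bases are designable.  For each site with a discriminating
    enzyme, primers are taken verbatim from the reference at
    +-amplicon_radius, the amplicon is amplified in silico, each allele is
    substituted at the site, and the per-allele digestion patterns are
    predicted.  Markers whose alleles digest identically are discarded.

    Returns (markers, warnings); warnings record skipped sites and why.
    """
    pp = primer_params or PrimerParams()
    seqs = _sequences(reference)
    markers: list[CapsMarker] = []
    warnings: list[str] = []

    for site in key_sites:
        seqid, pos = site.seqid, site.pos
        g_a, g_b = site.g_a, site.g_b
        if len(set(g_a)) != 1 or len(set(g_b)) != 1 or g_a[0] == g_b[0]:
            warnings.append(
                f"{seqid}:{pos}: majors {g_a}/{g_b} not distinct homozygotes; skipped"
            )
            continue
        alleles = (g_a[0], g_b[0])
        if seqid not in seqs:
            raise CoordinateError(f"unknown sequence {seqid!r}")
        seq = seqs[seqid]

        discs = find_discriminating_enzymes(
            {seqid: seq}, seqid, pos, alleles, enzymes, window=window
        )
        if not discs:
            continue

        start = max(1, pos - pp.amplicon_radius)
        end = min(len(seq), pos + pp.amplicon_radius)
        fwd = seq[start - 1:start - 1 + pp.primer_length]
        rev = reverse_complement(seq[end - pp.primer_length:end])
        try:
            amplicon = in_silico_pcr({seqid: seq}, fwd, rev)
        except (NoProductError, AmbiguousPrimerError) as exc:
            warnings.append(f"{seqid}:{pos}: primer placement failed ({exc}); skipped")
            continue
        if not amplicon.start <= pos <= amplicon.end:
            warnings.append(f"{seqid}:{pos}: amplicon does not cover site; skipped")
            continue
        site_idx = pos - amplicon.start

        for enz, creating in discs:
            fragments: dict[str, list[int]] = {}
            for allele in alleles:
                fragments[allele] = digest(
                    _substitute(amplicon.sequence, site_idx, allele), enz
                )
            if fragments[alleles[0]] == fragments[alleles[1]]:
                continue
            invisible = {
                al: [f for f in frags if f < pp.min_fragment]
                for al, frags in fragments.items()
                if any(f < pp.min_fragment for f in frags)
            }
            markers.append(
                CapsMarker(
                    seqid=seqid,
                    pos=pos,
                    alleles=alleles,
                    enzyme=enz,
                    discriminating_allele=creating,
                    amplicon=amplicon,
                    fragments_by_allele=fragments,
                    gel_invisible=invisible,
                )
            )
    if not markers:
        warnings.append("no discriminating enzyme found for any site")
    return markers, warnings


def markers_to_frame(markers: Sequence[CapsMarker]):
    """Tabulate markers (the markers TSV written by the CLI)."""
    import pandas as pd

    rows = []
    for m in markers:
        for allele, frags in m.fragments_by_allele.items():
            rows.append(
                {
                    "seqid": m.seqid, "pos": m.pos, "enzyme": m.enzyme.name,
                    "allele": allele,
                    "is_discriminating": allele == m.discriminating_allele,
                    "n_fragments": len(frags),
                    "fragments": ",".join(map(str, frags)),
                    "amplicon_length": len(m.amplicon),
                }
            )
    return pd.DataFrame(
        rows, columns=["seqid", "pos", "enzyme", "allele", "is_discriminating",
                       "n_fragments", "fragments", "amplicon_length"],
    )
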