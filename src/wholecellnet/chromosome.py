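"""Partition of the circular chromosome into ordered regions.

Cut points are the boundaries of every DnaA binding site plus the
replication origin and terminus.  Each binding site is its own region and
each maximal gap between cut points is a region, so regions tile the
circle exactly.  Indices run clockwise starting at 0 at the origin;
coordinates are 0-based half-open.  Per-region nucleotide counts provide
the stoichiometric weights for replication and transcription templates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .errors import KBError
from .kb import KBBundle

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ChromosomeRegion:
    index: int
    start: int  # rotated coordinates: 0 at ori, half-open
    end: int
    kind: str  # "binding_site" | "inter_site"
    site_protein: Optional[str] = None
    abs_start: int = 0  # genome coordinates of the region start

    @property
    def length(self) -> int:
        return self.end - self.start


def partition_chromosome(kb: KBBundle) -> list:
    """Ordered region tiling of the circular genome.

    Raises on overlapping binding sites or on an origin/terminus that
    falls inside a binding site.
    """
    length = kb.genome_length
    ori = kb.ori_position

    def rot(pos: int) -> int:
        return (pos - ori) % length

    sites = sorted(kb.binding_sites, key=lambda s: rot(s.position))
    intervals = []  # rotated, non-wrapping by construction check below
    for site in sites:
        r_start = rot(site.position)
        r_end = r_start + site.length
        if r_end > length:
            raise KBError(f"binding site {site.id} wraps the origin")
        intervals.append((r_start, r_end, site))
    for (s1, e1, a), (s2, e2, b) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise KBError(f"binding sites {a.id} and {b.id} overlap")
    ter = rot(kb.ter_position)
    for s, e, site in intervals:
        if s < ter < e or s < 0 < e:
            raise KBError(f"ori/ter falls inside binding site {site.id}")

    cuts = {0, ter}
    site_at = {}
    for s, e, site in intervals:
        cuts.add(s)
        cuts.add(e % length)
        site_at[s] = site
    ordered = sorted(cuts)
    regions = []
    for i, start in enumerate(ordered):
        end = ordered[i + 1] if i + 1 < len(ordered) else length
        if end == start:
            continue
        site = site_at.get(start)
        if site is not None and start + site.length == (end if end != length else length):
            kind, protein = "binding_site", site.protein
        elif site is not None:
            # a cut (ori/ter) cannot split a site: guarded above
            kind, protein = "binding_site", site.protein
        else:
            kind, protein = "inter_site", None
        regions.append(
            ChromosomeRegion(
                index=len(regions),
                start=start,
                end=end,
                kind=kind,
                site_protein=protein,
                abs_start=(start + ori) % length,
            )
        )
    return regions


def region_sequence(region: ChromosomeRegion, genome_sequence: str) -> str:
    length = len(genome_sequence)
    start = region.abs_start
    end = start + region.length
    if end <= length:
        return genome_sequence[start:end]
    return genome_sequence[start:] + genome_sequence[: end - length]


def region_nt_counts(
    region: ChromosomeRegion, genome_sequence: str, both_strands: bool = False
) -> dict:
    """Nucleotide counts of a region (optionally including the complement strand)."""
    counts = Counter(region_sequence(region, genome_sequence))
    if both_strands:
        counts = counts + Counter({_COMPLEMENT[b]: n for b, n in counts.items()})
    return dict(counts)


def terminus_region_index(regions: list, kb: KBBundle) -> int:
    """The region whose start sits at the replication terminus."""
    ter = (kb.ter_position - kb.ori_position) % kb.genome_length
    for region in regions:
        if region.start == ter:
            return region.index
    raise KBError("no region starts at the replication terminus")


def regions_overlapping(regions: list, start: int, end: int, kb: KBBundle) -> list:
    """Region indices overlapping genome interval [start, end), in circular order."""
    length = kb.genome_length
    r_start = (start - kb.ori_position) % length
    r_end = r_start + (end - start)
    hits = []
    for region in regions:
        for shift in (0, length):
            a, b = region.start + shift, region.end + shift
            if a < r_end and r_start < b:
                hits.append(region.index)
                break
    return hits
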