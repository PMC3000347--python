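"""Gene-model annotation: splice sites, introns, and coding regions.

An :class:`Annotation` is the union of one or more gene-model sources; a
splice site is "annotated" when its exact coordinate appears as an intron
boundary in any source.  Site coordinates follow the junction convention:
for an intron ``[s, e)`` on the forward strand the donor (5') site key is
``s`` and the acceptor (3') key is ``e``; on the minus strand the two are
swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic.truth import GeneModel, JunctionKey

SiteKey = tuple[str, str, str, int]  # (chrom, strand, '5'|'3', boundary coord)


def junction_sites(chrom: str, strand: str, start: int, end: int
                   ) -> tuple[SiteKey, SiteKey]:
    """(donor, acceptor) site keys of a junction."""
    if strand == "+":
        return (chrom, strand, "5", start), (chrom, strand, "3", end)
    return (chrom, strand, "5", end), (chrom, strand, "3", start)


def site_canonical_bases(site: SiteKey) -> tuple[int, int]:
    """Forward-genome positions of the two canonical intronic bases."""
    chrom, strand, typ, pos = site
    if (strand == "+") == (typ == "5"):
        return pos, pos + 1  # intron start side
    return pos - 2, pos - 1  # intron end side


def site_exonic_base(site: SiteKey) -> int:
    """Forward-genome position of the first exonic base beside the site."""
    chrom, strand, typ, pos = site
    if (strand == "+") == (typ == "5"):
        return pos - 1
    return pos


@dataclass
class Annotation:
    """Union of gene models, queryable for splice-site membership."""

    genes: list[GeneModel] = field(default_factory=list)
    utr_length: int = 30

    def __post_init__(self) -> None:
        self.introns: set[JunctionKey] = set()
        self.donor_sites: set[SiteKey] = set()
        self.acceptor_sites: set[SiteKey] = set()
        self._site_positions: dict[tuple[str, str, str], np.ndarray] = {}
        self._cds: dict[str, list[tuple[int, int]]] = {}
        self._exonic: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            self._add_gene(g)
        self._finalize()

    def _add_gene(self, g: GeneModel) -> None:
        for s, e in g.introns:
            key = (g.chrom, g.strand, s, e)
            self.introns.add(key)
            d, a = junction_sites(*key)
            self.donor_sites.add(d)
            self.acceptor_sites.add(a)
        self._exonic.setdefault(g.chrom, []).extend(g.exons)
        for iv in self._cds_intervals(g):
            self._cds.setdefault(g.chrom, []).append(iv)

    def _cds_intervals(self, g: GeneModel) -> list[tuple[int, int]]:
        """Coding part of each exon: the transcript minus a UTR at each end."""
        u = self.utr_length
        lens = [e - s for s, e in g.exons]
        total = sum(lens)
        if total <= 2 * u:
            return []
        # trim u bases from each transcript end; strand-symmetric in genomic space
        remaining_left = u
        remaining_right = u
        ivs = [list(x) for x in g.exons]
        i = 0
        while remaining_left > 0 and i < len(ivs):
            s, e = ivs[i]
            cut = min(e - s, remaining_left)
            ivs[i][0] += cut
            remaining_left -= cut
            i += 1
        i = len(ivs) - 1
        while remaining_right > 0 and i >= 0:
            s, e = ivs[i]
            cut = min(e - s, remaining_right)
            ivs[i][1] -= cut
            remaining_right -= cut
            i -= 1
        return [(s, e) for s, e in ivs if e > s]

    def _finalize(self) -> None:
        all_sites = self.donor_sites | self.acceptor_sites
        by_group: dict[tuple[str, str, str], list[int]] = {}
        for chrom, strand, typ, pos in all_sites:
            by_group.setdefault((chrom, strand, typ), []).append(pos)
        self._site_positions = {k: np.array(sorted(v), dtype=np.int64)
                                for k, v in by_group.items()}
        self._cds = {c: _merge(v) for c, v in self._cds.items()}
        self._exonic = {c: _merge(v) for c, v in self._exonic.items()}

    @classmethod
    def union(cls, annotations: list["Annotation"]) -> "Annotation":
        genes = [g for a in annotations for g in a.genes]
        return cls(genes=genes, utr_length=annotations[0].utr_length if annotations else 30)

    def is_annotated_site(self, site: SiteKey) -> bool:
        return site in self.donor_sites or site in self.acceptor_sites

    def nearest_site_distance(self, site: SiteKey) -> int:
        """Distance to the nearest annotated site of the same type and strand."""
        chrom, strand, typ, pos = site
        arr = self._site_positions.get((chrom, strand, typ))
        if arr is None or len(arr) == 0:
            return np.iinfo(np.int64).max
        i = np.searchsorted(arr, pos)
        best = np.iinfo(np.int64).max
        if i < len(arr):
            best = min(best, abs(int(arr[i]) - pos))
        if i > 0:
            best = min(best, abs(int(arr[i - 1]) - pos))
        return int(best)

    def region_of_site(self, site: SiteKey) -> str:
        """'CDS', 'UTR', or 'unannotated', from the adjacent exonic base."""
        chrom = site[0]
        base = site_exonic_base(site)
        if _contains(self._cds.get(chrom, []), base):
            return "CDS"
        if _contains(self._exonic.get(chrom, []), base):
            return "UTR"
        return "unannotated"


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _contains(ivs: list[tuple[int, int]], pos: int) -> bool:
    import bisect

    i = bisect.bisect_right(ivs, (pos, np.iinfo(np.int64).max)) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]
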