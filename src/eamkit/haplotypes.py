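"""Complete-LD tag-SNP collapsing and haplotype diversity.

In an inbred panel every accession is effectively phased, so the haplotype of
a gene amplicon is just the string of its alleles. SNPs whose genotype
columns are identical (or exactly complementary) across the panel are in
complete linkage disequilibrium (pairwise r^2 = 1) and carry redundant
association information: each such group is collapsed to a single tag SNP
before model fitting.

Haplotype diversity is Nei's unbiased gene diversity over haplotypes,
Hd = n/(n-1) * (1 - sum_i p_i^2), as reported by DnaSP.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from eamkit._util import log, round_half_away
from eamkit.snp_catalog import parse_snp_name


@dataclass(frozen=True)
class LdGroup:
    """A within-gene set of >= 2 SNPs in complete LD, represented by one tag."""

    gene: str
    members: tuple[str, ...]
    tag: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"LD group in {self.gene} needs >= 2 members, got {self.members}")
        if self.tag not in self.members:
            raise ValueError(f"tag {self.tag!r} not among members {self.members}")
        for m in self.members:
            gene, _, _, _ = parse_snp_name(m)
            if gene != self.gene:
                raise ValueError(f"member {m!r} does not belong to gene {self.gene!r}")


@dataclass
class HaplotypeTable:
    """Distinct allele strings of one gene's SNPs with accession counts."""

    gene: str
    haplotypes: list[str]
    counts: list[int]
    n: int

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.counts):
            raise ValueError("haplotypes and counts differ in length")
        if any(c < 1 for c in self.counts):
            raise ValueError("all haplotype counts must be >= 1")
        if sum(self.counts) != self.n:
            raise ValueError(f"counts sum to {sum(self.counts)}, expected n = {self.n}")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype strings")

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n


def detect_complete_ld(
    calls: np.ndarray,
    locus_names: Sequence[str],
    gene_of: Optional[Mapping[str, str] | Callable[[str], str]] = None,
    min_pair_coverage: float = 0.9,
) -> list[LdGroup]:
    """Group same-gene loci whose call columns are identical or complementary.

    Parameters
    ----------
    calls
        accessions x loci matrix coded 0 (ref-hom), 1 (het), 2 (alt-hom),
        NaN missing. Pairs are compared on their jointly observed accessions.
    locus_names
        SNP names, one per column; the gene is taken from the name unless
        `gene_of` overrides it.
    min_pair_coverage
        A group is only emitted if every within-group pair was observed in at
        least this fraction of accessions (guards spurious grouping on
        sparse data).

    Grouping is the transitive closure of the pairwise r^2 = 1 relation
    within each gene; the tag is the member with the smallest position.
    Monomorphic loci (r^2 undefined) are excluded with a warning.
    """
    calls = np.asarray(calls, dtype=float)
    if calls.ndim != 2 or calls.shape[1] != len(locus_names):
        raise ValueError("calls must be accessions x loci matching locus_names")
    n_acc = calls.shape[0]

    def gene_for(name: str) -> str:
        if gene_of is None:
            return parse_snp_name(name)[0]
        if callable(gene_of):
            return gene_of(name)
        return gene_of[name]

    by_gene: dict[str, list[int]] = {}
    for j, name in enumerate(locus_names):
        by_gene.setdefault(gene_for(name), []).append(j)

    groups: list[LdGroup] = []
    for gene in sorted(by_gene):
        idx = by_gene[gene]
        poly: list[int] = []
        for j in idx:
            col = calls[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0 or np.all(obs == obs[0]):
                log.warning("locus %s is monomorphic; excluded from LD grouping", locus_names[j])
                continue
            poly.append(j)
        # union-find over complete-LD pairs
        parent = {j: j for j in poly}

        def find(j: int) -> int:
            while parent[j] != j:
                parent[j] = parent[parent[j]]
                j = parent[j]
            return j

        for a_i, ja in enumerate(poly):
            for jb in poly[a_i + 1:]:
                ca, cb = calls[:, ja], calls[:, jb]
                both = ~np.isnan(ca) & ~np.isnan(cb)
                if both.sum() < min_pair_coverage * n_acc:
                    continue
                a, b = ca[both], cb[both]
                if np.array_equal(a, b):
                    complete = True
                elif np.array_equal(a, 2.0 - b):
                    complete = True
                    log.info(
                        "loci %s and %s are complementary (alleles swapped); "
                        "treated as complete LD", locus_names[ja], locus_names[jb],
                    )
                else:
                    complete = False
                if complete:
                    parent[find(ja)] = find(jb)

        clusters: dict[int, list[int]] = {}
        for j in poly:
            clusters.setdefault(find(j), []).append(j)
        for members_idx in clusters.values():
            if len(members_idx) < 2:
                continue
            names = [locus_names[j] for j in members_idx]
            names.sort(key=lambda nm: parse_snp_name(nm)[2])
            groups.append(LdGroup(gene=gene, members=tuple(names), tag=names[0]))
    return groups


def collapse_ld(snps: Sequence[str], groups: Sequence[LdGroup]) -> list[str]:
    """Replace each LD group among `snps` by its tag, preserving order.

    Idempotent: tags already present stay; overlapping groups are an error.
    """
    member_to_tag: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            if m in member_to_tag and member_to_tag[m] != g.tag:
                raise ValueError(f"SNP {m!r} appears in more than one LD group")
            member_to_tag[m] = g.tag
    out: list[str] = []
    for s in snps:
        tag = member_to_tag.get(s, s)
        if tag not in out:
            out.append(tag)
    return out


def enumerate_haplotypes(
    calls: np.ndarray,
    locus_names: Sequence[str],
    gene: str,
    ref_alt: Optional[Mapping[str, tuple[str, str]]] = None,
) -> HaplotypeTable:
    """Tabulate the distinct allele strings for one gene's loci.

    `calls` is the accessions x loci matrix (0/2 homozygous codes for inbred
    lines; hets are rendered with IUPAC-free 'h'). With `ref_alt` supplied
    the string uses the actual bases, otherwise '0'/'1'.
    """
    cols = [j for j, nm in enumerate(locus_names) if parse_snp_name(nm)[0] == gene]
    if not cols:
        raise KeyError(f"gene {gene!r} has no loci in the panel")
    calls = np.asarray(calls, dtype=float)
    strings: list[str] = []
    for row in calls[:, cols]:
        if np.any(np.isnan(row)):
            continue  # accessions with missing calls do not contribute a haplotype
        chars = []
        for j, c in zip(cols, row):
            if ref_alt is not None:
                ref, alt = ref_alt[locus_names[j]]
                chars.append(ref if c == 0 else alt if c == 2 else "h")
            else:
                chars.append("0" if c == 0 else "1" if c == 2 else "h")
        strings.append("".join(chars))
    counted = Counter(strings)
    ordered = sorted(counted.items(), key=lambda kv: (-kv[1], kv[0]))
    return HaplotypeTable(
        gene=gene,
        haplotypes=[h for h, _ in ordered],
        counts=[c for _, c in ordered],
        n=len(strings),
    )


def haplotype_diversity(table: HaplotypeTable, rounded: bool = False) -> float:
    """Nei/DnaSP unbiased haplotype diversity Hd = n/(n-1) (1 - sum p_i^2)."""
    if table.n < 2:
        raise ValueError(f"haplotype diversity needs n >= 2 sequences, got n = {table.n}")
    p = table.frequencies
    hd = table.n / (table.n - 1) * (1.0 - float(np.sum(p * p)))
    hd = min(max(hd, 0.0), 1.0)
    return round_half_away(hd, 3) if rounded else hd


def major_haplotype(table: HaplotypeTable) -> Optional[str]:
    """The unique haplotype with frequency strictly above 0.5, if any."""
    for h, c in zip(table.haplotypes, table.counts):
        if c / table.n > 0.5:
            return h
    return None


def biallelic_table_from_ratio(gene: str, ratio: float, n: int) -> HaplotypeTable:
    """Two-haplotype table implied by a carrier ratio over an n-accession panel.

    For an amplicon whose SNPs are all in one complete-LD group the panel
    holds exactly two haplotypes: the carrier class, round(ratio * n)
    accessions, and the reference class.
    """
    carriers = int(round_half_away(ratio * n, 0))
    if not 0 < carriers < n:
        raise ValueError(f"ratio {ratio} yields a monomorphic panel of size {n}")
    major, minor = max(carriers, n - carriers), min(carriers, n - carriers)
    return HaplotypeTable(gene=gene, haplotypes=["0", "1"], counts=[major, minor], n=n)


# --- on-disk form: gene <TAB> tag <TAB> comma-joined members ---------------

def write_ld_groups(groups: Sequence[LdGroup], path: str | Path) -> None:
    lines = ["gene\ttag\tmembers"]
    for g in groups:
        lines.append(f"{g.gene}\t{g.tag}\t{','.join(g.members)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ld_groups(path: str | Path) -> list[LdGroup]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["gene", "tag", "members"]:
        raise ValueError(f"bad LD-group header in {path}")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        gene, tag, members = line.split("\t")
        out.append(LdGroup(gene=gene, tag=tag, members=tuple(members.split(","))))
    return out


def load_bundled_ld_groups() -> list[LdGroup]:
    """The six complete-LD groups observed among the 24 GhSus catalog SNPs.

    Tags here follow the names used in the source study (for the GhSus1Dt
    pair the nonsynonymous member represents the group), not the
    smallest-position default of :func:`detect_complete_ld`.
    """
    with resources.as_file(resources.files("eamkit") / "data" / "ghsus_ld_groups.tsv") as p:
        return read_ld_groups(p)
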