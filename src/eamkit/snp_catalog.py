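"""SNP catalog for candidate-gene EcoTILLING panels.

A catalog row records one natural polymorphism found by screening a gene
amplicon across an inbred panel against a reference accession (TM-1 for
upland cotton): the substituted bases, the 1-based position in the gene's
reference sequence, the fraction of panel accessions carrying the variant,
the amino-acid consequence, and (for nonsynonymous sites) a SIFT score.

SNP names follow the field convention ``<gene>-<ref><position><alt>``, e.g.
``GhSus1Dt-G751A``: in the reference the Dt-subgenome copy carries G at
position 751, replaced by A in the variant accessions. The gene identifier
itself encodes the subgenome (At/Dt suffix).
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from eamkit._util import round_half_away

_BASES = frozenset("ACGT")

_NAME_RE = re.compile(r"^(?P<gene>[^-\s]+)-(?P<ref>[ACGT])(?P<pos>[0-9]+)(?P<alt>[ACGT])$")

#: amino-acid substitution such as "V153I"; "T678=" marks a synonymous site
_AA_RE = re.compile(r"^(?P<from>[A-Z])(?P<residue>[0-9]+)(?P<to>[A-Z]|=)$")

REGION_INTRONIC = "intronic"
REGION_SYNONYMOUS = "synonymous"
REGION_NONSYNONYMOUS = "nonsynonymous"


class SnpNameError(ValueError):
    """Raised for a SNP name that does not follow <gene>-<ref><pos><alt>."""


class AnnotationError(ValueError):
    """Raised for an amino-acid annotation that is neither 'No', 'X123=' nor 'X123Y'."""


@dataclass(frozen=True)
class SnpRecord:
    """One catalogued polymorphism.

    ``variant_ratio`` is the fraction of panel accessions carrying the
    variant base (carrier count / panel size); it is stored as catalogued,
    not folded to <= 0.5 — use :attr:`maf` for the folded frequency.
    """

    gene: str
    position: int
    ref_base: str
    alt_base: str
    variant_ratio: float
    aa_annotation: str
    sift_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(f"bases must be A/C/G/T, got {self.ref_base!r}/{self.alt_base!r}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt base identical ({self.ref_base}) for {self.gene}:{self.position}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 0.0 <= self.variant_ratio <= 1.0:
            raise ValueError(f"variant ratio {self.variant_ratio} outside [0, 1]")
        if self.sift_score is not None:
            if not 0.0 <= self.sift_score <= 1.0:
                raise ValueError(f"SIFT score {self.sift_score} outside [0, 1]")
            if classify_region(self) != REGION_NONSYNONYMOUS:
                raise ValueError(
                    f"SIFT score given for non-nonsynonymous site {self.name}"
                )
        else:
            classify_region(self)  # validate annotation shape eagerly

    @property
    def name(self) -> str:
        return format_snp_name(self.gene, self.ref_base, self.position, self.alt_base)

    @property
    def maf(self) -> float:
        """Folded minor-allele frequency, min(ratio, 1 - ratio)."""
        return min(self.variant_ratio, 1.0 - self.variant_ratio)


@dataclass
class SnpCatalog:
    """Ordered catalog of polymorphisms plus the panel size behind the ratios."""

    records: list[SnpRecord] = field(default_factory=list)
    panel_size: int = 277

    def __post_init__(self) -> None:
        if self.panel_size < 2:
            raise ValueError(f"panel size must be >= 2, got {self.panel_size}")
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.gene, rec.position)
            if key in seen:
                raise ValueError(f"duplicate catalog entry for {rec.gene}:{rec.position}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_names(self) -> list[str]:
        return [rec.name for rec in self.records]

    def genes(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.gene not in out:
                out.append(rec.gene)
        return out


def format_snp_name(gene: str, ref_base: str, position: int, alt_base: str) -> str:
    return f"{gene}-{ref_base}{position}{alt_base}"


def parse_snp_name(name: str) -> tuple[str, str, int, str]:
    """Split ``<gene>-<ref><position><alt>`` into (gene, ref, position, alt).

    >>> parse_snp_name("GhSus1Dt-G751A")
    ('GhSus1Dt', 'G', 751, 'A')
    """
    m = _NAME_RE.match(name)
    if m is None:
        if "-" not in name:
            raise SnpNameError(f"SNP name {name!r}: missing '-' between gene and variant")
        gene, _, variant = name.rpartition("-")
        raise SnpNameError(f"SNP name {name!r}: malformed variant token {variant!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise SnpNameError(f"SNP name {name!r}: position must be positive")
    return m.group("gene"), m.group("ref"), pos, m.group("alt")


def classify_region(record: SnpRecord) -> str:
    """Classify a record as intronic / synonymous / nonsynonymous.

    The catalog convention: annotation ``No`` marks an intronic site;
    ``T678=`` a synonymous codon (no residue change); ``V153I`` a
    nonsynonymous substitution. Case-sensitive.
    """
    ann = record.aa_annotation
    if ann == "No":
        return REGION_INTRONIC
    m = _AA_RE.match(ann)
    if m is None:
        raise AnnotationError(f"unrecognized amino-acid annotation {ann!r} for {record.gene}:{record.position}")
    return REGION_SYNONYMOUS if m.group("to") == "=" else REGION_NONSYNONYMOUS


def sift_damaging(catalog: SnpCatalog, threshold: float = 0.05) -> list[SnpRecord]:
    """Nonsynonymous records predicted damaging: SIFT score strictly below `threshold`."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"SIFT threshold must be in (0, 1), got {threshold}")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    return [
        rec
        for rec in catalog
        if rec.sift_score is not None
        and classify_region(rec) == REGION_NONSYNONYMOUS
        and rec.sift_score < threshold
    ]


@dataclass(frozen=True)
class CatalogSummary:
    n_snps: int
    n_coding: int
    n_synonymous: int
    n_nonsynonymous: int
    n_damaging: int
    ratio_min: float
    ratio_max: float
    ratio_mean: float
    ratio_mean_rounded: float


def catalog_summary(catalog: SnpCatalog, sift_threshold: float = 0.05) -> CatalogSummary:
    """Headline counts and variant-ratio statistics for a catalog."""
    if len(catalog) == 0:
        raise ValueError("cannot summarize an empty catalog")
    regions = [classify_region(rec) for rec in catalog]
    n_syn = regions.count(REGION_SYNONYMOUS)
    n_nonsyn = regions.count(REGION_NONSYNONYMOUS)
    ratios = [rec.variant_ratio for rec in catalog]
    mean = statistics.fmean(ratios)
    return CatalogSummary(
        n_snps=len(catalog),
        n_coding=n_syn + n_nonsyn,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
        n_damaging=len(sift_damaging(catalog, sift_threshold)),
        ratio_min=min(ratios),
        ratio_max=max(ratios),
        ratio_mean=mean,
        ratio_mean_rounded=round_half_away(mean, 3),
    )


def read_catalog(path: str | Path, panel_size: int = 277) -> SnpCatalog:
    """Read a tab-separated catalog: gene, snp_name, ratio, aa_annotation, sift_score.

    The sift_score cell may be empty (absent) for non-coding and synonymous
    sites. One header line is required.
    """
    records: list[SnpRecord] = []
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValueError(f"empty catalog file {path}")
    header = text[0].rstrip("\n").split("\t")
    expected = ["gene", "snp_name", "ratio", "aa_annotation", "sift_score"]
    if [h.strip() for h in header[: len(expected)]] != expected:
        raise ValueError(f"unexpected catalog header {header!r} in {path}")
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated cells")
        gene_col, name, ratio, ann = (c.strip() for c in cells[:4])
        sift = cells[4].strip() if len(cells) > 4 else ""
        gene, ref, pos, alt = parse_snp_name(name)
        if gene != gene_col:
            raise ValueError(f"{path}:{lineno}: gene column {gene_col!r} disagrees with SNP name {name!r}")
        records.append(
            SnpRecord(
                gene=gene,
                position=pos,
                ref_base=ref,
                alt_base=alt,
                variant_ratio=float(ratio),
                aa_annotation=ann,
                sift_score=float(sift) if sift else None,
            )
        )
    return SnpCatalog(records=records, panel_size=panel_size)


def load_bundled_catalog() -> SnpCatalog:
    """The packaged GhSus catalog: 24 SNPs in 8 sucrose-synthase genes, 277 accessions."""
    with resources.as_file(resources.files("eamkit") / "data" / "ghsus_snp_catalog.tsv") as p:
        return read_catalog(p, panel_size=277)


def write_catalog(catalog: SnpCatalog, path: str | Path) -> None:
    lines = ["gene\tsnp_name\tratio\taa_annotation\tsift_score"]
    for rec in catalog:
        sift = "" if rec.sift_score is None else repr(rec.sift_score)
        lines.append(f"{rec.gene}\t{rec.name}\t{rec.variant_ratio!r}\t{rec.aa_annotation}\t{sift}")
    Path(path).write_text("\n".join(lines) + "\n")
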