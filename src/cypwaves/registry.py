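"""Zebrafish cytochrome P450 (CYP) gene registry.

The registry is a curated table of CYP loci on the Zv8 assembly: one row per
annotated transcript, with family/subfamily parsed from the standard CYP
nomenclature (``CYP<family><subfamily letters><gene number>``).  Two genes
(CYP2X10, CYP2X12) appear twice as exact assembly copies carrying ``c1``/``c2``
suffixes; the distinct-gene view collapses these to one gene each.  Genes
supported only by EST evidence and absent from the assembly carry the
``missing_from_assembly`` flag and have no coordinates.

Besides simple accounting (gene and family counts), the module detects tandem
duplication arrays — runs of same-family genes on one chromosome separated by
small genomic gaps — by single-linkage grouping along each chromosome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised status flags for a gene record.
VALID_FLAGS = frozenset(
    {"pseudogene", "assembly_duplicate", "missing_from_assembly", "on_array"}
)

#: Default maximum intergenic gap (bp) for tandem-array membership.  100 kb
#: keeps every printed intra-array gap (all under ~25 kb) in one cluster while
#: splitting arrays separated by hundreds of kb (e.g. the CYP2AA array from
#: the CYP2AE pair ~230 kb downstream).
DEFAULT_MAX_GAP = 100_000

REQUIRED_COLUMNS = (
    "name",
    "family",
    "subfamily",
    "chromosome",
    "tx_start",
    "tx_end",
    "strand",
    "exon_count",
    "flags",
)

_NAME_RE = re.compile(r"^CYP(?P<family>\d+)(?P<letters>[A-Z]+)(?P<num>\d*)(?P<copy>c\d)?$")


class RegistrySchemaError(ValueError):
    """Raised when a registry file does not match the expected schema."""


class RegistryValidationError(ValueError):
    """Raised when a registry row violates a record invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One CYP locus as printed in the registry table.

    Coordinates are 1-based inclusive (Ensembl convention); they are ``None``
    exactly when the gene is flagged ``missing_from_assembly``.
    """

    name: str
    family: int
    subfamily: str
    chromosome: str | None
    tx_start: int | None
    tx_end: int | None
    strand: int | None
    exon_count: int | None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def base_name(self) -> str:
        """Gene name with any ``c1``/``c2`` assembly-copy suffix removed."""
        m = _NAME_RE.match(self.name)
        if m and m.group("copy"):
            return self.name[: -len(m.group("copy"))]
        return self.name

    @property
    def has_coordinates(self) -> bool:
        return self.tx_start is not None and self.tx_end is not None

    def validate(self, row_label: str | None = None) -> None:
        where = f" (row {row_label})" if row_label is not None else ""
        m = _NAME_RE.match(self.name)
        if m is None:
            raise RegistryValidationError(f"unparseable CYP name {self.name!r}{where}")
        if int(m.group("family")) != self.family:
            raise RegistryValidationError(
                f"family {self.family} does not match name {self.name!r}{where}"
            )
        missing = "missing_from_assembly" in self.flags
        if missing != (not self.has_coordinates):
            raise RegistryValidationError(
                f"{self.name}: coordinates must be absent iff missing_from_assembly{where}"
            )
        if self.has_coordinates:
            if self.tx_start > self.tx_end:  # type: ignore[operator]
                raise RegistryValidationError(
                    f"{self.name}: tx_start {self.tx_start} > tx_end {self.tx_end}{where}"
                )
            if self.strand not in (1, -1):
                raise RegistryValidationError(
                    f"{self.name}: strand must be +1 or -1, got {self.strand!r}{where}"
                )
        if self.exon_count is not None and self.exon_count < 1:
            raise RegistryValidationError(f"{self.name}: exon_count < 1{where}")
        bad = self.flags - VALID_FLAGS
        if bad:
            raise RegistryValidationError(f"{self.name}: unknown flags {sorted(bad)}{where}")


@dataclass
class Registry:
    """Ordered collection of :class:`GeneRecord` with provenance."""

    records: list[GeneRecord]
    source: str = "<memory>"
    version: str = "Zv8/Ensembl58"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def distinct_gene_names(self) -> list[str]:
        """Distinct base names, first-occurrence order (c1/c2 copies collapsed)."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.base_name, None)
        return list(seen)

    def subset(
        self,
        family: int | None = None,
        subfamily: str | None = None,
        chromosome: str | None = None,
    ) -> "Registry":
        recs = [
            r
            for r in self.records
            if (family is None or r.family == family)
            and (subfamily is None or r.subfamily == subfamily)
            and (chromosome is None or r.chromosome == chromosome)
        ]
        return Registry(recs, source=self.source, version=self.version)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "name": r.name,
                    "family": r.family,
                    "subfamily": r.subfamily,
                    "chromosome": r.chromosome,
                    "tx_start": r.tx_start,
                    "tx_end": r.tx_end,
                    "strand": r.strand,
                    "exon_count": r.exon_count,
                    "flags": ",".join(sorted(r.flags)),
                }
            )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@dataclass(frozen=True)
class TandemCluster:
    """A run of same-family genes adjacent on one chromosome."""

    chromosome: str
    members: tuple[str, ...]
    span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def packaged_registry_path() -> Path:
    """Path of the CYP registry table shipped with the package."""
    return Path(__file__).parent / "data" / "cyp_registry.tsv"


def _parse_optional_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def load_registry(path: str | Path | None = None) -> Registry:
    """Load and validate a registry TSV.

    With no argument, loads the packaged zebrafish CYP table (96 rows, 94
    distinct genes).

    Raises
    ------
    RegistrySchemaError
        If the file is empty or a required column is missing.
    RegistryValidationError
        If any row violates a record invariant (naming the offending row).
    """
    path = Path(path) if path is not None else packaged_registry_path()
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": "string"})
    except pd.errors.EmptyDataError as exc:
        raise RegistrySchemaError(f"{path}: empty registry file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RegistrySchemaError(f"{path}: missing required column(s) {missing}")

    records: list[GeneRecord] = []
    for idx, row in df.iterrows():
        flags_raw = row["flags"]
        if flags_raw is None or (isinstance(flags_raw, float) and pd.isna(flags_raw)):
            flags: frozenset[str] = frozenset()
        else:
            flags = frozenset(t for t in str(flags_raw).split(",") if t.strip())
        chrom = row["chromosome"]
        rec = GeneRecord(
            name=str(row["name"]).strip(),
            family=int(row["family"]),
            subfamily=str(row["subfamily"]).strip(),
            chromosome=None if pd.isna(chrom) else str(chrom).strip(),
            tx_start=_parse_optional_int(row["tx_start"]),
            tx_end=_parse_optional_int(row["tx_end"]),
            strand=_parse_optional_int(row["strand"]),
            exon_count=_parse_optional_int(row["exon_count"]),
            flags=flags,
        )
        rec.validate(row_label=str(idx + 2))  # +2: header + 1-based
        records.append(rec)

    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RegistryValidationError(f"{path}: duplicate record names {sorted(dupes)}")
    return Registry(records, source=str(path))


def count_genes(registry: Registry, family: int | None = None) -> int:
    """Number of distinct genes (c1/c2 copies collapsed), optionally per family.

    Genes missing from the assembly still count; an empty selection yields 0.
    """
    reg = registry if family is None else registry.subset(family=family)
    return len(reg.distinct_gene_names())


def count_families(registry: Registry) -> int:
    """Number of distinct CYP family numbers present."""
    return len({r.family for r in registry.records})


def tandem_clusters(
    registry: Registry,
    max_gap: int = DEFAULT_MAX_GAP,
    chromosome: str | None = None,
    family: int | None = None,
    subfamily: str | None = None,
) -> list[TandemCluster]:
    """Detect tandem duplication arrays by single-linkage interval grouping.

    Within each chromosome, same-family genes are sorted by ``tx_start`` (ties
    by ``tx_end`` then name) and a new cluster starts whenever the gap between
    the next gene's start and the running maximum end exceeds ``max_gap``.
    Singletons are returned as size-1 clusters.  Records without coordinates
    are excluded with a logged notice.
    """
    reg = registry.subset(family=family, subfamily=subfamily, chromosome=chromosome)
    usable = [r for r in reg.records if r.has_coordinates]
    skipped = [r.name for r in reg.records if not r.has_coordinates]
    if skipped:
        logger.info("tandem_clusters: excluding %d gene(s) without coordinates: %s",
                    len(skipped), ", ".join(skipped))

    clusters: list[TandemCluster] = []
    keys = sorted({(r.chromosome, r.family) for r in usable})
    for chrom, fam in keys:
        group = sorted(
            (r for r in usable if r.chromosome == chrom and r.family == fam),
            key=lambda r: (r.tx_start, r.tx_end, r.name),
        )
        current: list[GeneRecord] = []
        max_end = None
        for rec in group:
            if current and rec.tx_start - max_end > max_gap:  # type: ignore[operator]
                clusters.append(_make_cluster(chrom, current))
                current = []
                max_end = None
            current.append(rec)
            max_end = rec.tx_end if max_end is None else max(max_end, rec.tx_end)
        if current:
            clusters.append(_make_cluster(chrom, current))
    return clusters


def _make_cluster(chromosome: str, members: Sequence[GeneRecord]) -> TandemCluster:
    return TandemCluster(
        chromosome=chromosome,
        members=tuple(r.name for r in members),
        span=(min(r.tx_start for r in members), max(r.tx_end for r in members)),
    )


def export_registry(registry: Registry, path: str | Path, format: str = "tsv") -> Path:
    """Write the registry as TSV (lossless round trip), BED, or GFF3.

    BED uses 0-based half-open coordinates (start = tx_start - 1) and "+"/"-"
    strands; GFF3 keeps 1-based inclusive coordinates.  Records without
    coordinates are skipped in BED/GFF3 output.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        registry.to_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for r in registry.records:
                if not r.has_coordinates:
                    continue
                strand = "+" if r.strand == 1 else "-"
                fh.write(
                    f"{r.chromosome}\t{r.tx_start - 1}\t{r.tx_end}\t{r.name}\t0\t{strand}\n"
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in registry.records:
                if not r.has_coordinates:
                    continue
                strand = "+" if r.strand == 1 else "-"
                attrs = f"ID={r.name};family={r.family};subfamily={r.subfamily}"
                if r.flags:
                    attrs += f";flags={'|'.join(sorted(r.flags))}"
                fh.write(
                    f"{r.chromosome}\tcypwaves\tgene\t{r.tx_start}\t{r.tx_end}\t.\t{strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown export format {format!r}; expected tsv, bed or gff3")
    return path
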