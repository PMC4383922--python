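"""Readers and writers for every file-based input and output of the toolkit.

Supported dialects
------------------
* miRBase-style FASTA for mature and hairpin miRNAs: header token 1 is the
  name (e.g. ``hsa-miR-19b-3p``), token 2 the accession, the remainder a
  free-form description.
* 3'-UTR FASTA with pipe-delimited headers ``transcript_id|gene_symbol|description``.
* Tab-delimited mature x experiment read-count tables with a mandatory header
  row; per-experiment library sizes either as a reserved ``library_size`` row
  or a two-column sidecar file.
* gene2pubmed-style tab-delimited miRNA -> PubMed-ID association pairs.
* Plain-text high-confidence ID lists, one per line.
* Tab-delimited result tables (header + rows, deterministic column order).

All sequences are normalized to the uppercase RNA alphabet at ingest.
Written coordinates are 1-based inclusive; in-memory coordinates are 0-based
half-open.  Parsing preserves file order.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import LengthError, ParseError, ValidationError
from .sequence import normalize_rna

logger = logging.getLogger(__name__)

#: The five supported species, keyed by their miRBase 3-letter name prefix:
#: human, mouse, rat, dog and chicken.
SPECIES_CODES = ("hsa", "mmu", "rno", "cfa", "gga")

MATURE_LEN_MIN = 17
MATURE_LEN_MAX = 30


def species_of(name: str) -> str:
    """Species code from a miRNA name prefix; unknown prefixes are rejected."""
    prefix = name.split("-", 1)[0].lower()
    if prefix not in SPECIES_CODES:
        raise ParseError(
            f"unknown species prefix {prefix!r} in miRNA name {name!r}; "
            f"expected one of {', '.join(SPECIES_CODES)}"
        )
    return prefix


class Arm(enum.Enum):
    FIVE_P = "5p"
    THREE_P = "3p"
    UNKNOWN = "unknown"


@dataclass
class MatureRecord:
    """One mature miRNA: a processed arm of a hairpin precursor."""

    id: str
    name: str
    species: str
    sequence: str
    precursor_id: Optional[str] = None
    arm: Arm = Arm.UNKNOWN

    def __post_init__(self) -> None:
        if not MATURE_LEN_MIN <= len(self.sequence) <= MATURE_LEN_MAX:
            raise LengthError(
                f"mature {self.name}: length {len(self.sequence)} outside "
                f"{MATURE_LEN_MIN}-{MATURE_LEN_MAX} nt"
            )


@dataclass
class PrecursorRecord:
    """One hairpin miRNA gene hosting one or two mature arms."""

    id: str
    name: str
    species: str
    sequence: str
    historical_names: list[str] = field(default_factory=list)
    mature_ids: list[str] = field(default_factory=list)
    high_confidence: bool = False


@dataclass
class UtrRecord:
    """A 3'-UTR (or any user target region) with its gene annotation."""

    transcript_id: str
    gene_symbol: str
    description: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"UTR {self.transcript_id}: empty sequence")


@dataclass
class ExpressionTable:
    """Mature-miRNA x experiment read counts with per-experiment library sizes.

    ``counts`` is a dense nonnegative-integer DataFrame indexed by mature name,
    one column per experiment; ``library_sizes`` the total mapped reads per
    experiment (the RPM denominator).  Pairs absent from the source file are 0.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("expression table contains negative counts")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes[self.library_sizes <= 0].index.tolist()
            raise ValidationError(f"non-positive library size for experiments {bad}")
        colsums = self.counts.sum(axis=0)
        for exp in self.counts.columns:
            if self.library_sizes.get(exp, 0) < colsums[exp]:
                raise ValidationError(
                    f"experiment {exp}: library size {self.library_sizes.get(exp)} "
                    f"below column sum {colsums[exp]}"
                )

    def counts_for(self, mature_id: str) -> pd.Series:
        """Per-experiment counts for a mature; zeros if absent from the table."""
        if mature_id in self.counts.index:
            return self.counts.loc[mature_id]
        return pd.Series(0, index=self.counts.columns)


@dataclass
class PubmedMap:
    """Mapping precursor identifier -> set of associated PubMed IDs."""

    associations: dict[str, set[int]] = field(default_factory=dict)

    def n_records(self, *keys: str) -> int:
        """Count distinct PMIDs under the first key that is present."""
        for key in keys:
            if key is not None and key in self.associations:
                return len(self.associations[key])
        return 0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _prescan_fasta(path: Path) -> None:
    """Cheap structural check so malformed FASTA errors can name a line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:40]!r}"
                )
            return


def _header_fields(description: str) -> tuple[str, str, str]:
    tokens = description.split()
    name = tokens[0]
    accession = tokens[1] if len(tokens) > 1 else name
    rest = " ".join(tokens[2:])
    return name, accession, rest


def read_mature_fasta(
    path: str | Path, species_filter: Optional[str] = None
) -> list[MatureRecord]:
    """Parse a miRBase-style mature FASTA file.

    The arm is inferred from a ``-5p``/``-3p`` name suffix; sequences are
    normalized to RNA.  ``species_filter`` keeps only one species' records.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[MatureRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, accession, _ = _header_fields(rec.description)
        sp = species_of(name)
        if species_filter is not None and sp != species_filter.lower():
            continue
        seq = normalize_rna(str(rec.seq), name=f"mature record {name}")
        lowered = name.lower()
        if lowered.endswith("-5p"):
            arm = Arm.FIVE_P
        elif lowered.endswith("-3p"):
            arm = Arm.THREE_P
        else:
            arm = Arm.UNKNOWN
        records.append(
            MatureRecord(id=accession, name=name, species=sp, sequence=seq, arm=arm)
        )
    return records


def read_hairpin_fasta(path: str | Path) -> list[PrecursorRecord]:
    """Parse a miRBase-style hairpin FASTA file.

    Mature links are not inferred here; attach them with :func:`link_matures`.
    A historical-name annotation may follow the description as
    ``[historical:old-name;older-name]``.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[PrecursorRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name, accession, rest = _header_fields(rec.description)
        if name.lower() in seen:
            raise ParseError(f"{path}: duplicate precursor name {name!r}")
        seen.add(name.lower())
        sp = species_of(name)
        seq = normalize_rna(str(rec.seq), name=f"hairpin record {name}")
        historical: list[str] = []
        m = re.search(r"\[historical:([^\]]*)\]", rest)
        if m:
            historical = [h for h in m.group(1).split(";") if h]
        records.append(
            PrecursorRecord(
                id=accession,
                name=name,
                species=sp,
                sequence=seq,
                historical_names=historical,
            )
        )
    return records


def _name_stem(name: str) -> str:
    stem = name.lower()
    for suffix in ("-5p", "-3p"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem


def link_matures(
    precursors: Sequence[PrecursorRecord], matures: Sequence[MatureRecord]
) -> None:
    """Attach matures to precursors by shared name stem (in place).

    The stem of a mature is its name without the arm suffix, case-insensitive
    ("miR" == "mir").  A precursor matches when its full name equals the stem,
    or its name minus a trailing duplicate-locus index (``-1``, ``-2``...)
    does — e.g. ``hsa-miR-19b-3p`` attaches to both ``hsa-mir-19b-1`` and
    ``hsa-mir-19b-2``.  A precursor shorter than a mature it hosts is
    rejected.
    """
    by_stem: dict[str, list[PrecursorRecord]] = {}
    for prec in precursors:
        lowered = prec.name.lower()
        keys = {lowered}
        m = re.match(r"^(.*)-\d+$", lowered)
        if m:
            keys.add(m.group(1))
        for key in keys:
            by_stem.setdefault(key, []).append(prec)
    for mat in matures:
        hosts = by_stem.get(_name_stem(mat.name), [])
        for prec in hosts:
            if len(prec.sequence) < len(mat.sequence):
                raise ValidationError(
                    f"precursor {prec.name} ({len(prec.sequence)} nt) shorter "
                    f"than hosted mature {mat.name} ({len(mat.sequence)} nt)"
                )
            if mat.id not in prec.mature_ids:
                prec.mature_ids.append(mat.id)
        if hosts and mat.precursor_id is None:
            mat.precursor_id = hosts[0].id


def apply_high_confidence(
    precursors: Iterable[PrecursorRecord], highconf_ids: set[str]
) -> None:
    """Set the high-confidence flag for precursors named/accessioned in the list."""
    ids = {i.lower() for i in highconf_ids}
    for prec in precursors:
        prec.high_confidence = prec.name.lower() in ids or prec.id.lower() in ids


def read_utr_fasta(path: str | Path, species: str = "hsa") -> list[UtrRecord]:
    """Parse a 3'-UTR FASTA with ``transcript_id|gene_symbol|description`` headers.

    Missing header fields are tolerated (empty string, logged warning);
    duplicate transcript IDs are rejected.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[UtrRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        transcript_id = parts[0].split()[0]
        if transcript_id in seen:
            raise ParseError(f"{path}: duplicate transcript ID {transcript_id!r}")
        seen.add(transcript_id)
        gene_symbol = parts[1].strip() if len(parts) > 1 else ""
        description = parts[2].strip() if len(parts) > 2 else ""
        if len(parts) < 3:
            logger.warning(
                "UTR header for %s missing %s field(s); stored empty",
                transcript_id,
                3 - len(parts),
            )
        seq = normalize_rna(str(rec.seq), name=f"UTR record {transcript_id}")
        records.append(
            UtrRecord(
                transcript_id=transcript_id,
                gene_symbol=gene_symbol,
                description=description,
                species=species.lower(),
                sequence=seq,
            )
        )
    return records


def write_mature_fasta(records: Sequence[MatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name} {rec.id}\n{rec.sequence}\n")


def write_hairpin_fasta(records: Sequence[PrecursorRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            extra = ""
            if rec.historical_names:
                extra = f" [historical:{';'.join(rec.historical_names)}]"
            fh.write(f">{rec.name} {rec.id}{extra}\n{rec.sequence}\n")


def write_utr_fasta(records: Sequence[UtrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f">{rec.transcript_id}|{rec.gene_symbol}|{rec.description}\n"
                f"{rec.sequence}\n"
            )


# ---------------------------------------------------------------------------
# Tables and lists
# ---------------------------------------------------------------------------

#: Reserved first-column value carrying per-experiment library sizes in-band.
LIBRARY_SIZE_ROW = "library_size"


def read_expression_table(
    path: str | Path, sizes_path: Optional[str | Path] = None
) -> ExpressionTable:
    """Read a tab-delimited read-count table.

    Layout: mandatory header row (``mature_id`` + experiment names), one row
    per mature miRNA.  Library sizes come from a reserved ``library_size``
    row, a two-column sidecar file, or — with a logged warning — default to
    per-experiment column sums.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if raw.shape[1] < 1:
        raise ParseError(f"{path}: empty table (no columns)")
    id_col = raw.columns[0]
    experiments = [str(c) for c in raw.columns[1:]]

    counts_rows: dict[str, list[int]] = {}
    sizes: Optional[pd.Series] = None
    for _, row in raw.iterrows():
        mature_id = str(row[id_col])
        values: list[int] = []
        for exp in raw.columns[1:]:
            cell = row[exp]
            text = "" if pd.isna(cell) else str(cell).strip()
            if text == "":
                value = 0
            else:
                try:
                    value = int(text)
                except ValueError:
                    raise ValidationError(
                        f"{path}: row {mature_id!r}, column {exp!r}: "
                        f"count {text!r} is not a nonnegative integer"
                    ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}: row {mature_id!r}, column {exp!r}: negative count {value}"
                )
            values.append(value)
        if mature_id == LIBRARY_SIZE_ROW:
            sizes = pd.Series(values, index=experiments, dtype="int64")
        else:
            counts_rows[mature_id] = values

    counts = pd.DataFrame.from_dict(
        counts_rows, orient="index", columns=experiments, dtype="int64"
    )
    if counts.empty:
        counts = pd.DataFrame(
            {exp: pd.Series(dtype="int64") for exp in experiments}
        )

    if sizes_path is not None:
        pairs: dict[str, int] = {}
        with open(sizes_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ParseError(
                        f"{sizes_path}: line {lineno}: expected "
                        f"'experiment<TAB>size', got {line!r}"
                    )
                try:
                    pairs[fields[0]] = int(fields[1])
                except ValueError:
                    raise ParseError(
                        f"{sizes_path}: line {lineno}: size {fields[1]!r} "
                        "is not an integer"
                    ) from None
        sizes = pd.Series(pairs, dtype="int64").reindex(experiments)
        if sizes.isna().any():
            missing = sizes[sizes.isna()].index.tolist()
            raise ValidationError(f"{sizes_path}: missing sizes for {missing}")
        sizes = sizes.astype("int64")
    if sizes is None:
        logger.warning(
            "%s: no library sizes provided; defaulting to per-experiment column sums",
            path,
        )
        sizes = counts.sum(axis=0).astype("int64")
        sizes[sizes <= 0] = 1  # keep RPM defined for all-zero toy tables
    return ExpressionTable(counts=counts, library_sizes=sizes)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write counts plus the in-band ``library_size`` row."""
    out = table.counts.copy()
    out.loc[LIBRARY_SIZE_ROW] = table.library_sizes
    out.index.name = "mature_id"
    out.to_csv(path, sep="\t")


def read_pubmed_map(path: str | Path) -> PubmedMap:
    """Read tab-delimited miRNA<TAB>PMID association pairs; duplicates collapse."""
    associations: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'id<TAB>pmid', got {line!r}"
                )
            try:
                pmid = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: PMID {fields[1]!r} is not an integer"
                ) from None
            if pmid <= 0:
                raise ValidationError(f"{path}: line {lineno}: non-positive PMID {pmid}")
            associations.setdefault(fields[0], set()).add(pmid)
    return PubmedMap(associations=associations)


def write_pubmed_map(pubmed: PubmedMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(pubmed.associations):
            for pmid in sorted(pubmed.associations[key]):
                fh.write(f"{key}\t{pmid}\n")


def read_highconf_list(path: str | Path) -> set[str]:
    """Read a one-ID-per-line high-confidence miRNA list."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return ids


def write_highconf_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(ids):
            fh.write(f"{name}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _render_cell(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_results_tsv(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write a UTF-8 tab-delimited result table with a header row.

    Column order is ``columns`` if given, otherwise the key order of the first
    row (all rows must share one schema).  Integral floats render as integers.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            if set(row.keys()) != set(columns):
                raise ValidationError(
                    f"result row keys {sorted(row)} do not match schema {sorted(columns)}"
                )
            fh.write("\t".join(_render_cell(row[c]) for c in columns) + "\n")


def _infer_cell(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text in ("True", "False"):
        return text == "True"
    return text


def read_results_tsv(path: str | Path) -> list[dict[str, object]]:
    """Read back a result TSV, inferring int/float/bool cell types."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty result file (missing header)")
    columns = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise ParseError(
                f"{path}: line {lineno}: {len(cells)} cells for {len(columns)} columns"
            )
        rows.append({c: _infer_cell(v) for c, v in zip(columns, cells)})
    return rows
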