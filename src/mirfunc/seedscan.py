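"""Custom miRNA target scanning by 7-mer seed complementarity.

The scanner mirrors a web-server target-prediction workflow with two
submission modes:

* a miRNA sequence (17-30 nt) scanned against a set of 3'-UTR sequences, or
* a target sequence (100-30 000 nt) scanned against a species miRNome.

Each miRNA/target pair is screened for perfect Watson-Crick complementarity
between the miRNA *seed* — positions 2-8 from the 5' end, a 7-mer — and the
target sense strand.  Targets (or miRNAs) with at least one seed site receive
an integer surrogate score on the conventional 50-100 presentation scale and
results are ranked by descending score.

The surrogate score is an explicit, documented monotone map from site count
and site density; it is NOT a trained target-prediction model and makes no
claim about repression efficacy.  Coding-region or 5'-UTR scanning needs no
special handling: any sequence within the length bounds is a valid target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import LengthError, ValidationError
from .mirbase_io import MatureRecord, UtrRecord
from .sequence import normalize_rna, revcomp_rna


@dataclass(frozen=True)
class ScanParams:
    """Input bounds, seed definition and score presentation scale."""

    #: Accepted miRNA submission length, nt, inclusive.
    mirna_len_range: tuple[int, int] = (17, 30)
    #: Accepted target submission length, nt, inclusive.
    target_len_range: tuple[int, int] = (100, 30000)
    #: Seed span on the miRNA, 1-based inclusive positions (default 2-8).
    seed_start: int = 2
    seed_end: int = 8
    #: Presentation scale for the surrogate score.
    score_range: tuple[int, int] = (50, 100)

    def __post_init__(self) -> None:
        if self.seed_end - self.seed_start + 1 != 7:
            raise ValidationError(
                f"seed span {self.seed_start}-{self.seed_end} must cover exactly 7 nt"
            )

    @property
    def seed_len(self) -> int:
        return self.seed_end - self.seed_start + 1


DEFAULT_SCAN_PARAMS = ScanParams()


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary 7-mer match on the target sense strand.

    ``start``/``end`` are 0-based half-open target coordinates; reports
    render them 1-based inclusive.
    """

    target_id: str
    start: int
    end: int
    matched_7mer: str
    mirna_id: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_7mer):
            raise ValidationError(
                f"site {self.target_id}:{self.start}-{self.end} span does not "
                f"match 7-mer {self.matched_7mer!r}"
            )


@dataclass(frozen=True)
class ScanRow:
    rank: int
    score: int
    mirna_name: str
    target_id: str
    gene_symbol: str
    gene_annotation: str
    sites: tuple[SeedSite, ...]


@dataclass(frozen=True)
class ScanResult:
    """Ranked scan output: rows sorted by descending score, ranks 1..N."""

    rows: tuple[ScanRow, ...] = field(default_factory=tuple)

    def to_table_rows(self) -> list[dict[str, object]]:
        """Rows for the result TSV; site positions 1-based inclusive."""
        out = []
        for row in self.rows:
            out.append(
                {
                    "rank": row.rank,
                    "surrogate_score": row.score,
                    "mirna_name": row.mirna_name,
                    "target_id": row.target_id,
                    "gene_symbol": row.gene_symbol,
                    "n_sites": len(row.sites),
                    "site_positions": ";".join(
                        f"{s.start + 1}-{s.end}" for s in row.sites
                    ),
                    "matched_7mers": ";".join(s.matched_7mer for s in row.sites),
                }
            )
        return out


SCAN_COLUMNS = [
    "rank",
    "surrogate_score",
    "mirna_name",
    "target_id",
    "gene_symbol",
    "n_sites",
    "site_positions",
    "matched_7mers",
]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_mirna_seq(raw: str, params: ScanParams = DEFAULT_SCAN_PARAMS) -> str:
    """Normalize and validate a user miRNA sequence (default 17-30 nt)."""
    seq = normalize_rna(raw, name="miRNA sequence")
    lo, hi = params.mirna_len_range
    if not lo <= len(seq) <= hi:
        raise LengthError(
            f"miRNA sequence length {len(seq)} nt outside accepted range {lo}-{hi} nt"
        )
    return seq


def validate_target_seq(raw: str, params: ScanParams = DEFAULT_SCAN_PARAMS) -> str:
    """Normalize and validate a user target sequence (default 100-30 000 nt)."""
    seq = normalize_rna(raw, name="target sequence")
    lo, hi = params.target_len_range
    if not lo <= len(seq) <= hi:
        raise LengthError(
            f"target sequence length {len(seq)} nt outside accepted range {lo}-{hi} nt"
        )
    return seq


# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------


def seed_of(mirna_seq: str, params: ScanParams = DEFAULT_SCAN_PARAMS) -> str:
    """The miRNA seed: positions ``seed_start``-``seed_end``, 1-based (default 2-8)."""
    if len(mirna_seq) < params.seed_end:
        raise ValidationError(
            f"miRNA sequence of {len(mirna_seq)} nt too short for seed "
            f"positions {params.seed_start}-{params.seed_end}"
        )
    return mirna_seq[params.seed_start - 1 : params.seed_end]


def find_seed_sites(
    mirna_id: str,
    mirna_seq: str,
    target: UtrRecord,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
) -> list[SeedSite]:
    """All positions where the target carries the reverse complement of the seed.

    The sense strand only is scanned; matches may overlap; sites are returned
    sorted by start coordinate.
    """
    seed = seed_of(mirna_seq, params)
    probe = revcomp_rna(seed)
    sites: list[SeedSite] = []
    start = target.sequence.find(probe)
    while start != -1:
        sites.append(
            SeedSite(
                target_id=target.transcript_id,
                start=start,
                end=start + len(probe),
                matched_7mer=probe,
                mirna_id=mirna_id,
            )
        )
        start = target.sequence.find(probe, start + 1)
    return sites


def site_score(
    sites: Sequence[SeedSite],
    target_len: int,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
) -> int:
    """Integer surrogate score on the 50-100 presentation scale.

    score = min(hi, lo + round(30·(1 − 2^−(n−1)) + 20·min(1, 7n/L)))

    with n the site count and L the target length: a saturating count term
    (0, 15, 22.5, ... toward 30) plus a small coverage-density term.
    Monotone nondecreasing in n at fixed L and in density; a single site on a
    long target sits at the scale floor, full seed coverage at the ceiling.
    """
    if not sites:
        raise ValidationError("site_score requires at least one seed site")
    if target_len <= 0:
        raise ValidationError(f"non-positive target length {target_len}")
    lo, hi = params.score_range
    n = len(sites)
    count_term = 30.0 * (1.0 - 2.0 ** (-(n - 1)))
    density_term = 20.0 * min(1.0, params.seed_len * n / target_len)
    return min(hi, lo + round(count_term + density_term))


# ---------------------------------------------------------------------------
# Scan modes
# ---------------------------------------------------------------------------


def _ranked(entries: list[tuple[int, str, ScanRow]]) -> ScanResult:
    # stable sort on (-score, tie key); ranks assigned 1..N afterwards
    entries.sort(key=lambda e: (-e[0], e[1]))
    rows = tuple(
        replace(row, rank=i) for i, (_, _, row) in enumerate(entries, start=1)
    )
    return ScanResult(rows=rows)


def scan_custom_mirna(
    mirna_seq: str,
    utr_set: Sequence[UtrRecord],
    params: ScanParams = DEFAULT_SCAN_PARAMS,
    mirna_name: str = "custom-miRNA",
) -> ScanResult:
    """Scan one user miRNA against a 3'-UTR collection.

    One result row per target with at least one seed site, ranked by
    descending surrogate score (ties broken by ascending target ID).
    """
    seq = validate_mirna_seq(mirna_seq, params)
    entries: list[tuple[int, str, ScanRow]] = []
    for utr in utr_set:
        sites = find_seed_sites(mirna_name, seq, utr, params)
        if not sites:
            continue
        score = site_score(sites, len(utr.sequence), params)
        row = ScanRow(
            rank=0,
            score=score,
            mirna_name=mirna_name,
            target_id=utr.transcript_id,
            gene_symbol=utr.gene_symbol,
            gene_annotation=utr.description,
            sites=tuple(sites),
        )
        entries.append((score, utr.transcript_id, row))
    return _ranked(entries)


def scan_custom_target(
    target_seq: str,
    mirnome: Sequence[MatureRecord],
    params: ScanParams = DEFAULT_SCAN_PARAMS,
    target_id: str = "custom-target",
    gene_symbol: str = "",
    description: str = "",
    species: Optional[str] = None,
) -> ScanResult:
    """Scan one user target sequence against a species miRNome.

    One result row per miRNA with at least one seed site in the target,
    ranked by descending surrogate score (ties broken by ascending miRNA
    name).  ``species`` optionally filters the miRNome.
    """
    seq = validate_target_seq(target_seq, params)
    target = UtrRecord(
        transcript_id=target_id,
        gene_symbol=gene_symbol,
        description=description,
        species=(species or "hsa"),
        sequence=seq,
    )
    entries: list[tuple[int, str, ScanRow]] = []
    for mat in mirnome:
        if species is not None and mat.species != species.lower():
            continue
        sites = find_seed_sites(mat.name, mat.sequence, target, params)
        if not sites:
            continue
        score = site_score(sites, len(seq), params)
        row = ScanRow(
            rank=0,
            score=score,
            mirna_name=mat.name,
            target_id=target_id,
            gene_symbol=gene_symbol,
            gene_annotation=description,
            sites=tuple(sites),
        )
        entries.append((score, mat.name, row))
    return _ranked(entries)
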